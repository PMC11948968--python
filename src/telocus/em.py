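"""Prior-weighted EM for multi-mapping fragment reassignment.

The generative model treats each sequenced fragment as drawn from one of K
TE transcripts.  Two simplex parameter vectors are estimated: ``pi``, the
proportion of fragments originating from each transcript, and ``theta``,
the reassignment proportions applied to non-unique fragments.  For
fragment ``a`` with candidate locus ``i`` and alignment weight ``q_{a,i}``,
the E-step posterior is

    E[t_i | s_a]  propto  q_{a,i} * pi_i * theta_i^{y_a}

normalized over the fragment's candidates, where ``y_a = 1`` for
multi-mapped fragments and 0 otherwise (a uniquely mapped fragment keeps
posterior 1 on its sole candidate).

The M-step is a maximum-a-posteriori update that injects the long-read
subfamily fractions ``t_i^Lf`` (see :mod:`telocus.prior`) as a prior with
weight ``w``:

    pi_hat_i    = (sum_a E_{a,i}      + (w*T) * t_i^Lf) / (T + (w*T) * F)
    theta_hat_i = (sum_a E_{a,i}*y_a  + (w*M) * t_i^Lf) / (M + (w*M) * F)

with ``T = sum_{i,a} E_{a,i}`` (= number of fragments), ``M = sum_a y_a``
(number of multi-mapped fragments) and ``F = sum_i t_i^Lf`` (the number of
subfamilies with nonzero long-read signal; no renormalization is applied
beyond the formula).  Both updates are algebraically simplex-valued.  At
``w = 0`` the updates reduce to the prior-free maximum-likelihood EM; as
``w -> infinity`` they converge to the normalized prior.

E- and M-steps alternate until the maximum absolute change over the
concatenation of ``pi`` and ``theta`` falls below ``epsilon`` (default
0.001) or ``max_iter`` is reached.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .fragments import FragmentMatrix
from .prior import PriorVector

__all__ = [
    "EMParams",
    "EMState",
    "initialize",
    "e_step",
    "m_step_map",
    "run_em",
    "tied_best_fraction",
]

logger = logging.getLogger(__name__)

PRIOR_CHANGE_OPTIONS = ("pi", "theta", "both", "none")


@dataclasses.dataclass
class EMParams:
    """Tuning knobs of the prior-weighted EM.

    ``long_read_weight`` scales the prior's pull (0 disables it);
    ``prior_change`` selects which of pi / theta receives the prior term
    ("none" gives a pure prior-free EM for A/B comparisons).
    """

    long_read_weight: float = 1.0
    prior_change: str = "both"
    epsilon: float = 1e-3
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.long_read_weight < 0:
            raise ValueError("long_read_weight must be >= 0")
        if self.prior_change not in PRIOR_CHANGE_OPTIONS:
            raise ValueError(
                f"prior_change must be one of {PRIOR_CHANGE_OPTIONS}, got {self.prior_change!r}"
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclasses.dataclass
class EMState:
    """Current parameter estimates, posteriors and iteration diagnostics.

    ``E`` is aligned with the matrix's COO entries (one posterior weight
    per fragment-candidate pair, summing to 1 within each fragment).
    """

    pi: np.ndarray
    theta: np.ndarray
    E: np.ndarray
    n_iter: int = 0
    max_delta: float = np.inf
    converged: bool = False
    trace: list[tuple[int, float]] = dataclasses.field(default_factory=list)


def initialize(matrix: FragmentMatrix, K: int | None = None) -> EMState:
    """Equal-weight initialization: uniform posteriors, uniform pi/theta."""
    K = matrix.K if K is None else K
    if K == 0:
        raise ValueError("cannot initialize EM with K = 0 loci")
    if matrix.n_fragments == 0:
        raise ValueError("cannot initialize EM with an empty fragment matrix")
    counts = np.diff(matrix.row_ptr)
    E = 1.0 / counts[matrix.frag_idx].astype(float)
    return EMState(pi=np.full(K, 1.0 / K), theta=np.full(K, 1.0 / K), E=E)


def e_step(pi: np.ndarray, theta: np.ndarray, matrix: FragmentMatrix) -> np.ndarray:
    """Posterior assignment weights under the current pi/theta.

    Normalization divides by the per-fragment maximum before summing to
    guard against underflow.  A fragment whose unnormalized weights are all
    zero falls back to a uniform posterior (with a warning).
    """
    frag, locus = matrix.frag_idx, matrix.locus_idx
    N = matrix.n_fragments
    unnorm = matrix.q * pi[locus]
    multi = matrix.y[frag] == 1
    unnorm = np.where(multi, unnorm * theta[locus], unnorm)
    rowmax = np.zeros(N)
    np.maximum.at(rowmax, frag, unnorm)
    dead = rowmax == 0
    if dead.any():
        logger.warning(
            "%d fragments had all-zero posterior weights; uniform fallback", int(dead.sum())
        )
        unnorm = np.where(dead[frag], 1.0, unnorm)
        rowmax = np.where(dead, 1.0, rowmax)
    scaled = unnorm / rowmax[frag]
    rowsum = np.bincount(frag, weights=scaled, minlength=N)
    return scaled / rowsum[frag]


def m_step_map(
    E: np.ndarray,
    matrix: FragmentMatrix,
    prior: PriorVector | np.ndarray,
    params: EMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """MAP updates for (pi, theta) with the long-read prior term.

    With no multi-mapped fragments (M = 0) theta has no data; it is set
    uniform and logged.
    """
    fraction = prior.fraction if isinstance(prior, PriorVector) else np.asarray(prior, float)
    K = matrix.K
    frag, locus = matrix.frag_idx, matrix.locus_idx
    w = params.long_read_weight
    w_pi = w if params.prior_change in ("both", "pi") else 0.0
    w_th = w if params.prior_change in ("both", "theta") else 0.0
    fsum = fraction.sum()

    col = np.bincount(locus, weights=E, minlength=K)
    T = col.sum()
    pi_hat = (col + (w_pi * T) * fraction) / (T + (w_pi * T) * fsum)

    multi_E = E * matrix.y[frag]
    col_m = np.bincount(locus, weights=multi_E, minlength=K)
    M = col_m.sum()
    if M == 0:
        logger.info("no multi-mapped fragments; theta set uniform")
        theta_hat = np.full(K, 1.0 / K)
    else:
        theta_hat = (col_m + (w_th * M) * fraction) / (M + (w_th * M) * fsum)
    return pi_hat, theta_hat


def run_em(
    matrix: FragmentMatrix,
    prior: PriorVector | np.ndarray,
    params: EMParams | None = None,
) -> EMState:
    """Alternate E- and M-steps until the parameter change drops below epsilon.

    Returns the state with a final E-step evaluated at the converged
    parameters.  Non-convergence within ``max_iter`` is flagged on the
    state, not raised.
    """
    params = params or EMParams()
    state = initialize(matrix)
    pi, theta = state.pi, state.theta
    for it in range(1, params.max_iter + 1):
        E = e_step(pi, theta, matrix)
        pi_new, theta_new = m_step_map(E, matrix, prior, params)
        delta = max(np.abs(pi_new - pi).max(), np.abs(theta_new - theta).max())
        state.trace.append((it, float(delta)))
        pi, theta = pi_new, theta_new
        state.n_iter, state.max_delta = it, float(delta)
        if delta < params.epsilon:
            state.converged = True
            break
    state.pi, state.theta = pi, theta
    state.E = e_step(pi, theta, matrix)
    if not state.converged:
        logger.warning(
            "EM did not converge in %d iterations (last max delta %.3g)",
            params.max_iter,
            state.max_delta,
        )
    return state


def tied_best_fraction(
    matrix: FragmentMatrix, E: np.ndarray, rel_tol: float = 1e-9
) -> float:
    """Fraction of multi-mapped fragments whose posterior best is tied.

    A fragment counts as unresolved when its top two posterior weights
    differ by at most ``rel_tol`` relative to the maximum — the EM could
    not single out one locus.  Returns 0 when there are no multi-mapped
    fragments.
    """
    n_multi = matrix.n_multi
    if n_multi == 0:
        return 0.0
    tied = 0
    for a in np.flatnonzero(matrix.y == 1):
        s, e = matrix.row_ptr[a], matrix.row_ptr[a + 1]
        row = E[s:e]
        top = row.max()
        if (row >= top * (1 - rel_tol)).sum() >= 2:
            tied += 1
    return tied / n_multi
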