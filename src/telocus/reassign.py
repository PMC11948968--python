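"""Final per-locus counts from converged posteriors, and TPM reports.

After EM convergence every fragment carries a posterior over its candidate
loci.  Four reassignment modes turn posteriors into counts:

``best``
    each fragment contributes 1 to its highest-posterior locus; exact ties
    are broken by a seeded uniform choice.
``long_read``
    like ``best``, but a tied set's mass is redistributed by the weighted
    mean of the raw long-read TPM values ``t^L`` of the tied loci:
    ``TE_A^fc = (TE_A^c + TE_B^c + ...) * t_A^L / (t_A^L + t_B^L + ...)``.
    If every tied locus has ``t^L = 0`` the mass is split evenly (warned).
``average``
    fractional posteriors are summed per locus (column sums of E).
``unique``
    only uniquely mapped fragments are counted.

``best``, ``average`` and ``long_read`` conserve total mass (sum of final
counts = number of fragments); ``unique`` sums to the number of y = 0
fragments.  Tie detection uses a relative tolerance on posterior weights
because exact float equality is too brittle.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationIndex
from .em import EMState
from .fragments import FragmentMatrix
from .prior import PriorVector

__all__ = ["CountTable", "final_counts", "counts_to_report"]

logger = logging.getLogger(__name__)

REASSIGN_MODES = ("best", "average", "unique", "long_read")
TIE_REL_TOL = 1e-9


@dataclasses.dataclass
class CountTable:
    """Per-locus count summary.

    ``em_count`` is the posterior column sum (the EM's fractional count,
    TE^c); ``final_count`` is the mode-dependent final assignment (TE^fc);
    ``unique_count`` counts uniquely mapped fragments only.
    """

    locus_ids: list[str]
    final_count: np.ndarray
    unique_count: np.ndarray
    em_count: np.ndarray
    mode: str
    n_fragments: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "final_count": self.final_count,
                "unique_count": self.unique_count,
                "em_count": self.em_count,
            }
        )


def final_counts(
    state: EMState,
    matrix: FragmentMatrix,
    prior: PriorVector | np.ndarray | None,
    mode: str = "long_read",
    seed: int = 0,
    index: AnnotationIndex | None = None,
    tie_rel_tol: float = TIE_REL_TOL,
) -> CountTable:
    """Convert posteriors into a :class:`CountTable` under ``mode``.

    ``prior`` supplies the raw long-read TPM used by ``long_read`` tie
    redistribution (the subfamily fractions are not used here); it may be
    omitted for the other modes.
    """
    if mode not in REASSIGN_MODES:
        raise ValueError(f"mode must be one of {REASSIGN_MODES}, got {mode!r}")
    if mode == "long_read":
        if prior is None:
            raise ValueError("long_read mode requires the long-read prior table")
        tl = prior.tpm if isinstance(prior, PriorVector) else np.asarray(prior, float)
    else:
        tl = None
    K = matrix.K
    rng = np.random.default_rng(seed)
    E, frag, locus = state.E, matrix.frag_idx, matrix.locus_idx

    em_count = np.bincount(locus, weights=E, minlength=K)
    unique_rows = matrix.y == 0
    unique_count = np.zeros(K)
    final = np.zeros(K)
    zero_tl_ties = 0

    for a in range(matrix.n_fragments):
        s, e = matrix.row_ptr[a], matrix.row_ptr[a + 1]
        loci, post = locus[s:e], E[s:e]
        if unique_rows[a]:
            unique_count[loci[0]] += 1.0
        if mode == "average":
            np.add.at(final, loci, post)
            continue
        if mode == "unique":
            if unique_rows[a]:
                final[loci[0]] += 1.0
            continue
        top = post.max()
        tied = loci[post >= top * (1 - tie_rel_tol)]
        if tied.size == 1:
            final[tied[0]] += 1.0
        elif mode == "best":
            final[rng.choice(tied)] += 1.0
        else:  # long_read
            weights = tl[tied]
            total = weights.sum()
            if total > 0:
                final[tied] += weights / total
            else:
                zero_tl_ties += 1
                final[tied] += 1.0 / tied.size
    if zero_tl_ties:
        logger.warning(
            "%d tied fragments had zero long-read TPM at every tied locus; split evenly",
            zero_tl_ties,
        )
    ids = index.locus_ids() if index is not None else [str(i) for i in range(K)]
    return CountTable(
        locus_ids=ids,
        final_count=final,
        unique_count=unique_count,
        em_count=em_count,
        mode=mode,
        n_fragments=matrix.n_fragments,
    )


def counts_to_report(
    table: CountTable,
    index: AnnotationIndex,
    library_size_rule: str = "te_total",
    coding_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-locus report with TPM under the chosen library-size rule.

    ``te_total`` normalizes against the TE length-rate sum itself;
    ``coding_gene_total`` uses the summed length-rates of a coding-gene
    count table (columns ``count`` and ``length``) as the denominator, so
    TE TPM values are on the same scale as a gene-level quantification and
    their sum is below 1e6 whenever genes carry most of the library.
    Rows are sorted by locus id.
    """
    if library_size_rule not in ("te_total", "coding_gene_total"):
        raise ValueError(f"unknown library_size_rule {library_size_rule!r}")
    lengths = index.lengths()
    rate = np.asarray(table.final_count, float) / lengths
    if library_size_rule == "te_total":
        denom = rate.sum()
    else:
        if coding_counts is None:
            raise ValueError("coding_gene_total rule requires a coding-gene count table")
        coding_rate = (
            coding_counts["count"].to_numpy(float) / coding_counts["length"].to_numpy(float)
        )
        denom = coding_rate.sum()
    tpm = np.zeros_like(rate) if denom == 0 else 1e6 * rate / denom
    subfam = {loc.locus_id: loc.subfamily for loc in index}
    df = pd.DataFrame(
        {
            "locus_id": table.locus_ids,
            "subfamily": [subfam.get(i, "") for i in table.locus_ids],
            "final_count": table.final_count,
            "unique_count": table.unique_count,
            "em_count": table.em_count,
            "tpm": tpm,
        }
    )
    return df.sort_values("locus_id", kind="stable").reset_index(drop=True)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
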