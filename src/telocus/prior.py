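"""Long-read expression priors for TE loci.

Long-read RNA-seq spans whole TE copies, so most long reads place
unambiguously at a single locus.  This module turns a per-locus long-read
count (or TPM) table into the prior injected into the EM M-step:

1. raw counts are converted to TPM,
2. zero entries are optionally replaced by a small *rescue* constant ``c``
   so loci seen only in the short-read data are not forced to zero, and
3. TPM values are normalized **within each subfamily** into fractions
   ``t_i^Lf = t_i^L / sum_{j in subT} t_j^L``, where ``subT`` is the set of
   loci sharing a subfamily with ``i``.

Subfamily-level normalization reflects that multi-mapping is essentially a
within-subfamily phenomenon: the prior expresses how long reads divide a
subfamily's expression among its copies, not how subfamilies compare.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationIndex

__all__ = [
    "PriorVector",
    "counts_to_tpm",
    "apply_rescue",
    "subfamily_fractions",
    "load_longread_table",
    "build_prior",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PriorVector:
    """Per-locus long-read TPM (after rescue) and subfamily fraction.

    Arrays are aligned with the :class:`~telocus.annotation.AnnotationIndex`
    locus order.  For every subfamily with at least one positive TPM the
    fractions sum to 1; an all-zero subfamily keeps fractions of 0 (the
    prior then contributes nothing for those loci).
    """

    locus_ids: list[str]
    tpm: np.ndarray
    fraction: np.ndarray
    rescue_c: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus_id": self.locus_ids, "tpm": self.tpm, "fraction": self.fraction}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def counts_to_tpm(
    counts: np.ndarray, lengths: np.ndarray, locus_ids: list[str] | None = None
) -> np.ndarray:
    """Convert raw per-locus counts to transcripts per million.

    ``tpm_i = 1e6 * (count_i / length_i) / sum_j (count_j / length_j)``.
    An all-zero input yields an all-zero output.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    bad = np.flatnonzero(lengths <= 0)
    if bad.size:
        name = locus_ids[bad[0]] if locus_ids is not None else f"index {bad[0]}"
        raise ValueError(f"non-positive length for locus {name}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return 1e6 * rate / total


def apply_rescue(tpm: np.ndarray, c: float) -> np.ndarray:
    """Replace zero TPM entries with the rescue constant ``c``.

    With ``c = 0`` (the default) the input is returned unchanged; a small
    positive ``c`` (e.g. 1e-50) keeps loci quantified only by short reads
    from being zeroed by the multiplicative prior.
    """
    if c < 0:
        raise ValueError(f"rescue constant must be >= 0, got {c}")
    tpm = np.asarray(tpm, dtype=float)
    if c == 0:
        return tpm.copy()
    out = tpm.copy()
    out[out == 0] = c
    return out


def subfamily_fractions(tpm: np.ndarray, index: AnnotationIndex) -> PriorVector:
    """Normalize per-locus TPM within each subfamily into prior fractions."""
    tpm = np.asarray(tpm, dtype=float)
    if tpm.shape != (index.K,):
        raise ValueError(f"expected {index.K} tpm values, got {tpm.shape}")
    fraction = np.zeros(index.K)
    for members in index.subfamily_members.values():
        pos = np.array(sorted(index.position(m) for m in members))
        total = tpm[pos].sum()
        if total > 0:
            fraction[pos] = tpm[pos] / total
    return PriorVector(locus_ids=index.locus_ids(), tpm=tpm, fraction=fraction)


def load_longread_table(path: str | Path) -> pd.DataFrame:
    """Read a long-read per-locus table (TSV with header).

    Must contain a ``locus_id`` column plus ``tpm`` and/or ``count``.
    """
    df = pd.read_csv(path, sep="\t")
    if "locus_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'locus_id'")
    if "tpm" not in df.columns and "count" not in df.columns:
        raise ValueError(f"{path}: need a 'tpm' or 'count' column")
    return df


def build_prior(
    table: pd.DataFrame | None,
    index: AnnotationIndex,
    rescue_c: float = 0.0,
) -> PriorVector:
    """Assemble the :class:`PriorVector` from a long-read table.

    Loci present in the annotation but absent from the table get TPM 0
    (rescue then applies); ids in the table but not in the annotation are
    warned about and ignored.  A supplied ``tpm`` column is used directly;
    otherwise ``count`` is converted with the annotated locus lengths.
    ``table=None`` builds an all-zero prior (useful for prior-free runs).
    """
    if table is None:
        tpm = np.zeros(index.K)
    else:
        extra = [i for i in table["locus_id"] if i not in index]
        if extra:
            logger.warning(
                "long-read table has %d ids absent from the annotation (e.g. %s); ignored",
                len(extra),
                extra[0],
            )
        col = "tpm" if "tpm" in table.columns else "count"
        series = table.set_index("locus_id")[col]
        if series.index.has_duplicates:
            raise ValueError("long-read table has duplicate locus ids")
        values = series.reindex(index.locus_ids()).fillna(0.0).to_numpy(dtype=float)
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValueError("long-read table values must be finite and non-negative")
        tpm = values if col == "tpm" else counts_to_tpm(values, index.lengths(), index.locus_ids())
    tpm = apply_rescue(tpm, rescue_c)
    prior = subfamily_fractions(tpm, index)
    prior.rescue_c = rescue_c
    return prior
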