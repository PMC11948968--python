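"""Sparse fragment-by-locus evidence matrix from short-read alignments.

A *fragment* is a sequenced template (a read pair counts once).  Each
fragment contributes one matrix row holding its candidate TE loci with
alignment-score-derived likelihood weights ``q`` in (0, 1] (best candidate
gets 1).  Fragments with a single candidate are uniquely mapped
(indicator ``y = 0``); fragments with two or more candidates are
multi-mapped (``y = 1``) and are the ones the EM reassigns.

Construction is canonical — rows sorted by fragment name, candidates by
locus index — so the matrix is independent of alignment record order.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import sparse

from .annotation import AnnotationIndex

__all__ = ["FragmentMatrix", "score_to_weight", "ingest_alignments"]

logger = logging.getLogger(__name__)


def score_to_weight(scores, lam: float = 0.1) -> np.ndarray:
    """Map alignment scores of one fragment's candidates to weights.

    ``q_i = exp(lam * (score_i - max score))`` — order preserving, best
    candidate pinned at 1.  ``lam`` rescales per-base score differences to
    likelihood ratios and is aligner dependent, hence tunable.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("score_to_weight requires at least one score")
    return np.exp(lam * (scores - scores.max()))


@dataclasses.dataclass
class FragmentMatrix:
    """Sparse fragments x loci matrix in row-sorted COO layout.

    ``frag_idx``/``locus_idx``/``q``/``score`` are parallel arrays sorted by
    (fragment, locus).  ``y[a] = 1`` iff fragment ``a`` has >= 2 candidates.
    """

    fragment_names: list[str]
    K: int
    frag_idx: np.ndarray
    locus_idx: np.ndarray
    q: np.ndarray
    score: np.ndarray
    y: np.ndarray
    row_ptr: np.ndarray  # CSR-style offsets, len N+1

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_names)

    @property
    def n_multi(self) -> int:
        return int(self.y.sum())

    def row(self, a: int) -> tuple[np.ndarray, np.ndarray]:
        """(locus indices, q weights) of fragment ``a``."""
        s, e = self.row_ptr[a], self.row_ptr[a + 1]
        return self.locus_idx[s:e], self.q[s:e]

    def to_sparse(self) -> sparse.csr_matrix:
        return sparse.csr_matrix(
            (self.q, (self.frag_idx, self.locus_idx)), shape=(self.n_fragments, self.K)
        )

    def write_tsv(self, path: str | Path, index: AnnotationIndex) -> None:
        ids = index.locus_ids()
        pd.DataFrame(
            {
                "fragment_id": [self.fragment_names[a] for a in self.frag_idx],
                "locus_id": [ids[i] for i in self.locus_idx],
                "q": self.q,
                "y": self.y[self.frag_idx],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_candidates(
        cls,
        candidates: dict[str, dict[int, float]],
        K: int,
        lam: float = 0.1,
    ) -> "FragmentMatrix":
        """Build from {fragment name -> {locus index -> score}}."""
        if not candidates:
            raise ValueError("no fragments with TE-overlapping alignments")
        names = sorted(candidates)
        frag_idx, locus_idx, qs, scores = [], [], [], []
        y = np.zeros(len(names), dtype=np.int8)
        row_ptr = [0]
        for a, name in enumerate(names):
            row = sorted(candidates[name].items())
            loci = [i for i, _ in row]
            sc = np.array([s for _, s in row], dtype=float)
            q = score_to_weight(sc, lam)
            frag_idx.extend([a] * len(row))
            locus_idx.extend(loci)
            qs.extend(q)
            scores.extend(sc)
            y[a] = 1 if len(row) >= 2 else 0
            row_ptr.append(row_ptr[-1] + len(row))
        return cls(
            fragment_names=names,
            K=K,
            frag_idx=np.array(frag_idx, dtype=np.int64),
            locus_idx=np.array(locus_idx, dtype=np.int64),
            q=np.array(qs, dtype=float),
            score=np.array(scores, dtype=float),
            y=y,
            row_ptr=np.array(row_ptr, dtype=np.int64),
        )


def _load_exclusion(bed: str | Path) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with Path(bed).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def _alignment_score(read: pysam.AlignedSegment) -> tuple[float, bool]:
    """Aligner score for a record; falls back to -(edit distance), else 0."""
    if read.has_tag("AS"):
        return float(read.get_tag("AS")), True
    if read.has_tag("NM"):
        return -float(read.get_tag("NM")), True
    return 0.0, False


def ingest_alignments(
    path: str | Path,
    index: AnnotationIndex,
    min_overlap: float = 0.0,
    lam: float = 0.1,
    exclude_bed: str | Path | None = None,
    stranded: bool = False,
) -> FragmentMatrix:
    """Read a BAM/SAM file and build the fragment x locus matrix.

    A candidate is created for every distinct TE locus that a fragment's
    alignments overlap by at least ``min_overlap`` of the aligned bases
    (default: any overlap, >= 1 base).  Mates overlapping the same locus
    form a single candidate with the summed pair score; duplicate
    alignments of the same (fragment, locus, mate) keep the best score.
    Secondary and supplementary alignments are included.  Fragments
    overlapping no TE locus are dropped.
    """
    exclusion = _load_exclusion(exclude_bed) if exclude_bed else None
    # qname -> locus position -> mate (0/1) -> best score
    acc: dict[str, dict[int, dict[int, float]]] = {}
    missing_score = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.reference_name is None:
                continue
            chrom = read.reference_name
            start, end = read.reference_start, read.reference_end
            if end is None or end <= start:
                continue
            if exclusion is not None:
                tree = exclusion.get(chrom)
                if tree is not None and tree.overlap(start, end):
                    continue
            aligned = read.query_alignment_length or (end - start)
            min_bases = max(1, int(math.ceil(min_overlap * aligned)))
            strand = None
            if stranded:
                strand = "-" if read.is_reverse else "+"
            hits = index.overlapping_loci(chrom, start, end, strand=strand)
            if not hits:
                continue
            score, has_score = _alignment_score(read)
            if not has_score:
                missing_score += 1
            mate = 1 if read.is_read2 else 0
            per_locus = acc.setdefault(read.query_name, {})
            for lid in hits:
                loc = index.get(lid)
                if min(end, loc.end) - max(start, loc.start) < min_bases:
                    continue
                pos = index.position(lid)
                mates = per_locus.setdefault(pos, {})
                if mate not in mates or score > mates[mate]:
                    mates[mate] = score
    if missing_score:
        logger.warning(
            "%d alignments had neither AS nor NM tags; scored 0 (uniform weights)",
            missing_score,
        )
    candidates = {
        name: {pos: sum(mates.values()) for pos, mates in per_locus.items()}
        for name, per_locus in acc.items()
        if per_locus
    }
    if not candidates:
        raise ValueError(f"{path}: no fragments overlap the TE annotation")
    matrix = FragmentMatrix.from_candidates(candidates, index.K, lam=lam)
    logger.info(
        "ingested %d fragments (%d multi-mapped) over %d loci",
        matrix.n_fragments,
        matrix.n_multi,
        index.K,
    )
    return matrix
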