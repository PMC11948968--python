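"""Indexed locus-level transposable-element (TE) annotations.

A locus-level TE annotation carries one record per genomic TE copy (a
*locus*), each assigned to a subfamily whose members descend from a common
consensus sequence.  High within-subfamily sequence identity is what makes
short RNA-seq reads multi-map, so the annotation plays two roles for the
quantifier: it defines the transcript universe ``T = {t_1, ..., t_K}`` over
which fragment-origin proportions are estimated, and it answers the
interval-overlap queries used to attach alignments to candidate loci.

Coordinates are 0-based half-open internally; GTF input/output converts at
the boundary (GTF is 1-based inclusive).  Overlap queries are
strand-agnostic by default, with an optional stranded mode.
"""

from __future__ import annotations

import dataclasses
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GTFParseError",
    "TELocus",
    "AnnotationIndex",
    "parse_te_gtf",
    "write_te_gtf",
]


class GTFParseError(ValueError):
    """A GTF record could not be interpreted as a TE locus."""


# GTF attribute column: key "value"; pairs separated by semicolons.
_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


@dataclasses.dataclass(frozen=True)
class TELocus:
    """One genomic TE copy.

    ``start``/``end`` are 0-based half-open.  ``subfamily`` groups copies
    sharing a consensus; ``family`` and ``te_class`` are optional coarser
    groupings (e.g. L1 / LINE) carried through for reporting only.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    subfamily: str = ""
    family: str | None = None
    te_class: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.locus_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"locus {self.locus_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotationIndex:
    """Ordered collection of :class:`TELocus` with an interval index.

    Loci keep their input order; ``position(locus_id)`` gives the dense
    integer index used by the fragment matrix and the EM state.
    """

    def __init__(self, loci: Iterable[TELocus]):
        self.loci: list[TELocus] = list(loci)
        self._pos: dict[str, int] = {}
        for i, loc in enumerate(self.loci):
            if loc.locus_id in self._pos:
                raise ValueError(f"duplicate locus id {loc.locus_id!r}")
            self._pos[loc.locus_id] = i
        self.subfamily_members: dict[str, set[str]] = defaultdict(set)
        for loc in self.loci:
            self.subfamily_members[loc.subfamily].add(loc.locus_id)
        self.subfamily_members = dict(self.subfamily_members)
        self._trees: dict[str, IntervalTree] = {}
        for i, loc in enumerate(self.loci):
            self._trees.setdefault(loc.chrom, IntervalTree()).addi(loc.start, loc.end, i)

    # -- container protocol -------------------------------------------------
    @property
    def K(self) -> int:
        return len(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[TELocus]:
        return iter(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._pos

    def get(self, locus_id: str) -> TELocus:
        return self.loci[self._pos[locus_id]]

    def position(self, locus_id: str) -> int:
        """Dense integer index of a locus (stable across the run)."""
        return self._pos[locus_id]

    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def lengths(self) -> np.ndarray:
        """Per-locus lengths in bases, in index order."""
        return np.array([loc.length for loc in self.loci], dtype=float)

    def subfamilies(self) -> list[str]:
        return [loc.subfamily for loc in self.loci]

    # -- queries ------------------------------------------------------------
    def overlapping_loci(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[str]:
        """Locus ids whose intervals intersect ``[start, end)`` on ``chrom``.

        Returned in genomic order (start, then end, then input order).  An
        unknown chromosome yields an empty list.  When ``strand`` is given,
        only loci on that strand (or with unspecified strand) are returned.
        """
        if start >= end:
            raise ValueError(f"query start ({start}) must be < end ({end})")
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda i: (self.loci[i].start, self.loci[i].end, i))
        out = []
        for i in hits:
            loc = self.loci[i]
            if strand is not None and loc.strand not in (strand, "."):
                continue
            out.append(loc.locus_id)
        return out


def parse_te_gtf(
    path: str | Path,
    locus_key: str = "gene_id",
    subfamily_key: str = "family_id",
    class_key: str = "class_id",
) -> AnnotationIndex:
    """Parse a RepeatMasker-style locus-level TE GTF.

    Every feature row must carry a locus-identifier attribute
    (``locus_key``) and a subfamily attribute (``subfamily_key``); the key
    names are configurable because RepeatMasker-derived GTF dialects differ.
    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention.

    Raises
    ------
    GTFParseError
        On malformed rows, missing attributes, or invalid coordinates; the
        message names the offending line number.
    """
    loci: list[TELocus] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, _feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GTFParseError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            if locus_key not in attr:
                raise GTFParseError(
                    f"{path.name}:{lineno}: missing locus-id attribute {locus_key!r}"
                )
            if subfamily_key not in attr:
                raise GTFParseError(
                    f"{path.name}:{lineno}: missing subfamily attribute {subfamily_key!r}"
                )
            if start1 > end1:
                raise GTFParseError(
                    f"{path.name}:{lineno}: start ({start1}) greater than end ({end1})"
                )
            loci.append(
                TELocus(
                    locus_id=attr[locus_key],
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in ("+", "-") else ".",
                    subfamily=attr[subfamily_key],
                    te_class=attr.get(class_key),
                )
            )
    try:
        return AnnotationIndex(loci)
    except ValueError as exc:
        raise GTFParseError(str(exc)) from exc


def write_te_gtf(
    index: AnnotationIndex,
    path: str | Path,
    source: str = "telocus",
    feature: str = "exon",
    locus_key: str = "gene_id",
    subfamily_key: str = "family_id",
    class_key: str = "class_id",
) -> None:
    """Write the annotation back to GTF (round-trips with :func:`parse_te_gtf`)."""
    with Path(path).open("w") as fh:
        for loc in index:
            attrs = f'{locus_key} "{loc.locus_id}"; {subfamily_key} "{loc.subfamily}";'
            if loc.te_class is not None:
                attrs += f' {class_key} "{loc.te_class}";'
            fh.write(
                "\t".join(
                    [
                        loc.chrom,
                        source,
                        feature,
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        loc.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
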