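"""Synthetic study system: toy TE genome, reads, priors and evaluation.

Generates, at desk scale and without any external download, the three
inputs the quantifier consumes plus the ground truth needed to score it:

* a toy genome in which each TE subfamily is a random consensus whose
  copies are independently mutated at a configurable per-base substitution
  rate (no indels, so copies stay length-matched and coordinates trivial);
  a configurable number of copy pairs are exact duplicates, emulating the
  zero-divergence young TE copies that cause irreducible multi-mapping in
  real genomes;
* a sparse ground-truth expression profile (a fraction of loci silent,
  expressed loci log-normal) normalized to TPM;
* paired-end fragments drawn proportional to truth TPM x locus length,
  with a matched "long-read" per-locus table derived from the same truth
  (optionally binomially thinned to emulate shallow long-read depth);
* a self-contained aligner stand-in that scores each fragment against all
  copies of its subfamily and writes ordinary SAM records, so the whole
  pipeline can run without an external aligner;
* confusion-matrix scoring of an estimated count table against the truth.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationIndex, TELocus, write_te_gtf
from .fragments import FragmentMatrix
from .reassign import CountTable

__all__ = [
    "SimConfig",
    "SimFragment",
    "SyntheticTruth",
    "make_te_genome",
    "simulate_fragments",
    "synthetic_align",
    "write_bundle",
    "coverage_scale_ratio",
    "ConfusionResult",
    "evaluate_confusion",
    "make_mixture_matrix",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclasses.dataclass
class SimConfig:
    """Simulation parameters; the defaults define the benchmark conditions.

    ``within_subfamily_divergence`` is the per-base substitution fraction
    applied independently to each copy (valid range [0, 0.5)).
    ``identical_pairs`` exact-duplicate copy pairs are planted (cycling
    over subfamilies) to reproduce the zero-divergence duplicates found in
    young TE subfamilies; the second member of each pair is forced silent,
    matching the epigenetic silencing of recent duplicates and creating
    the irreducible multi-mapping case the prior is meant to resolve.
    ``silent_fraction`` of loci get truth TPM 0 (forced-silent duplicates
    count toward the quota; the remainder is drawn uniformly from
    non-duplicate loci).  ``score_range`` controls which copies the
    aligner stand-in reports: a copy is a candidate when its pair-level
    alignment score is within ``score_range`` of the best, mirroring the
    multi-mapping score window of spliced short-read aligners.
    ``longread_noise`` > 0 binomially thins the matched long-read table to
    emulate shallow or unmatched long-read samples.
    """

    n_subfamilies: int = 2
    copies_per_subfamily: int = 5
    consensus_length: int = 1000
    within_subfamily_divergence: float = 0.02
    read_length: int = 76
    fragment_size: int = 200
    total_fragments: int = 5000
    silent_fraction: float = 0.2
    identical_pairs: int = 1
    spacer_length: int = 300
    expression_sigma: float = 1.0
    longread_noise: float = 0.0
    score_range: float = 6.0
    chrom: str = "chrS"
    seed: int = 42

    def validate(self) -> None:
        if not (0 <= self.within_subfamily_divergence < 0.5):
            raise ValueError(
                "within_subfamily_divergence must be in [0, 0.5), got "
                f"{self.within_subfamily_divergence}"
            )
        if not (self.read_length <= self.fragment_size <= self.consensus_length):
            raise ValueError(
                "need read_length <= fragment_size <= consensus_length, got "
                f"{self.read_length}/{self.fragment_size}/{self.consensus_length}"
            )
        if self.n_subfamilies < 1 or self.copies_per_subfamily < 1:
            raise ValueError("need at least one subfamily with one copy")
        if not (0 <= self.silent_fraction < 1):
            raise ValueError("silent_fraction must be in [0, 1)")
        if not (0 <= self.longread_noise < 1):
            raise ValueError("longread_noise must be in [0, 1)")
        if self.identical_pairs > 0 and self.copies_per_subfamily < 2:
            logger.info("identical_pairs ignored: subfamilies have a single copy")

    @property
    def n_loci(self) -> int:
        return self.n_subfamilies * self.copies_per_subfamily


@dataclasses.dataclass
class SimFragment:
    """One simulated sequenced template, anchored on the genome."""

    name: str
    origin: int  # locus position in the annotation index
    start: int  # genomic start of the fragment


@dataclasses.dataclass
class SyntheticTruth:
    """Genome, annotation and ground truth of one simulated experiment."""

    genome: dict[str, str]
    index: AnnotationIndex
    truth_tpm: np.ndarray
    consensus: list[str]
    config: SimConfig
    fragments: list[SimFragment] = dataclasses.field(default_factory=list)
    longread: pd.DataFrame | None = None

    def _genome_bytes(self, chrom: str) -> np.ndarray:
        return np.frombuffer(self.genome[chrom].encode(), dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a new base)."""
    out = seq.copy()
    if rate <= 0:
        return out
    mask = rng.random(seq.size) < rate
    if mask.any():
        idx = np.searchsorted(_BASES, seq[mask])
        shift = rng.integers(1, 4, size=int(mask.sum()))
        out[mask] = _BASES[(idx + shift) % 4]
    return out


def make_te_genome(config: SimConfig) -> SyntheticTruth:
    """Build the toy genome, its annotation and the truth expression profile.

    Each subfamily gets an independent random consensus; copies are
    mutated at the divergence rate and laid on a single synthetic
    chromosome separated by random spacers.  Exact-duplicate pairs copy
    the sequence of the subfamily's first copy onto its second; the
    duplicate is forced silent in the truth profile.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    consensus = [
        _random_seq(rng, config.consensus_length) for _ in range(config.n_subfamilies)
    ]
    copies: list[list[np.ndarray]] = [
        [
            _mutate(consensus[sf], config.within_subfamily_divergence, rng)
            for _ in range(config.copies_per_subfamily)
        ]
        for sf in range(config.n_subfamilies)
    ]
    duplicate_pairs: list[tuple[int, int]] = []  # (expressed member, silent member)
    if config.copies_per_subfamily >= 2:
        for p in range(config.identical_pairs):
            sf = p % config.n_subfamilies
            copies[sf][1] = copies[sf][0].copy()
            base = sf * config.copies_per_subfamily
            duplicate_pairs.append((base, base + 1))

    parts: list[np.ndarray] = []
    loci: list[TELocus] = []
    pos = 0
    for sf in range(config.n_subfamilies):
        subfamily = f"SF{sf + 1}"
        for c, seq in enumerate(copies[sf]):
            spacer = _random_seq(rng, config.spacer_length)
            parts.append(spacer)
            pos += spacer.size
            loci.append(
                TELocus(
                    locus_id=f"{subfamily}_c{c + 1}",
                    chrom=config.chrom,
                    start=pos,
                    end=pos + seq.size,
                    strand="+",
                    subfamily=subfamily,
                )
            )
            parts.append(seq)
            pos += seq.size
    parts.append(_random_seq(rng, config.spacer_length))
    chrom_seq = b"".join(p.tobytes() for p in parts).decode()
    index = AnnotationIndex(loci)

    K = index.K
    n_silent = int(round(K * config.silent_fraction))
    forced = [s for _, s in duplicate_pairs][:n_silent]
    protected = {p for pair in duplicate_pairs for p in pair}
    pool = np.array([i for i in range(K) if i not in protected], dtype=int)
    n_extra = min(max(n_silent - len(forced), 0), pool.size)
    extra = rng.choice(pool, size=n_extra, replace=False) if n_extra else np.array([], int)
    silent = np.concatenate([np.array(forced, dtype=int), extra])
    tpm = np.exp(rng.normal(0.0, config.expression_sigma, size=K))
    tpm[silent.astype(int)] = 0.0
    if tpm.sum() == 0:
        raise ValueError("all loci silent; nothing to simulate")
    tpm = 1e6 * tpm / tpm.sum()
    return SyntheticTruth(
        genome={config.chrom: chrom_seq},
        index=index,
        truth_tpm=tpm,
        consensus=[c.tobytes().decode() for c in consensus],
        config=config,
    )


def simulate_fragments(truth: SyntheticTruth, config: SimConfig | None = None) -> SyntheticTruth:
    """Draw paired-end fragments from the truth profile.

    Per-locus fragment counts are multinomial with probability proportional
    to truth TPM x locus length; fragment starts are uniform within the
    locus.  Also attaches the matched long-read table (TPM equal to the
    truth, or binomially thinned counts when ``longread_noise`` > 0).
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    lengths = truth.index.lengths()
    weights = truth.truth_tpm * lengths
    too_short = lengths < config.fragment_size
    if too_short.any():
        names = [truth.index.loci[i].locus_id for i in np.flatnonzero(too_short)]
        logger.warning("skipping loci shorter than the fragment size: %s", names)
        weights = np.where(too_short, 0.0, weights)
    p = weights / weights.sum()
    counts = rng.multinomial(config.total_fragments, p)
    fragments: list[SimFragment] = []
    n = 0
    for i, cnt in enumerate(counts):
        if cnt == 0:
            continue
        loc = truth.index.loci[i]
        starts = loc.start + rng.integers(
            0, loc.length - config.fragment_size + 1, size=cnt
        )
        for s in np.sort(starts):
            fragments.append(SimFragment(name=f"frag{n:06d}", origin=i, start=int(s)))
            n += 1
    truth.fragments = fragments

    if config.longread_noise > 0:
        keep = 1.0 - config.longread_noise
        base = np.round(truth.truth_tpm).astype(np.int64)
        thinned = rng.binomial(base, keep)
        truth.longread = pd.DataFrame(
            {"locus_id": truth.index.locus_ids(), "count": thinned}
        )
    else:
        truth.longread = pd.DataFrame(
            {"locus_id": truth.index.locus_ids(), "tpm": truth.truth_tpm}
        )
    return truth


def _fragment_reads(truth: SyntheticTruth, frag: SimFragment) -> tuple[str, str]:
    """(R1, R2) raw read sequences; R2 is the reverse complement of the 3' end."""
    cfg = truth.config
    seq = truth.genome[cfg.chrom][frag.start : frag.start + cfg.fragment_size]
    r1 = seq[: cfg.read_length]
    r2 = str(Seq(seq[cfg.fragment_size - cfg.read_length :]).reverse_complement())
    return r1, r2


def write_fastq(truth: SyntheticTruth, r1_path: str | Path, r2_path: str | Path) -> None:
    """Write the simulated pairs as two FASTQ files (uniform top quality)."""
    qual = [40] * truth.config.read_length

    def _records(mate: int):
        for frag in truth.fragments:
            r1, r2 = _fragment_reads(truth, frag)
            rec = SeqRecord(
                Seq(r1 if mate == 1 else r2),
                id=f"{frag.name}/{mate}",
                description="",
            )
            rec.letter_annotations["phred_quality"] = qual
            yield rec

    SeqIO.write(_records(1), str(r1_path), "fastq")
    SeqIO.write(_records(2), str(r2_path), "fastq")


def write_fasta(truth: SyntheticTruth, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in truth.genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def synthetic_align(truth: SyntheticTruth, out_sam: str | Path) -> Path:
    """Score each fragment against all copies of its subfamily; write SAM.

    Because copies are substitution-only mutants of a shared consensus,
    the fragment's window maps at the same offset in every copy; the score
    is matched bases minus mismatches per read (AS tag).  A copy becomes a
    candidate when its pair-level score is within ``score_range`` of the
    best candidate's, the way short-read aligners only report multi-hits
    inside a score window; the true origin is always emitted (as the
    primary alignment), so the candidate set is guaranteed to contain it.
    """
    cfg = truth.config
    genome = truth._genome_bytes(cfg.chrom)
    rl, fs = cfg.read_length, cfg.fragment_size
    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": cfg.chrom, "LN": len(genome)}],
    }
    members_by_subfam = {
        sf: sorted(truth.index.position(m) for m in members)
        for sf, members in truth.index.subfamily_members.items()
    }
    out_sam = Path(out_sam)
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
        for frag in truth.fragments:
            origin = truth.index.loci[frag.origin]
            offset = frag.start - origin.start
            w1 = genome[frag.start : frag.start + rl]
            w2 = genome[frag.start + fs - rl : frag.start + fs]
            scored = []
            for pos in members_by_subfam[origin.subfamily]:
                cand = truth.index.loci[pos]
                cstart = cand.start + offset
                m1 = int((genome[cstart : cstart + rl] != w1).sum())
                m2 = int((genome[cstart + fs - rl : cstart + fs] != w2).sum())
                scored.append((pos, cstart, m1, m2, 2 * rl - 2 * (m1 + m2)))
            best = max(s for *_, s in scored)
            candidates = [
                (pos, cstart, m1, m2)
                for pos, cstart, m1, m2, s in scored
                if pos == frag.origin or s >= best - cfg.score_range
            ]
            for pos, cstart, m1, m2 in candidates:
                secondary = pos != frag.origin
                for mate, (mm, rstart) in enumerate(
                    [(m1, cstart), (m2, cstart + fs - rl)]
                ):
                    rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                    rec.query_name = frag.name
                    rec.flag = (
                        0x1
                        | 0x2
                        | (0x20 | 0x40 if mate == 0 else 0x10 | 0x80)
                        | (0x100 if secondary else 0)
                    )
                    rec.reference_id = 0
                    rec.reference_start = rstart
                    rec.mapping_quality = 0 if len(candidates) > 1 else 60
                    rec.cigartuples = [(0, rl)]
                    rec.next_reference_id = 0
                    rec.next_reference_start = cstart if mate == 1 else cstart + fs - rl
                    rec.template_length = fs if mate == 0 else -fs
                    rec.query_sequence = genome[rstart : rstart + rl].tobytes().decode()
                    rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    rec.set_tag("AS", rl - 2 * mm)
                    rec.set_tag("NM", mm)
                    fh.write(rec)
    return out_sam


def write_bundle(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the complete synthetic bundle under one directory.

    Writes genome FASTA, TE GTF, paired FASTQ, SAM alignments, the
    long-read table and the truth table; deterministic per seed.  Returns
    the paths keyed by role.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_fragments(make_te_genome(config))
    paths = {
        "genome": out_dir / "genome.fa",
        "gtf": out_dir / "tes.gtf",
        "r1": out_dir / "reads_R1.fastq",
        "r2": out_dir / "reads_R2.fastq",
        "sam": out_dir / "alignments.sam",
        "longread": out_dir / "longread.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(truth, paths["genome"])
    write_te_gtf(truth.index, paths["gtf"])
    write_fastq(truth, paths["r1"], paths["r2"])
    synthetic_align(truth, paths["sam"])
    truth.longread.to_csv(paths["longread"], sep="\t", index=False)
    pd.DataFrame(
        {
            "locus_id": truth.index.locus_ids(),
            "subfamily": truth.index.subfamilies(),
            "length": truth.index.lengths().astype(int),
            "tpm": truth.truth_tpm,
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    logger.info(
        "wrote synthetic bundle to %s (%d loci, %d fragments)",
        out_dir,
        truth.index.K,
        len(truth.fragments),
    )
    return paths


def coverage_scale_ratio(bases_long: int, bases_short: int) -> int:
    """Integer multiplier matching simulated short-read depth to long-read depth.

    ``floor(mapped bases in the long-read library / mapped bases in the
    simulated short-read library)``; the multiplier is applied to the
    long-read TPM coverage before re-simulation.
    """
    if bases_short <= 0:
        raise ValueError("bases_short must be > 0")
    if bases_long < 0:
        raise ValueError("bases_long must be >= 0")
    return int(bases_long // bases_short)


@dataclasses.dataclass
class ConfusionResult:
    """Locus-level detection confusion matrix with derived metrics.

    ``degenerate`` flags precision (or recall) reported as 0 because its
    denominator was empty.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def evaluate_confusion(
    estimated,
    truth,
    include_mask=None,
    threshold: float = 0.0,
    estimated_ids: list[str] | None = None,
    truth_ids: list[str] | None = None,
) -> ConfusionResult:
    """Score expressed-locus detection of an estimate against the truth.

    A locus is called expressed on each side when its value exceeds
    ``threshold``.  ``include_mask`` restricts scoring to a subset of loci
    (e.g. loci captured by at least one approach).  ``estimated`` may be a
    :class:`~telocus.reassign.CountTable` (its TPM-bearing final counts are
    used) or a plain per-locus array aligned with ``truth``.
    """
    if isinstance(estimated, CountTable):
        estimated_ids = estimated.locus_ids
        estimated = estimated.final_count
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if estimated_ids is not None and truth_ids is not None:
        if list(estimated_ids) != list(truth_ids):
            bad = sorted(set(estimated_ids) ^ set(truth_ids)) or ["(order differs)"]
            raise ValueError(f"locus universes differ: {bad}")
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: estimate {est.shape} vs truth {tru.shape}")
    if include_mask is not None:
        mask = np.asarray(include_mask, dtype=bool)
        est, tru = est[mask], tru[mask]
    called = est > threshold
    actual = tru > threshold
    tp = int(np.sum(called & actual))
    tn = int(np.sum(~called & ~actual))
    fp = int(np.sum(called & ~actual))
    fn = int(np.sum(~called & actual))
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return ConfusionResult(tp, tn, fp, fn, precision, recall, f1, degenerate)


def make_mixture_matrix(
    proportions,
    n_fragments: int,
    ambiguous_fraction: float = 0.3,
    mean_cross_mismatches: float = 6.0,
    lam: float = 0.1,
    seed: int = 0,
) -> FragmentMatrix:
    """Small parameter-recovery testbed: a K-locus fragment mixture.

    Fragment origins are drawn from ``proportions``.  A fragment is
    multi-mapped with probability ``ambiguous_fraction``, in which case
    every locus is a candidate: the origin scores 0 and each other locus
    scores ``-2 m`` with ``m ~ 1 + Poisson(mean_cross_mismatches - 1)``,
    mirroring the per-candidate mismatch penalty of the aligner stand-in
    at the default simulated divergence.
    """
    p = np.asarray(proportions, dtype=float)
    if p.min() < 0 or p.sum() <= 0:
        raise ValueError("proportions must be non-negative with positive sum")
    p = p / p.sum()
    K = p.size
    rng = np.random.default_rng(seed)
    origins = rng.choice(K, size=n_fragments, p=p)
    ambiguous = rng.random(n_fragments) < ambiguous_fraction
    candidates: dict[str, dict[int, float]] = {}
    for a in range(n_fragments):
        name = f"m{a:06d}"
        if ambiguous[a] and K > 1:
            row = {}
            for i in range(K):
                if i == origins[a]:
                    row[i] = 0.0
                else:
                    m = 1 + rng.poisson(max(mean_cross_mismatches - 1, 0.0))
                    row[i] = -2.0 * m
            candidates[name] = row
        else:
            candidates[name] = {int(origins[a]): 0.0}
    return FragmentMatrix.from_candidates(candidates, K, lam=lam)
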