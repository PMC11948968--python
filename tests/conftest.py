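"""Shared fixtures: toy annotations, a hand-written SAM, the default bundle."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import telocus as tlc

SAM_HEADER = "@HD\tVN:1.6\tSO:queryname\n@SQ\tSN:chr1\tLN:10000\n"


def make_sam(path, lines):
    """Write a SAM file from pre-formatted alignment lines."""
    path.write_text(SAM_HEADER + "".join(line + "\n" for line in lines))
    return path


def sam_line(qname, flag, pos, score, seq="A" * 20, rnext=0, tlen=0, mapq=0):
    """One SAM record on chr1 with a 20M cigar and an AS tag (1-based pos)."""
    return "\t".join(
        [
            qname,
            str(flag),
            "chr1",
            str(pos),
            str(mapq),
            f"{len(seq)}M",
            "=",
            str(rnext or pos),
            str(tlen),
            seq,
            "I" * len(seq),
            f"AS:i:{score}",
        ]
    )


@pytest.fixture
def toy_index():
    """Three loci, two subfamilies, on one chromosome."""
    return tlc.AnnotationIndex(
        [
            tlc.TELocus("A", "chr1", 100, 300, "+", "AluY"),
            tlc.TELocus("B", "chr1", 500, 700, "+", "AluY"),
            tlc.TELocus("C", "chr1", 900, 1100, "-", "L1HS"),
        ]
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default simulated experiment, quantified with and without the prior.

    One full bundle (2 subfamilies x 5 copies, 1 kb consensus, 2% within-
    subfamily divergence, one exact-duplicate pair with a silenced member,
    20% silent loci, 5,000 paired 76-bp fragments, seed 42), ingested from
    its on-disk files, with EM run at weight 1 (truth-derived prior) and at
    weight 0 (no long-read information).
    """
    cfg = tlc.SimConfig()
    out = tmp_path_factory.mktemp("bundle")
    paths = tlc.write_bundle(cfg, out)
    index = tlc.parse_te_gtf(paths["gtf"])
    matrix = tlc.ingest_alignments(paths["sam"], index)
    prior = tlc.build_prior(tlc.load_longread_table(paths["longread"]), index)
    zero_prior = tlc.build_prior(None, index)
    truth = (
        pd.read_csv(paths["truth"], sep="\t").set_index("locus_id").loc[index.locus_ids()]
    )
    state_w1 = tlc.run_em(matrix, prior, tlc.EMParams(long_read_weight=1.0))
    state_w0 = tlc.run_em(matrix, zero_prior, tlc.EMParams(long_read_weight=0.0))
    return SimpleNamespace(
        cfg=cfg,
        paths=paths,
        index=index,
        matrix=matrix,
        prior=prior,
        zero_prior=zero_prior,
        truth_tpm=truth["tpm"].to_numpy(),
        state_w1=state_w1,
        state_w0=state_w0,
    )


def report_tpm(state, bundle, prior, seed=1):
    """Run reassignment + TPM report; return per-locus TPM in index order."""
    table = tlc.final_counts(
        state, bundle.matrix, prior, mode="long_read", seed=seed, index=bundle.index
    )
    rep = tlc.counts_to_report(table, bundle.index)
    return rep.set_index("locus_id").loc[bundle.index.locus_ids()]["tpm"].to_numpy()
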