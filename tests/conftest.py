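"""Shared fixtures: session-scoped synthetic genomes reused across modules."""

from __future__ import annotations

import pytest

from heterokit import invphylo, methdip, satarch, synthio


@pytest.fixture(scope="session")
def genome_bundle():
    """Default-architecture diploid genome: caps, bimodal centromeres, rDNA,
    one gap per haplotype, methylation with truth CDRs and spacer pockets."""
    cfg = synthio.SimConfig(n_chromosomes=2, seed=1)
    sequences, truth = synthio.generate_assembly(cfg, seed=1)
    synthio.place_truth_cdrs(truth, cfg, seed=1)
    track = synthio.generate_methylation(sequences, truth, cfg, seed=1)
    merged = satarch.merge_to_arrays(truth.satellites, max_gap_bp=50_000)
    arrays = satarch.classify_arrays(merged, truth.chrom_lengths)
    return dict(config=cfg, sequences=sequences, truth=truth, track=track,
                arrays=arrays)


@pytest.fixture(scope="session")
def cdr_sim():
    """Forty centromere-only chromosomes for CDR parameter recovery:
    truth CDR length = 0.3 * array length + noise."""
    cfg = synthio.SimConfig(
        n_chromosomes=40,
        chrom_length_bp=1_600_000,
        haplotypes=("hap1",),
        cap=synthio.CapConfig(p_arm=False, q_arm=False),
        rdna=synthio.RdnaConfig(copies=0, n_rdna_chromosomes=0),
        gaps=synthio.GapConfig(n_gaps=0),
        centromere=synthio.CentromereConfig(
            distribution="unimodal",
            mean_large_bp=500_000, sd_large_bp=150_000,
            min_bp=150_000, max_bp=1_000_000,
        ),
        seed=7,
    )
    sequences, truth = synthio.generate_assembly(cfg, seed=7)
    synthio.place_truth_cdrs(truth, cfg, seed=7)
    track = synthio.generate_methylation(sequences, truth, cfg, seed=7)
    merged = satarch.merge_to_arrays(truth.satellites)
    arrays = satarch.classify_arrays(merged, truth.chrom_lengths,
                                     end_window_bp=2_000)
    cdrs = methdip.call_cdrs_all(track, arrays)
    return dict(config=cfg, truth=truth, track=track, arrays=arrays, cdrs=cdrs)


@pytest.fixture(scope="session")
def ape_tree():
    return invphylo.default_ape_tree()
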