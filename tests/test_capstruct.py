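"""Subterminal cap decomposition, spacer statistics and methylation pocket."""

import math

import numpy as np
import pandas as pd
import pytest

from heterokit import capstruct, methdip, satarch, synthio


def _ann(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


class TestDetectCaps:
    def test_no_subterminal_arrays_no_caps(self):
        arrays = pd.DataFrame([dict(chrom="chr1", start=4_000_000, end=6_000_000,
                                    family="alphasat_HOR", n_members=1,
                                    covered_bp=2_000_000, cls="centromeric_hor",
                                    arm="unknown")])
        caps = capstruct.detect_caps(arrays, {"chr1": 10_000_000})
        assert caps.empty

    def test_caps_on_both_arms(self):
        cfg = synthio.SimConfig(
            n_chromosomes=1, chrom_length_bp=8_000_000, haplotypes=("hap1",),
            cap=synthio.CapConfig(p_arm=True, q_arm=True, cap_length_bp=1_500_000,
                                  tract_mean_bp=150_000, tract_sd_bp=20_000),
            centromere=synthio.CentromereConfig(
                distribution="unimodal", mean_large_bp=300_000,
                sd_large_bp=50_000, min_bp=150_000, max_bp=500_000),
            rdna=synthio.RdnaConfig(copies=0, n_rdna_chromosomes=0),
            gaps=synthio.GapConfig(n_gaps=0),
            seed=6,
        )
        _, truth = synthio.generate_assembly(cfg, seed=6)
        arrays = satarch.classify_arrays(
            satarch.merge_to_arrays(truth.satellites, max_gap_bp=50_000),
            truth.chrom_lengths, end_window_bp=1_700_000,
        )
        caps = capstruct.detect_caps(arrays, truth.chrom_lengths,
                                     end_window_bp=1_700_000)
        assert list(caps["arm"]) == ["p", "q"]
        want = set(zip(truth.caps["start"], truth.caps["end"]))
        got = set(zip(caps["start"], caps["end"]))
        assert got == want

    def test_cap_span_matches_truth(self, genome_bundle):
        truth, arrays = genome_bundle["truth"], genome_bundle["arrays"]
        caps = capstruct.detect_caps(arrays, truth.chrom_lengths)
        want = set(zip(truth.caps["chrom"], truth.caps["start"],
                       truth.caps["end"]))
        got = set(zip(caps["chrom"], caps["start"], caps["end"]))
        assert got == want


class TestFindSpacers:
    def test_fully_covered_cap_has_no_spacers(self):
        ann = _ann([("chr1", 0, 2_000_000, "pCht")])
        spacers, modal = capstruct.find_spacers(("chr1", 0, 2_000_000), ann)
        assert spacers.empty and modal is None

    def test_majority_bin_wins(self):
        rows, pos = [], 0
        for gap in [32_000, 32_000, 57_000]:
            rows.append(("chr1", pos, pos + 300_000, "pCht"))
            pos += 300_000 + gap
        rows.append(("chr1", pos, pos + 300_000, "pCht"))
        spacers, modal = capstruct.find_spacers(("chr1", 0, pos + 300_000),
                                                _ann(rows))
        assert len(spacers) == 3
        assert modal == 32_000

    def test_tie_breaks_toward_smaller_bin(self):
        rows, pos = [], 0
        for gap in [32_000, 57_000]:
            rows.append(("chr1", pos, pos + 300_000, "pCht"))
            pos += 300_000 + gap
        rows.append(("chr1", pos, pos + 300_000, "pCht"))
        _, modal = capstruct.find_spacers(("chr1", 0, pos + 300_000), _ann(rows))
        assert modal == 32_000

    def test_length_filter_excludes_extremes(self):
        rows, pos = [], 0
        for gap in [2_000, 34_000, 500_000]:
            rows.append(("chr1", pos, pos + 300_000, "pCht"))
            pos += 300_000 + gap
        rows.append(("chr1", pos, pos + 300_000, "pCht"))
        spacers, modal = capstruct.find_spacers(("chr1", 0, pos + 300_000),
                                                _ann(rows))
        assert len(spacers) == 1
        assert modal == 34_000

    def test_truth_spacers_recovered_with_exact_modal_length(self, genome_bundle):
        truth, arrays = genome_bundle["truth"], genome_bundle["arrays"]
        caps = capstruct.detect_caps(arrays, truth.chrom_lengths)
        for _, cap in caps.iterrows():
            cs = capstruct.build_cap_structure(cap, truth.satellites)
            assert cs.modal_spacer_bp == 34_000
            want = truth.spacers[truth.spacers["chrom"] == cap["chrom"]]
            got = set(zip(cs.spacers["start"], cs.spacers["end"]))
            assert got == set(zip(want["start"], want["end"]))

    def test_cap_bookkeeping_is_exact(self, genome_bundle):
        truth, arrays = genome_bundle["truth"], genome_bundle["arrays"]
        caps = capstruct.detect_caps(arrays, truth.chrom_lengths)
        cs = capstruct.build_cap_structure(caps.iloc[0], truth.satellites)
        book = cs.bookkeeping()
        assert book["tract_bp"] + book["spacer_bp"] + book["margin_bp"] == cs.length
        assert book["margin_bp"] == 0  # caps begin and end with satellite


class TestTractStats:
    def test_single_tract_spacing_missing(self):
        cs = capstruct.CapStructure(chrom="chr1", start=0, end=500_000,
                                    arm="p", tracts=[(0, 500_000)],
                                    spacers=pd.DataFrame())
        mean_len, sd, spacing = capstruct.tract_stats(cs)
        assert mean_len == 500_000
        assert math.isnan(sd) and math.isnan(spacing)

    def test_no_tracts_rejected(self):
        cs = capstruct.CapStructure(chrom="chr1", start=0, end=1, arm="p")
        with pytest.raises(ValueError):
            capstruct.tract_stats(cs)

    def test_tract_mean_recovered_within_sampling_error(self):
        cfg = synthio.SimConfig(
            n_chromosomes=1, chrom_length_bp=14_000_000, haplotypes=("hap1",),
            cap=synthio.CapConfig(tract_mean_bp=500_000, tract_sd_bp=50_000,
                                  spacer_bp=34_000, n_tracts=20),
            centromere=synthio.CentromereConfig(
                distribution="unimodal", mean_large_bp=300_000,
                sd_large_bp=50_000, min_bp=150_000, max_bp=500_000),
            rdna=synthio.RdnaConfig(copies=0, n_rdna_chromosomes=0),
            gaps=synthio.GapConfig(n_gaps=0),
            seed=2,
        )
        _, truth = synthio.generate_assembly(cfg, seed=2)
        cap = truth.caps.iloc[0]
        cs = capstruct.build_cap_structure(cap, truth.satellites)
        assert len(cs.tracts) == 20
        mean_len, _, _ = capstruct.tract_stats(cs)
        bound = 2 * 50_000 / np.sqrt(20)
        assert abs(mean_len - 500_000) <= bound

    def test_periodicity_recovered_within_5_percent(self):
        cfg = synthio.SimConfig(
            n_chromosomes=1, chrom_length_bp=8_000_000, haplotypes=("hap1",),
            cap=synthio.CapConfig(spacer_bp=57_000, spacer_period_bp=750_000,
                                  n_tracts=8),
            centromere=synthio.CentromereConfig(
                distribution="unimodal", mean_large_bp=200_000,
                sd_large_bp=30_000, min_bp=100_000, max_bp=300_000),
            rdna=synthio.RdnaConfig(copies=0, n_rdna_chromosomes=0),
            gaps=synthio.GapConfig(n_gaps=0),
            seed=3,
        )
        _, truth = synthio.generate_assembly(cfg, seed=3)
        cs = capstruct.build_cap_structure(truth.caps.iloc[0], truth.satellites)
        _, _, spacing = capstruct.tract_stats(cs)
        assert abs(spacing - 750_000) / 750_000 <= 0.05


class TestSpacerMethylationProfile:
    def _spacers(self, mids, half=17_000, chrom="chr1"):
        return pd.DataFrame([
            dict(chrom=chrom, start=m - half, end=m + half, midpoint=m,
                 left_tract=i, right_tract=i + 1)
            for i, m in enumerate(mids)
        ])

    def _track(self, end, fraction_fn, spacing=40):
        pos = np.arange(0, end, spacing)
        frac = np.array([fraction_fn(p) for p in pos], dtype=float)
        df = pd.DataFrame(dict(chrom="chr1", start=pos, end=pos + 1,
                               coverage=30, fraction=frac))
        return methdip.MethylationTrack(df)

    def test_uniform_methylation_gives_null_pocket(self):
        spacers = self._spacers([200_000, 600_000, 1_000_000])
        track = self._track(1_200_000, lambda p: 0.9)
        profile, pocket = capstruct.spacer_methylation_profile(spacers, track)
        assert pocket["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert 0.3 <= pocket["p_value"] <= 0.7
        defined = profile.dropna(subset=["mean"])
        assert np.allclose(defined["mean"], 0.9)

    def test_hypomethylated_spacers_give_strong_negative_pocket(self):
        spacers = self._spacers([200_000, 600_000, 1_000_000])
        ivs = list(zip(spacers["start"], spacers["end"]))

        def frac(p):
            return 0.1 if any(s <= p < e for s, e in ivs) else 0.9

        track = self._track(1_200_000, frac)
        _, pocket = capstruct.spacer_methylation_profile(spacers, track)
        assert pocket["statistic"] == pytest.approx(-0.8, abs=0.01)
        assert pocket["p_value"] < 0.001

    def test_single_spacer_sd_missing_mean_defined(self):
        spacers = self._spacers([200_000])
        track = self._track(400_000, lambda p: 0.9)
        profile, _ = capstruct.spacer_methylation_profile(spacers, track)
        defined = profile.dropna(subset=["mean"])
        assert not defined.empty
        assert profile["sd"].isna().all()

    def test_no_cpgs_anywhere_rejected(self):
        spacers = self._spacers([200_000])
        empty = methdip.MethylationTrack(pd.DataFrame(
            columns=["chrom", "start", "end", "coverage", "fraction"]))
        with pytest.raises(ValueError):
            capstruct.spacer_methylation_profile(spacers, empty)

    def test_profile_mirror_symmetric_for_symmetric_placement(self, genome_bundle):
        truth, track = genome_bundle["truth"], genome_bundle["track"]
        spacers = truth.spacers.copy()
        spacers["midpoint"] = (spacers["start"] + spacers["end"]) // 2
        profile, pocket = capstruct.spacer_methylation_profile(spacers, track)
        means = profile["mean"].to_numpy()
        asym = np.nanmean(np.abs(means - means[::-1]))
        assert asym < 0.1
        assert pocket["statistic"] < -0.5
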