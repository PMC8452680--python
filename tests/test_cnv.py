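"""Copy-number pipeline: binning, ratios, segmentation, calling,
breakpoint counting."""

import numpy as np
import pandas as pd
import pytest

from rigmeth import cnv
from rigmeth.config import PipelineConfig


def manifest_from_positions(positions: dict) -> pd.DataFrame:
    """positions: chrom -> list of 1-based probe positions."""
    rows = []
    for chrom, ps in positions.items():
        for i, p in enumerate(ps):
            rows.append((f"{chrom}_{i:04d}", chrom, p))
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
    df = df.set_index("probe_id")
    df["on_450k"] = df["on_epic"] = True
    df["snp_proximal"] = df["multi_mapping"] = False
    df["control_type"] = "none"
    df["channel"] = ""
    return df


def bins_from_log2(values_per_chrom: dict) -> tuple[pd.DataFrame, pd.Series]:
    """Build a synthetic bin table + log2 series directly (unit fixture)."""
    rows, vals = [], {}
    for chrom, values in values_per_chrom.items():
        for i, v in enumerate(values):
            bid = f"{chrom}:{i * 100}-{(i + 1) * 100}"
            rows.append((bid, chrom, i * 100, (i + 1) * 100, 10))
            vals[bid] = v
    bins = pd.DataFrame(rows, columns=["bin", "chrom", "start", "end",
                                       "n_probes"]).set_index("bin")
    bins["probes"] = [[] for _ in range(len(bins))]
    return bins, pd.Series(vals)


class TestTotalIntensity:
    def test_sums_channels(self):
        from rigmeth.synth import IntensityData
        m = pd.DataFrame([[500.0, 0.0]], index=["s"], columns=["a", "b"])
        u = pd.DataFrame([[500.0, 0.0]], index=["s"], columns=["a", "b"])
        meta = pd.DataFrame({"material": "frozen", "array": "450k"}, index=["s"])
        tot = cnv.total_intensity(IntensityData(m, u, pd.DataFrame(), meta))
        assert tot.loc["s", "a"] == 1000.0 and tot.loc["s", "b"] == 0.0


class TestBinGenome:
    def test_dense_probes_give_fixed_width_bins(self):
        positions = {"1": list(range(50, 10_000, 50))}
        manifest = manifest_from_positions(positions)
        bins = cnv.bin_genome(manifest, manifest.index, bin_width=1000,
                              min_probes=5, chrom_lengths={"1": 10_000})
        assert len(bins) == 10
        assert (bins["n_probes"] >= 5).all()
        assert bins["start"].tolist() == list(range(0, 10_000, 1000))

    def test_sparse_region_forces_merges(self):
        # probes only in [0,1000) and [5000,6000): middle bins merge
        positions = {"1": list(range(10, 1000, 10)) + list(range(5000, 6000, 10))}
        manifest = manifest_from_positions(positions)
        bins = cnv.bin_genome(manifest, manifest.index, bin_width=1000,
                              min_probes=5, chrom_lengths={"1": 10_000})
        assert (bins["n_probes"] >= 5).all()
        # bins tile the chromosome contiguously
        assert bins["start"].iloc[0] == 0
        assert (bins["end"].iloc[:-1].to_numpy()
                == bins["start"].iloc[1:].to_numpy()).all()

    def test_greedy_merge_matches_hand_enumeration(self):
        # 4 nominal bins of width 100 with probe counts 3, 1, 4, 2 and
        # min_probes 4: greedy left-to-right closes [0,200) (3+1) then
        # [200,300) (4); trailing deficient [300,400) merges backwards
        positions = {"1": [10, 20, 30, 110, 210, 220, 230, 240, 310, 320]}
        manifest = manifest_from_positions(positions)
        bins = cnv.bin_genome(manifest, manifest.index, bin_width=100,
                              min_probes=4, chrom_lengths={"1": 400})
        assert [(r.start, r.end, r.n_probes) for r in bins.itertuples()] == \
            [(0, 200, 4), (200, 400, 6)]

    def test_underpopulated_chromosome_dropped(self, caplog):
        positions = {"1": list(range(100, 5000, 100)), "2": [10, 20]}
        manifest = manifest_from_positions(positions)
        with caplog.at_level("WARNING", logger="rigmeth.cnv"):
            bins = cnv.bin_genome(manifest, manifest.index, bin_width=1000,
                                  min_probes=5, chrom_lengths={"1": 5000,
                                                               "2": 5000})
        assert set(bins["chrom"]) == {"1"}
        assert "dropped" in caplog.text

    def test_xy_excluded(self):
        positions = {"1": list(range(100, 2000, 100)),
                     "X": list(range(100, 2000, 100))}
        manifest = manifest_from_positions(positions)
        bins = cnv.bin_genome(manifest, manifest.index, bin_width=1000,
                              min_probes=5, chrom_lengths={"1": 2000, "X": 2000})
        assert set(bins["chrom"]) == {"1"}


class TestLog2Ratio:
    @staticmethod
    def totals(rng, n_samples, manifest, cn_mask=None, cn_factor=1.0):
        X = rng.lognormal(mean=np.log(5000), sigma=0.3,
                          size=(n_samples, len(manifest)))
        if cn_mask is not None:
            X[:, cn_mask] *= cn_factor
        return pd.DataFrame(X, index=[f"s{i}" for i in range(n_samples)],
                            columns=manifest.index)

    def test_reference_like_sample_centers_on_zero(self, rng):
        manifest = manifest_from_positions({"1": list(range(25, 50_000, 25))})
        bins = cnv.bin_genome(manifest, manifest.index, 1000, 5,
                              {"1": 50_000})
        ref = self.totals(rng, 10, manifest)
        sample = self.totals(rng, 1, manifest)
        L = cnv.log2_ratio(sample, ref, bins)
        assert abs(L.iloc[0].median()) < 0.05

    @pytest.mark.parametrize("cn, expected", [(4, 1.0), (1, -1.0)])
    def test_planted_copy_number_hits_log2(self, rng, cn, expected):
        positions = {c: list(range(25, 50_000, 25)) for c in ("1", "2", "3")}
        manifest = manifest_from_positions(positions)
        bins = cnv.bin_genome(manifest, manifest.index, 1000, 5,
                              {c: 50_000 for c in positions})
        mask = (manifest["chrom"] == "3").to_numpy()
        ref = self.totals(rng, 10, manifest)
        sample = self.totals(rng, 1, manifest, cn_mask=mask, cn_factor=cn / 2)
        L = cnv.log2_ratio(sample, ref, bins)
        chr3_bins = bins.index[bins["chrom"] == "3"]
        assert L.loc["s0", chr3_bins].mean() == pytest.approx(expected, abs=0.1)

    def test_invariant_to_global_intensity_scaling(self, rng):
        manifest = manifest_from_positions({"1": list(range(25, 20_000, 25))})
        bins = cnv.bin_genome(manifest, manifest.index, 1000, 5, {"1": 20_000})
        ref = self.totals(rng, 5, manifest)
        sample = self.totals(rng, 2, manifest)
        L1 = cnv.log2_ratio(sample, ref, bins, epsilon=0.0)
        L2 = cnv.log2_ratio(sample * 3.7, ref * 3.7, bins, epsilon=0.0)
        np.testing.assert_allclose(L1.to_numpy(), L2.to_numpy(), atol=1e-10)

    def test_requires_three_references(self, rng):
        manifest = manifest_from_positions({"1": list(range(25, 5000, 25))})
        bins = cnv.bin_genome(manifest, manifest.index, 1000, 5, {"1": 5000})
        with pytest.raises(ValueError, match="reference"):
            cnv.log2_ratio(self.totals(rng, 1, manifest),
                           self.totals(rng, 2, manifest), bins)


def naive_dp_segments(y, penalty):
    """Independent recursive DP oracle for optimal partitioning (<= 30 bins)."""
    from functools import lru_cache
    y = np.asarray(y, dtype=float)

    def sse(i, j):
        seg = y[i:j]
        return float(((seg - seg.mean()) ** 2).sum())

    @lru_cache(maxsize=None)
    def best(j):
        if j == 0:
            return (-penalty, ())
        options = []
        for i in range(j):
            prev_cost, prev_cuts = best(i)
            options.append((prev_cost + sse(i, j) + penalty,
                            prev_cuts + ((i, j),)))
        return min(options, key=lambda t: t[0])

    return list(best(len(y))[1])


class TestSegmentProfile:
    def test_constant_profile_is_single_segment_per_chromosome(self):
        bins, log2 = bins_from_log2({"1": [0.0] * 12, "2": [0.3] * 8})
        segs = cnv.segment_profile(log2, bins, penalty=0.1)
        assert len(segs) == 2
        assert {s.chrom for s in segs} == {"1", "2"}

    def test_noisy_step_localized_within_one_bin(self, rng):
        y = np.concatenate([rng.normal(0, 0.05, 20), rng.normal(1.0, 0.05, 20)])
        bins, log2 = bins_from_log2({"1": y})
        segs = cnv.segment_profile(log2, bins, penalty=None)
        assert len(segs) >= 2
        boundaries = sorted(s.start for s in segs)[1:]
        assert any(abs(b - 20 * 100) <= 100 for b in boundaries)

    def test_noiseless_staircase_matches_dp_oracle(self):
        y = [0.0] * 8 + [1.0] * 6 + [-0.5] * 10
        bins, log2 = bins_from_log2({"1": y})
        segs = cnv.segment_profile(log2, bins, penalty=0.05)
        oracle = naive_dp_segments(y, 0.05)
        assert [(s.start // 100, s.end // 100) for s in segs] == \
            [(i, j) for i, j in oracle]
        for s, (i, j) in zip(segs, oracle):
            assert s.mean_log2 == pytest.approx(np.mean(y[i:j]), abs=1e-12)

    def test_random_profiles_match_dp_oracle(self, rng):
        for _ in range(5):
            y = rng.normal(0, 0.3, rng.integers(5, 25))
            penalty = float(rng.uniform(0.02, 0.5))
            bins, log2 = bins_from_log2({"1": y})
            segs = cnv.segment_profile(log2, bins, penalty=penalty)
            oracle = naive_dp_segments(y, penalty)
            assert [(s.start // 100, s.end // 100) for s in segs] == oracle

    def test_segments_partition_bins(self, rng):
        y = rng.normal(0, 0.2, 30)
        bins, log2 = bins_from_log2({"1": y})
        segs = cnv.segment_profile(log2, bins, penalty=0.1)
        assert sum(s.n_bins for s in segs) == len(bins)
        spans = sorted((s.start, s.end) for s in segs)
        assert spans[0][0] == 0 and spans[-1][1] == 3000
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c

    def test_nan_bins_masked(self):
        y = [0.0, np.nan, 0.0, 0.0, np.nan, 0.0]
        bins, log2 = bins_from_log2({"1": y})
        segs = cnv.segment_profile(log2, bins, penalty=0.1)
        assert sum(s.n_bins for s in segs) == 4


class TestCalls:
    @staticmethod
    def gene_bed():
        return pd.DataFrame([{"chrom": "1", "start": 400, "end": 600,
                              "name": "PDGFRA"}])

    def test_focal_high_amplification(self):
        segs = [cnv.Segment("1", 0, 400, 4, 0.0),
                cnv.Segment("1", 400, 700, 3, 2.0),
                cnv.Segment("1", 700, 10_000, 93, 0.0)]
        call, = cnv.call_focal(segs, self.gene_bed(), {"1": 10_000})
        assert call.status == "high_amplification"

    def test_broad_amplitude_is_not_focal(self):
        # same amplitude across 40% of the chromosome: gain, not focal amp
        segs = [cnv.Segment("1", 0, 4000, 40, 2.0),
                cnv.Segment("1", 4000, 10_000, 60, 0.0)]
        call, = cnv.call_focal(segs, self.gene_bed(), {"1": 10_000})
        assert call.status == "gain"

    def test_diploid_genome_all_neutral(self):
        segs = [cnv.Segment("1", 0, 10_000, 100, 0.01)]
        call, = cnv.call_focal(segs, self.gene_bed(), {"1": 10_000})
        assert call.status == "neutral"

    def test_uncovered_gene_not_assessable(self):
        segs = [cnv.Segment("2", 0, 10_000, 100, 0.0)]
        call, = cnv.call_focal(segs, self.gene_bed(), {"1": 10_000, "2": 10_000})
        assert call.status == "not_assessable"

    def test_whole_arm_single_copy_gain(self):
        arms = {"1q": ("1", 4000, 10_000)}
        segs = [cnv.Segment("1", 0, 4000, 40, 0.0),
                cnv.Segment("1", 4000, 10_000, 60, np.log2(1.5))]
        call, = cnv.call_arm(segs, arms)
        assert call.status == "gain"

    def test_neutral_arm(self):
        arms = {"1q": ("1", 4000, 10_000)}
        segs = [cnv.Segment("1", 0, 10_000, 100, 0.02)]
        call, = cnv.call_arm(segs, arms)
        assert call.status == "neutral"

    def test_half_arm_loss_at_boundary_follows_rule(self):
        # exactly 50% of the arm at -0.4, rest at 0: weighted mean -0.2
        # passes the amplitude threshold and the fraction rule (>= 0.5)
        arms = {"1q": ("1", 4000, 10_000)}
        segs = [cnv.Segment("1", 4000, 7000, 30, -0.4),
                cnv.Segment("1", 7000, 10_000, 30, 0.0)]
        call, = cnv.call_arm(segs, arms)
        wmean = (-0.4 * 3000 + 0.0 * 3000) / 6000
        assert wmean <= -0.15
        assert call.status == "loss"
        # just under half the territory altered: no call
        segs2 = [cnv.Segment("1", 4000, 6900, 29, -0.4),
                 cnv.Segment("1", 6900, 10_000, 31, 0.0)]
        call2, = cnv.call_arm(segs2, arms)
        assert call2.status == "neutral"


class TestCountBreakpoints:
    def test_flat_genome_has_none(self):
        segs = [cnv.Segment(str(c), 0, 1000, 10, 0.0) for c in range(1, 23)]
        assert cnv.count_breakpoints(segs) == 0

    def test_planted_transitions_counted_exactly(self):
        segs = [cnv.Segment("1", 0, 100, 1, 0.0),
                cnv.Segment("1", 100, 200, 1, 1.0),
                cnv.Segment("1", 200, 300, 1, 0.0),
                cnv.Segment("2", 0, 100, 1, 0.0),
                cnv.Segment("2", 100, 200, 1, -0.8)]
        assert cnv.count_breakpoints(segs, min_delta=0.3) == 3

    def test_subthreshold_transition_not_counted(self):
        segs = [cnv.Segment("1", 0, 100, 1, 0.0),
                cnv.Segment("1", 100, 200, 1, 0.1)]
        assert cnv.count_breakpoints(segs, min_delta=0.3) == 0

    def test_monotone_in_min_delta_and_penalty(self, rng):
        y = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(0.6, 0.1, 10),
                            rng.normal(-0.4, 0.1, 10)])
        bins, log2 = bins_from_log2({"1": y})
        counts_delta = []
        segs = cnv.segment_profile(log2, bins, penalty=0.05)
        for delta in (0.1, 0.3, 0.5, 1.0):
            counts_delta.append(cnv.count_breakpoints(segs, min_delta=delta))
        assert counts_delta == sorted(counts_delta, reverse=True)
        counts_pen = []
        for penalty in (0.01, 0.1, 1.0, 10.0):
            segs = cnv.segment_profile(log2, bins, penalty=penalty)
            counts_pen.append(cnv.count_breakpoints(segs, min_delta=0.1))
        assert counts_pen == sorted(counts_pen, reverse=True)

    def test_breakpoint_bound_invariant(self, rng):
        y = rng.normal(0, 0.4, 40)
        bins, log2 = bins_from_log2({"1": y[:20], "2": y[20:]})
        segs = cnv.segment_profile(log2, bins, penalty=0.05)
        n_chroms = len({s.chrom for s in segs})
        assert cnv.count_breakpoints(segs, 0.0) <= len(segs) - n_chroms


class TestEndToEndRecovery:
    def test_planted_calls_recovered_in_small_cohort(self, small_cfg,
                                                     small_cohort, small_norm,
                                                     small_manifest):
        data, truth = small_cohort
        g = small_cfg.genome
        pc = PipelineConfig()
        bins = cnv.bin_genome(small_manifest, small_norm.beta.columns,
                              pc.bin_width, pc.min_probes_per_bin,
                              g.chrom_lengths)
        genes = pd.DataFrame([{"chrom": c, "start": s, "end": e, "name": n}
                              for n, (c, s, e) in g.genes.items()])
        refs = truth.roles[truth.roles == "reference"].index
        qs = truth.roles[truth.roles == "query"].index
        profs = cnv.profile_cohort(small_norm.cnv_totals.loc[qs],
                                   small_norm.cnv_totals.loc[refs],
                                   bins, genes, g.arms(), g.chrom_lengths, pc)
        status = {sid: {c.target: c.status for c in p.calls}
                  for sid, p in profs.items()}
        assert status["RIG_01"]["PDGFRA"] == "high_amplification"
        assert status["RIG_01"]["13q"] == "loss"
        assert status["RIG_02"]["CDKN2A/B"] == "homozygous_deletion"
        for sid in ("RIG_03", "RIG_04", "RIG_05", "RIG_06"):
            non_neutral = {t: s for t, s in status[sid].items()
                           if s != "neutral"}
            assert non_neutral == {}
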