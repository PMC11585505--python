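"""Log ratios, binning, segmentation, arm calls, burdens, Jaccard, oscillation."""

import numpy as np
import pandas as pd
import pytest

import pitmeth as pm
from pitmeth.cnv import CNVSegment, _segment_one


def seg(sample, chrom, start, end, mean, n_bins=10):
    return CNVSegment(sample, chrom, start, end, mean, n_bins)


class TestLogRatios:
    def make_intensity(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(np.log(5000), 0.3, 200)
        x = np.tile(base[:, None], (1, 6)).astype(float)
        return pd.DataFrame(x, index=[f"p{i}" for i in range(200)],
                            columns=[f"s{j}" for j in range(6)])

    def test_reference_sample_ratio_zero_and_doubling_one(self):
        inten = self.make_intensity()
        inten["s5"] *= 2.0
        lr = pm.compute_log_ratios(inten, ["s0", "s1", "s2"])
        assert np.allclose(lr["s0"], 0.0)
        assert np.allclose(lr["s5"], 1.0)

    def test_too_few_references_rejected(self):
        with pytest.raises(ValueError, match="3 reference"):
            pm.compute_log_ratios(self.make_intensity(), ["s0", "s1"])

    def test_zero_reference_median_dropped(self):
        inten = self.make_intensity()
        inten.iloc[0, :] = 0.0
        lr = pm.compute_log_ratios(inten, ["s0", "s1", "s2"])
        assert "p0" not in lr.index and len(lr) == 199


class TestBinSignal:
    def make_toy(self):
        # 12 probes on 2 chromosomes, 1-based positions
        man = pd.DataFrame({
            "chrom": ["c1"] * 8 + ["c2"] * 4,
            "pos": [50, 150, 250, 350, 450, 1050, 1150, 2050,
                    50, 150, 1050, 1150],
        }, index=[f"p{i}" for i in range(12)])
        lr = pd.DataFrame(
            {"s0": [1.0, 2, 3, 4, 5, 10, 20, 7, 1, 3, 5, 9]},
            index=man.index,
        )
        return lr, man

    def test_hand_computed_bin_medians(self):
        lr, man = self.make_toy()
        out = pm.bin_signal(lr, man, 1000)
        assert out.loc[("c1", 0, 1000), "s0"] == 3.0       # median of 1..5
        assert out.loc[("c1", 1000, 2000), "s0"] == 15.0   # median of 10, 20
        assert out.loc[("c1", 2000, 3000), "s0"] == 7.0    # single probe
        assert out.loc[("c2", 0, 1000), "s0"] == 2.0
        assert out.loc[("c2", 1000, 2000), "s0"] == 7.0

    def test_empty_bins_absent(self):
        lr, man = self.make_toy()
        out = pm.bin_signal(lr, man, 100)
        # no probe in c1 [500, 600) -> that bin must not exist
        assert ("c1", 500, 600) not in out.index

    def test_invalid_bin_size(self):
        lr, man = self.make_toy()
        with pytest.raises(ValueError):
            pm.bin_signal(lr, man, 0)


class TestSegmentation:
    def test_constant_signal_single_segment(self):
        rng = np.random.default_rng(1)
        assert _segment_one(np.full(60, 0.2), 5, 0.01, 200, rng) == [(0, 60)]

    def test_noiseless_step_exact_breakpoint(self):
        y = np.concatenate([np.zeros(50), np.full(50, 0.6)])
        segs = _segment_one(y, 5, 0.01, 200, np.random.default_rng(2))
        assert segs == [(0, 50), (50, 100)]

    def test_noisy_step_within_two_bins(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            y = np.concatenate([np.zeros(50), np.full(50, 0.6)])
            y = y + rng.normal(0, 0.1, 100)
            segs = _segment_one(y, 5, 0.01, 200, np.random.default_rng(500 + rep))
            cuts = [a for a, _ in segs if a > 0]
            hits += any(abs(c - 50) <= 2 for c in cuts)
        assert hits >= 38

    def test_genomic_coordinates_carried_through(self):
        # two chromosomes, step on c1 only
        idx = pd.MultiIndex.from_tuples(
            [("c1", s, s + 1000) for s in range(0, 40000, 1000)]
            + [("c2", s, s + 1000) for s in range(0, 20000, 1000)],
            names=["chrom", "start", "end"],
        )
        y = np.concatenate([np.zeros(20), np.full(20, 0.8), np.zeros(20)])
        binned = pd.DataFrame({"s0": y}, index=idx)
        segs = pm.segment_bins(binned, min_bins=3, seed=3)
        c1 = sorted([s for s in segs if s.chrom == "c1"], key=lambda s: s.start)
        assert [(s.start, s.end) for s in c1] == [(0, 20000), (20000, 40000)]
        assert [s for s in segs if s.chrom == "c2"][0].mean == 0.0


ARMS = pd.DataFrame({
    "chrom": ["c1", "c1"], "start": [0, 40], "end": [40, 100],
    "arm": ["c1p", "c1q"],
})


class TestArmCalls:
    def test_sixty_percent_gain_called(self):
        calls = pm.call_arm_states([seg("s", "c1", 0, 24, 0.4)], ARMS)
        row = calls[calls["arm"] == "c1p"].iloc[0]
        assert row["state"] == "gain" and row["gain_fraction"] == pytest.approx(0.6)

    def test_forty_percent_gain_balanced(self):
        calls = pm.call_arm_states([seg("s", "c1", 0, 16, 0.4)], ARMS)
        assert calls[calls["arm"] == "c1p"].iloc[0]["state"] == "balanced"

    def test_whole_chromosome_gain_hits_both_arms(self):
        calls = pm.call_arm_states([seg("s", "c1", 0, 100, 0.4)], ARMS)
        assert set(calls["state"]) == {"gain"}

    def test_fractions_sum_bounded(self):
        segs = [seg("s", "c1", 0, 20, 0.4), seg("s", "c1", 20, 40, -0.4)]
        calls = pm.call_arm_states(segs, ARMS)
        assert ((calls["gain_fraction"] + calls["loss_fraction"]) <= 1 + 1e-12).all()

    def test_exact_tie_resolved_by_weighted_magnitude(self):
        segs = [seg("s", "c1", 0, 20, 0.2), seg("s", "c1", 20, 40, -0.5)]
        calls = pm.call_arm_states(segs, ARMS, arm_fraction=0.5)
        assert calls[calls["arm"] == "c1p"].iloc[0]["state"] == "loss"

    def test_uncovered_arm_balanced(self):
        calls = pm.call_arm_states([seg("s", "c1", 0, 40, 0.4)], ARMS,
                                   samples=["s"])
        assert calls[calls["arm"] == "c1q"].iloc[0]["state"] == "balanced"

    def test_brute_force_oracle_on_random_segments(self):
        rng = np.random.default_rng(4)
        segs = []
        for s in range(8):
            pos = 0
            while pos < 100:
                width = int(rng.integers(5, 30))
                segs.append(seg(f"s{s}", "c1", pos, min(pos + width, 100),
                                float(rng.normal(0, 0.3))))
                pos += width
        calls = pm.call_arm_states(segs, ARMS)
        for _, row in calls.iterrows():
            gained = sum(
                max(0, min(x.end, ARMS[ARMS["arm"] == row["arm"]]["end"].iloc[0])
                    - max(x.start, ARMS[ARMS["arm"] == row["arm"]]["start"].iloc[0]))
                for x in segs if x.sample == row["sample"] and x.mean >= 0.1
            )
            arm_row = ARMS[ARMS["arm"] == row["arm"]].iloc[0]
            assert row["gain_fraction"] == pytest.approx(
                gained / (arm_row["end"] - arm_row["start"])
            )


def sheet_for(samples, groups):
    from conftest import make_sheet
    return make_sheet(samples, groups)


class TestCumulativeProfile:
    def make_calls(self, n_gain, n_total=10):
        rows = []
        for i in range(n_total):
            state = "gain" if i < n_gain else "balanced"
            rows.append((f"s{i}", "c1p", state, 0.6 if state == "gain" else 0.0, 0.0))
        return pd.DataFrame(rows, columns=["sample", "arm", "state",
                                           "gain_fraction", "loss_fraction"])

    def test_six_of_ten_frequent(self):
        calls = self.make_calls(6)
        sheet = sheet_for([f"s{i}" for i in range(10)], ["APT"] * 10)
        prof = pm.cumulative_profile(calls, sheet)
        row = prof.iloc[0]
        assert row["gain_pct"] == pytest.approx(60.0) and bool(row["frequent"])

    def test_exactly_half_not_frequent(self):
        calls = self.make_calls(5)
        sheet = sheet_for([f"s{i}" for i in range(10)], ["APT"] * 10)
        assert not bool(pm.cumulative_profile(calls, sheet).iloc[0]["frequent"])

    def test_matches_brute_force_recount(self, cohort, genome):
        rng = np.random.default_rng(5)
        samples = list(cohort["sheet"]["sample"])
        arms = genome.arm_table()["arm"].tolist()
        rows = []
        for s in samples:
            for a in arms:
                rows.append((s, a, rng.choice(["gain", "loss", "balanced"]), 0.6, 0.0))
        calls = pd.DataFrame(rows, columns=["sample", "arm", "state",
                                            "gain_fraction", "loss_fraction"])
        prof = pm.cumulative_profile(calls, cohort["sheet"])
        sheet = cohort["sheet"].set_index("sample")
        for _, row in prof.iterrows():
            members = sheet.index[sheet["group"] == row["group"]]
            sub = calls[(calls["sample"].isin(members)) & (calls["arm"] == row["arm"])]
            assert row["gain_pct"] == pytest.approx(
                100 * (sub["state"] == "gain").sum() / len(members)
            )


class TestArmBurden:
    def test_counts_and_group_summary(self):
        rows = [("a", "c1p", "gain", 0.6, 0), ("a", "c1q", "loss", 0, 0.6),
                ("a", "c2p", "balanced", 0, 0), ("b", "c1p", "balanced", 0, 0)]
        calls = pd.DataFrame(rows, columns=["sample", "arm", "state",
                                            "gain_fraction", "loss_fraction"])
        sheet = sheet_for(["a", "b"], ["APT", "benign"])
        per_sample, summary = pm.arm_burden_summary(calls, sheet)
        assert per_sample["a"] == 2 and per_sample["b"] == 0
        apt = summary[summary["group"] == "APT"].iloc[0]
        assert apt["median"] == 2 and apt["min"] == 2 and apt["max"] == 2

    def test_matches_recount_on_fixture(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(20)]
        rows = []
        for s in samples:
            for a in ["c1p", "c1q", "c2p", "c2q"]:
                rows.append((s, a, rng.choice(["gain", "loss", "balanced"]), 0, 0))
        calls = pd.DataFrame(rows, columns=["sample", "arm", "state",
                                            "gain_fraction", "loss_fraction"])
        sheet = sheet_for(samples, ["APT"] * 10 + ["benign"] * 10)
        per_sample, _ = pm.arm_burden_summary(calls, sheet)
        for s in samples:
            expected = ((calls["sample"] == s) & (calls["state"] != "balanced")).sum()
            assert per_sample[s] == expected


class TestJaccard:
    def calls_from(self, profiles):
        rows = []
        for s, feats in profiles.items():
            for arm, state in feats:
                rows.append((s, arm, state, 0.6, 0.0))
            if not feats:
                rows.append((s, "c1p", "balanced", 0.0, 0.0))
        return pd.DataFrame(rows, columns=["sample", "arm", "state",
                                           "gain_fraction", "loss_fraction"])

    def test_hand_formula_cases(self):
        calls = self.calls_from({
            "a": [("7p", "gain"), ("9q", "loss")],
            "b": [("7p", "gain")],
            "c": [("1p", "loss")],
            "d": [("7p", "gain"), ("9q", "loss")],
        })
        dist, _ = pm.jaccard_cluster(calls)
        assert dist.loc["a", "d"] == pytest.approx(0.0)
        assert dist.loc["a", "b"] == pytest.approx(0.5)
        assert dist.loc["b", "c"] == pytest.approx(1.0)

    def test_all_balanced_pair_distance_zero(self):
        calls = self.calls_from({"a": [], "b": [], "c": [("7p", "gain")]})
        dist, _ = pm.jaccard_cluster(calls)
        assert dist.loc["a", "b"] == 0.0
        assert dist.loc["a", "c"] == 1.0

    def test_distance_matrix_properties(self, cohort, genome):
        rng = np.random.default_rng(7)
        rows = []
        for s in cohort["sheet"]["sample"]:
            for a in genome.arm_table()["arm"]:
                rows.append((s, a, rng.choice(["gain", "loss", "balanced"],
                                              p=[0.2, 0.2, 0.6]), 0, 0))
        calls = pd.DataFrame(rows, columns=["sample", "arm", "state",
                                            "gain_fraction", "loss_fraction"])
        dist, _ = pm.jaccard_cluster(calls)
        d = dist.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1

    def test_topology_invariant_under_sqrt_transform(self):
        rng = np.random.default_rng(8)
        rows = []
        for s in range(10):
            for a in ["1p", "1q", "2p", "2q", "3p", "3q"]:
                rows.append((f"s{s}", a, rng.choice(["gain", "loss", "balanced"]),
                             0, 0))
        calls = pd.DataFrame(rows, columns=["sample", "arm", "state",
                                            "gain_fraction", "loss_fraction"])
        dist, dendro = pm.jaccard_cluster(calls)
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform
        z_sqrt = hierarchy.linkage(
            squareform(np.sqrt(dist.to_numpy()), checks=False), method="complete"
        )
        for k in (2, 3, 4):
            a = hierarchy.fcluster(dendro.linkage, k, "maxclust")
            b = hierarchy.fcluster(z_sqrt, k, "maxclust")
            from sklearn.metrics import adjusted_rand_score
            assert adjusted_rand_score(a, b) == 1.0


class TestChromothripsis:
    def test_alternating_twelve_segments_flagged(self):
        segs = []
        for i in range(12):
            segs.append(seg("s", "c1", i * 10, (i + 1) * 10,
                            0.5 if i % 2 == 0 else -0.5))
        flags = pm.chromothripsis_flags(segs, min_switches=10)
        row = flags.iloc[0]
        assert row["switches"] == 11 and bool(row["flagged"])

    def test_monotone_gain_not_flagged(self):
        flags = pm.chromothripsis_flags([seg("s", "c1", 0, 100, 0.5)])
        assert not bool(flags.iloc[0]["flagged"])

    def test_balanced_between_counts_single_switch(self):
        segs = [seg("s", "c1", 0, 10, 0.5), seg("s", "c1", 10, 20, 0.0),
                seg("s", "c1", 20, 30, -0.5)]
        flags = pm.chromothripsis_flags(segs, min_switches=2)
        assert flags.iloc[0]["switches"] == 1

    def test_planted_oscillation_recovered_from_simulation(self, genome):
        man = pm.generate_manifest(genome, 12000, seed=13)
        design = pm.CohortDesign(
            seed=13, n_dmp=0, n_benign=6, n_apt=4, n_pc=2,
            chromothripsis=(pm.ChromothripsisEvent("PC", "chr4", 12, 1),),
        )
        beta, inten, sheet, truth = pm.generate_cohort(design, man, genome)
        ref = sheet.loc[sheet["group"] == "benign", "sample"]
        lr = pm.compute_log_ratios(inten, ref)
        binned = pm.bin_signal(lr, man, 100_000)
        segs = pm.segment_bins(binned, seed=13)
        flags = pm.chromothripsis_flags(segs)
        flagged = set(map(tuple, flags[flags["flagged"]][["sample", "chrom"]].values))
        assert flagged == set(map(tuple, truth.chromothripsis))


class TestSegFrame:
    def test_seg_columns(self):
        frame = pm.segments_to_frame([seg("s", "c1", 0, 10, 0.5, 3)])
        assert list(frame.columns) == ["ID", "chrom", "loc.start", "loc.end",
                                       "num.mark", "seg.mean"]
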