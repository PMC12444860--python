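"""Cohort statistics: pulsing summaries, correlations, dye classification,
shell ratios, group tests, exact binomial tallies."""

import numpy as np
import pandas as pd
import pytest

from phagopulse.errors import ConfigurationError, ShapeError, StateError
from phagopulse.segmentation import LabelVolume
from phagopulse.stats import (EventTally, MaskIntensitySeries, NeutrophilRecord,
                              burden_correlation, clopper_pearson, compare_groups,
                              dcf_shell_ratio, dye_positive_fraction, load_event_tally,
                              pulsing_summary, relative_change, tally_statistics)
from phagopulse.synthetic import SimConfig, plan_cohort


def rec(nid, n_ph, n_pulsing, n_bact=None):
    return NeutrophilRecord(nid, n_bact if n_bact is not None else n_ph,
                            list(range(n_ph)), n_pulsing)


class TestPulsingSummary:
    def test_all_pulsing(self):
        s = pulsing_summary([rec(0, 3, 3), rec(1, 5, 5)])
        assert s["pct_pulsing_per_neutrophil_mean"] == 100.0
        assert s["pct_neutrophils_with_pulsing"] == 100.0

    def test_hand_computed_two_neutrophils(self):
        """Fractions 0% and 50% -> mean 25%, half of neutrophils pulsing."""
        s = pulsing_summary([rec(0, 4, 0), rec(1, 4, 2)])
        assert s["pct_pulsing_per_neutrophil_mean"] == pytest.approx(25.0)
        assert s["pct_neutrophils_with_pulsing"] == pytest.approx(50.0)
        assert s["pct_pulsing_pooled_phagosomes"] == pytest.approx(25.0)

    def test_zero_phagosome_neutrophils_excluded(self):
        records = [NeutrophilRecord(0, 0, [], 0), rec(1, 2, 1)]
        s = pulsing_summary(records)
        assert s["n_neutrophils"] == 1
        assert s["n_neutrophils_excluded_zero_phagosomes"] == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            pulsing_summary([NeutrophilRecord(0, 0, [], 0)])

    def test_recovers_generative_p_pulse_within_3se(self):
        """Scheduled cohort at p_pulse=0.124: per-neutrophil mean within 3 s.e."""
        cfg = SimConfig(n_neutrophils=200, phagosomes_min=1, phagosomes_max=25,
                        p_pulse=0.124, n_frames=60, seed=55)
        log = plan_cohort(cfg)
        records = []
        for n in log.neutrophils:
            phs = log.phagosomes_of(n.neutrophil_id)
            records.append(NeutrophilRecord(n.neutrophil_id, n.n_bacteria,
                                            [p.phagosome_id for p in phs],
                                            sum(p.pulsing for p in phs)))
        s = pulsing_summary(records)
        fracs = [100 * sum(p.pulsing for p in log.phagosomes_of(n.neutrophil_id))
                 / n.n_bacteria for n in log.neutrophils]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(s["pct_pulsing_per_neutrophil_mean"] - 12.4) < 3 * se

    def test_pulse_count_distribution_reported(self):
        s = pulsing_summary([rec(0, 2, 2)], latencies_min=[5.0, 9.0], pulse_counts=[3, 18])
        assert s["latency_min_mean"] == pytest.approx(7.0)
        assert s["pulse_count_max"] == 18
        assert s["pulse_count_distribution"] == {3: 1, 18: 1}


class TestBurdenCorrelation:
    def test_perfectly_increasing(self):
        records = [rec(i, 5, i, n_bact=i + 1) for i in range(5)]
        res = burden_correlation(records)
        assert res.rho == pytest.approx(1.0)

    def test_perfectly_decreasing_triplet(self):
        records = [rec(0, 5, 3, n_bact=1), rec(1, 5, 2, n_bact=2), rec(2, 5, 1, n_bact=3)]
        assert burden_correlation(records).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        """Spearman with midrank ties equals the rank-transform + Pearson oracle."""
        from scipy.stats import rankdata

        x = rng.integers(1, 10, size=50)
        y = rng.integers(0, 5, size=50)
        records = [rec(i, 10, int(yy), n_bact=int(xx)) for i, (xx, yy) in enumerate(zip(x, y))]
        res = burden_correlation(records)
        rx, ry = rankdata(x), rankdata(y)  # midranks
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_flagged(self):
        records = [rec(i, 5, 2, n_bact=3) for i in range(5)]
        res = burden_correlation(records)
        assert not res.valid and np.isnan(res.rho)

    def test_requires_three_neutrophils(self):
        with pytest.raises(ConfigurationError):
            burden_correlation([rec(0, 2, 1), rec(1, 2, 0)])


class TestRelativeChange:
    def test_constant_series_gives_unity(self):
        s = MaskIntensitySeries(0, "prey", [0, 10, 60], [50.0, 50.0, 50.0], "non-pulsing")
        per_obj, grp, excl = relative_change([s], baseline_min=0)
        assert np.allclose(per_obj["relative_change"], 1.0)
        assert excl == []

    def test_halving(self):
        s = MaskIntensitySeries(0, "prey", [0, 10], [10.0, 5.0], "non-pulsing")
        per_obj, _, _ = relative_change([s], baseline_min=0)
        assert per_obj.loc[per_obj.timepoint_min == 10, "relative_change"].iloc[0] == 0.5

    def test_zero_baseline_excluded_and_logged(self):
        s = MaskIntensitySeries(0, "prey", [0, 10], [0.0, 5.0], "x")
        per_obj, _, excl = relative_change([s], baseline_min=0)
        assert excl == [0] and len(per_obj) == 0

    def test_pulsing_class_stays_brighter(self):
        """With the pH map, open (pulsing) phagosomes keep the prey bright at 10 min
        while sealed ones dim — group means must separate in that direction."""
        cfg = SimConfig()
        dim = cfg.prey_dim_factor * cfg.prey_intensity + cfg.background
        bright = cfg.prey_intensity + cfg.background
        series = []
        for i in range(6):  # non-pulsing: sealed at 10 min
            series.append(MaskIntensitySeries(i, "prey", [0, 10], [bright, dim],
                                              "non-pulsing"))
        for i in range(6, 12):  # pulsing: open interval at 10 min
            series.append(MaskIntensitySeries(i, "prey", [0, 10], [bright, bright],
                                              "pulsing"))
        _, grp, _ = relative_change(series, baseline_min=0)
        at10 = grp[grp.timepoint_min == 10].set_index("group")["mean"]
        assert at10["pulsing"] > at10["non-pulsing"]


class TestDyePositive:
    def test_all_background_is_zero_percent(self):
        frac, labels, thr = dye_positive_fraction(np.full(50, 10.0),
                                                  background_mean=10.0, background_sd=1.0)
        assert frac == 0.0 and not labels.any()

    def test_fixed_threshold_override(self):
        frac, labels, thr = dye_positive_fraction(np.array([5.0, 50.0]),
                                                  fixed_threshold=20.0)
        assert frac == 50.0 and thr == 20.0

    def test_binomial_recovery_at_half(self, rng):
        """p_leak = 0.5, n = 2000: classified fraction within 3 binomial s.e."""
        n = 2000
        leaky = rng.random(n) < 0.5
        vals = 10.0 + 100.0 * leaky + rng.normal(0, 2.0, n)
        frac, _, _ = dye_positive_fraction(vals, background_mean=10.0, background_sd=2.0)
        se = 100 * np.sqrt(0.25 / n)
        assert abs(frac - 50.0) < 3 * se

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.5])
    def test_recovery_across_leak_rates(self, p, rng):
        n = 2000
        leaky = rng.random(n) < p
        vals = 10.0 + 100.0 * leaky + rng.normal(0, 2.0, n)
        frac, _, _ = dye_positive_fraction(vals, background_mean=10.0, background_sd=2.0)
        se = 100 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - 100 * p) < 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(StateError):
            dye_positive_fraction(np.array([]), background_mean=0, background_sd=1)


class TestShellRatio:
    def _prey(self, shape=(9, 21, 21), vox=(0.33, 0.33, 1.5)):
        labels = np.zeros(shape, int)
        labels[4, 9:12, 9:12] = 1
        return LabelVolume(labels, "prey", 0, vox)

    def test_uniform_image_ratio_one(self):
        prey = self._prey()
        df = dcf_shell_ratio(np.full(prey.labels.shape, 7.0), prey, reference_mean=7.0)
        assert df.loc[0, "ratio"] == pytest.approx(1.0)
        assert not df.loc[0, "empty_shell"]

    def test_shell_matches_distance_oracle(self):
        """Shell voxels equal the brute-force anisotropic distance scan."""
        prey = self._prey()
        frame = np.arange(prey.labels.size, dtype=float).reshape(prey.labels.shape)
        df = dcf_shell_ratio(frame, prey, reference_mean=1.0, shell_radius_um=0.5)
        sx, sy, sz = prey.voxel_size
        mask = prey.labels == 1
        pts = np.argwhere(mask)
        shell = np.zeros_like(mask)
        for z in range(mask.shape[0]):
            for y in range(mask.shape[1]):
                for x in range(mask.shape[2]):
                    if mask[z, y, x]:
                        continue
                    d = np.sqrt(((pts[:, 0] - z) * sz) ** 2 + ((pts[:, 1] - y) * sy) ** 2
                                + ((pts[:, 2] - x) * sx) ** 2).min()
                    shell[z, y, x] = d <= 0.5
        assert df.loc[0, "n_shell_voxels"] == shell.sum()
        assert df.loc[0, "shell_mean"] == pytest.approx(frame[shell].mean())

    def test_ros_on_bacterium_ratio_four(self):
        prey = self._prey()
        frame = np.full(prey.labels.shape, 10.0)
        # paint the 0.5 µm shell at 4x the reference
        from scipy.ndimage import distance_transform_edt
        dist = distance_transform_edt(prey.labels == 0, sampling=(1.5, 0.33, 0.33))
        frame[(dist > 0) & (dist <= 0.5)] = 40.0
        df = dcf_shell_ratio(frame, prey, reference_mean=10.0)
        assert df.loc[0, "ratio"] == pytest.approx(4.0)

    def test_invalid_inputs(self):
        prey = self._prey()
        with pytest.raises(ConfigurationError):
            dcf_shell_ratio(np.zeros(prey.labels.shape), prey, reference_mean=0.0)
        with pytest.raises(ShapeError):
            dcf_shell_ratio(np.zeros((2, 2, 2)), prey, reference_mean=1.0)


class TestCompareGroups:
    def test_identical_groups_near_null(self, rng):
        v = rng.normal(0, 1, 40)
        out = compare_groups({"a": v, "b": v.copy()}, design="mannwhitney")
        assert out["pvalue"] > 0.9

    def test_strong_separation(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        out = compare_groups({"a": a, "b": b}, design="ttest")
        assert out["pvalue"] < 1e-6

    def test_kruskal_matches_hand_ranked_formula(self):
        """H on a 3-group toy set equals the hand-ranked statistic."""
        groups = {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]}
        out = compare_groups(groups, design="kruskal")
        # hand computation: ranks 1..6, no ties
        N = 6
        rank_sums = {"a": 1 + 2, "b": 3 + 4, "c": 5 + 6}
        H = 12.0 / (N * (N + 1)) * sum(rs ** 2 / 2 for rs in rank_sums.values()) - 3 * (N + 1)
        assert out["statistic"] == pytest.approx(H)
        assert {"group_a", "group_b", "z", "p_raw", "p_holm"} <= set(out["posthoc"].columns)

    def test_small_group_flagged_for_ttest(self):
        out = compare_groups({"a": [1.0], "b": [1.0, 2.0, 3.0]}, design="ttest")
        assert out["flags"]


class TestTallies:
    def test_packaged_fixture_reproduces_printed_percentages(self):
        df = tally_statistics(load_event_tally()).set_index("event")
        assert df.loc["re_opening_during_pulse", "percent"] == 19.6
        assert df.loc["full_release_during_pulse", "percent"] == 5.1
        assert df.loc["recaptured_same_neutrophil", "percent"] == 94
        assert df.loc["tubule_neck_during_pulse", "percent"] == 9.7

    def test_zero_numerator_ci(self):
        df = tally_statistics(EventTally({"none": (0, 10, 1)}))
        assert df.loc[0, "percent"] == 0.0
        assert df.loc[0, "ci95_low_pct"] == 0.0
        assert df.loc[0, "ci95_high_pct"] == pytest.approx(30.85, abs=0.01)

    def test_full_numerator(self):
        df = tally_statistics(EventTally({"all": (31, 31, 0)}))
        assert df.loc[0, "percent"] == 100
        assert df.loc[0, "ci95_high_pct"] == 100.0

    def test_invalid_tallies_rejected(self):
        with pytest.raises(ConfigurationError):
            EventTally({"bad": (5, 0, 1)})
        with pytest.raises(ConfigurationError):
            EventTally({"bad": (6, 5, 1)})

    def test_clopper_pearson_halfway(self):
        lo, hi = clopper_pearson(5, 10)
        assert 0.18 < lo < 0.20 and 0.80 < hi < 0.82
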