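"""Track-set selection, CI construction, dispersion statistics and tests."""

import numpy as np
import pandas as pd
import pytest

import amitrace as at
from amitrace import io
from amitrace.synth import CohortDataset


def _cohort(support_rows, samples):
    sup = pd.DataFrame(
        support_rows,
        columns=["sample_id", io.ID, io.SUPPORT_MAC, io.SUPPORT_LEFT, io.SUPPORT_RIGHT],
    )
    return CohortDataset(samples=pd.DataFrame(samples), support=sup)


@pytest.fixture
def toy_cohort():
    samples = [
        {"sample_id": "d5_r1", "timepoint": "d5", "generation": 17},
        {"sample_id": "d5_r2", "timepoint": "d5", "generation": 17},
        {"sample_id": "d14_r1", "timepoint": "d14", "generation": 48},
    ]
    rows = []
    for sid in ("d5_r1", "d5_r2", "d14_r1"):
        rows += [
            (sid, "good", 60, 20, 20),      # irs 0.2, coverage 100
            (sid, "border", 10, 5, 5),      # coverage exactly 20 -> excluded
            (sid, "lowscore", 95, 3, 2),    # irs 0.05 -> excluded
        ]
    # locus failing thresholds in just one sample
    rows += [
        ("d5_r1", "flaky", 60, 20, 20),
        ("d5_r2", "flaky", 95, 3, 2),
        ("d14_r1", "flaky", 60, 20, 20),
    ]
    return _cohort(rows, samples)


class TestSelectTrackSet:
    def test_thresholds_and_irs0(self, toy_cohort):
        ts = at.select_track_set(toy_cohort)
        assert ts.locus_ids == ["good"]
        # pooled irs = 40/(40 + 2*60) in both first-timepoint replicates
        assert ts.irs0["good"] == pytest.approx(0.25)
        assert ts.timepoint == "d5"

    def test_locus_failing_one_sample_excluded(self, toy_cohort):
        assert "flaky" not in at.select_track_set(toy_cohort).locus_ids

    def test_coverage_exactly_at_floor_excluded(self, toy_cohort):
        assert "border" not in at.select_track_set(toy_cohort).locus_ids

    def test_empty_track_set_warns(self, toy_cohort):
        with pytest.warns(UserWarning):
            ts = at.select_track_set(toy_cohort, min_reads=10_000)
        assert ts.locus_ids == []


class TestConstructCi:
    def test_band_width_from_analytic_sigma(self, haploid_model):
        ts = at.TrackSet(["a"], pd.Series({"a": 0.5}, name="irs0"), 3, "d5")
        ci = at.construct_ci(ts, haploid_model, 31)
        assert ci["sigma"].iloc[0] == pytest.approx(0.0668, abs=5e-4)
        assert ci["lo"].iloc[0] == pytest.approx(0.366, abs=1e-3)
        assert ci["hi"].iloc[0] == pytest.approx(0.634, abs=1e-3)

    def test_band_clamped_to_unit_interval(self, haploid_model):
        ts = at.TrackSet(["a"], pd.Series({"a": 0.95}, name="irs0"), 3, "d5")
        ci = at.construct_ci(ts, haploid_model, 2000)
        assert ci["hi"].iloc[0] == 1.0
        assert 0.0 <= ci["lo"].iloc[0] <= 0.95

    def test_bands_widen_with_elapsed_generations(self, haploid_model):
        ts = at.TrackSet(["a"], pd.Series({"a": 0.4}, name="irs0"), 3, "d5")
        widths = [
            (lambda c: c["hi"] - c["lo"])(at.construct_ci(ts, haploid_model, g)).iloc[0]
            for g in (5, 17, 31, 60)
        ]
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_requires_positive_elapsed_generations(self, haploid_model):
        ts = at.TrackSet(["a"], pd.Series({"a": 0.4}, name="irs0"), 3, "d5")
        with pytest.raises(ValueError):
            at.construct_ci(ts, haploid_model, 0)


class TestWithinCi:
    def test_observations_at_irs0_always_inside(self, toy_cohort, haploid_model):
        ts = at.select_track_set(toy_cohort)
        ci = at.construct_ci(ts, haploid_model, 31)
        frac, flags = at.within_ci_fraction(toy_cohort, ci, "d14")
        assert frac == 1.0
        assert len(flags) == 1  # one tracked locus x one d14 replicate

    def test_miscalibrated_cohort_undercovers(self, haploid_model, chromosomal_model):
        # evolve under the faster (chromosomal) kernel, build CI from the
        # slower haploid model: coverage must fall below the nominal 95%
        rng = np.random.default_rng(31)
        irs0 = rng.uniform(0.3, 0.7, 300)
        cohort = at.evolve_cohort(
            chromosomal_model, irs0, [0, 31], 6, depth_model=2000, seed=33
        )
        ts = at.select_track_set(cohort)
        ci = at.construct_ci(ts, haploid_model, 31)
        frac, _ = at.within_ci_fraction(cohort, ci, cohort.timepoints()[1])
        assert frac < 0.95


class TestDispersion:
    def test_replicate_sd_hand_example(self):
        samples = [
            {"sample_id": f"d5_r{i}", "timepoint": "d5", "generation": 17} for i in (1, 2, 3)
        ] + [
            {"sample_id": f"d14_r{i}", "timepoint": "d14", "generation": 48} for i in (1, 2, 3)
        ]
        rows = []
        # pooled irs = (L+R)/(L+R + 2*MAC): exactly 0.2, 0.3, 0.4 per replicate
        for sid, (mac, left, right) in zip(
            ["d5_r1", "d5_r2", "d5_r3"], [(80, 20, 20), (70, 30, 30), (60, 40, 40)]
        ):
            rows.append((sid, "a", mac, left, right))
            rows.append((sid, "b", 50, 25, 25))  # identical across replicates
        for sid in ("d14_r1", "d14_r2", "d14_r3"):
            rows.append((sid, "a", 70, 15, 15))
            rows.append((sid, "b", 50, 25, 25))
        cohort = _cohort(rows, samples)
        sd, ratios = at.dispersion_stats(cohort)
        assert sd.loc["a", "d5"] == pytest.approx(0.1)
        # locus b: identical replicates -> SD 0 -> dropped from ratios
        assert sd.loc["b", "d5"] == 0.0
        assert "b" not in set(ratios["locus_id"])

    def test_identical_samples_not_significant(self):
        a = np.linspace(0.01, 0.2, 40)
        res = at.compare_dispersion(a, a.copy(), paired=True)
        assert res.p_value >= 0.5
        assert res.effect_size_r == pytest.approx(0.0, abs=1e-9)

    def test_shifted_sample_detected_at_n75(self):
        rng = np.random.default_rng(44)
        a = np.abs(rng.normal(0.05, 0.02, 75))
        b = a * 1.4 + rng.normal(0, 0.005, 75)
        res = at.compare_dispersion(a, b, paired=True)
        assert res.p_value < 0.05
        assert res.effect_size_r > 0.2
        assert res.n == 75

    def test_unpaired_comparison_pools_sizes(self):
        rng = np.random.default_rng(45)
        a = np.abs(rng.normal(0.05, 0.02, 75))     # observed dispersion
        b = np.abs(rng.normal(0.02, 0.01, 1196))   # error distribution
        res = at.compare_dispersion(b, a, paired=False)
        assert res.n == 75 + 1196
        assert res.p_value < 0.05  # observed larger than error

    def test_underpowered_warning(self):
        with pytest.warns(UserWarning):
            at.compare_dispersion([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], paired=True)

    def test_comparisons_table_bh_adjusted(self, haploid_model):
        cohort = at.evolve_cohort(
            haploid_model, np.full(150, 0.5), [17, 35, 49], 4, depth_model=300, seed=46
        )
        ts = at.select_track_set(cohort)
        sd, _ = at.dispersion_stats(cohort, ts)
        tests = at.track.dispersion_comparisons(sd)
        assert len(tests) == 3
        assert (tests["p_adj"] >= tests["p_value"] - 1e-12).all()
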