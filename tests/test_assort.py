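"""Assortment kernels, closed forms, switch probabilities, culture regimes."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

import amitrace as at
from amitrace.assort import division_kernel, sample_division


def enumerate_haploid(k, m):
    """Brute-force single division: 2m of 2k labelled subunits, daughter draws k."""
    counts = Counter()
    labels = [1] * (2 * m) + [0] * (2 * k - 2 * m)
    for combo in itertools.combinations(range(2 * k), k):
        counts[sum(labels[i] for i in combo)] += 1
    total = sum(counts.values())
    return {mp: c / total for mp, c in counts.items()}


def enumerate_chromosomal(k, m):
    """Brute force: halve k G1 copies without replacement, then re-replicate."""
    counts = Counter()
    labels = [1] * m + [0] * (k - m)
    for combo in itertools.combinations(range(k), k // 2):
        counts[2 * sum(labels[i] for i in combo)] += 1
    total = sum(counts.values())
    return {mp: c / total for mp, c in counts.items()}


class TestModels:
    def test_variance_constants(self):
        assert at.build_model("haploid", 860).variance_constant_c == pytest.approx(1 / 1719)
        assert at.build_model("chromosomal", 860).variance_constant_c == pytest.approx(1 / 859)
        assert at.build_model("diploid", 860).variance_constant_c == 0.0

    def test_odd_or_tiny_ploidy_rejected(self):
        with pytest.raises(ValueError):
            at.build_model("haploid", 861)
        with pytest.raises(ValueError):
            at.build_model("haploid", 0)
        with pytest.raises(ValueError):
            at.build_model("triploid", 860)

    def test_diploid_never_assorts(self):
        d = at.build_model("diploid", 20)
        dist = at.propagate(d, 0.5, 100)
        assert dist.sigma() == 0.0
        assert at.sigma_analytic(d, 0.5, 1000) == 0.0


class TestKernel:
    def test_haploid_k4_exact_probabilities(self):
        K = division_kernel(at.build_model("haploid", 4))
        row = K[2]
        assert row[2] == pytest.approx(18 / 35)
        assert row[1] == pytest.approx(8 / 35)
        assert row[3] == pytest.approx(8 / 35)
        assert row[0] == pytest.approx(1 / 70)
        assert row[4] == pytest.approx(1 / 70)

    @pytest.mark.parametrize("k", [2, 4, 8])
    @pytest.mark.parametrize("kind,oracle", [
        ("haploid", enumerate_haploid), ("chromosomal", enumerate_chromosomal)
    ])
    def test_kernel_matches_brute_force(self, k, kind, oracle):
        K = division_kernel(at.build_model(kind, k))
        for m in range(k + 1):
            expected = oracle(k, m)
            for mp in range(k + 1):
                assert K[m, mp] == pytest.approx(expected.get(mp, 0.0), abs=1e-12)

    @pytest.mark.parametrize("kind", ["haploid", "chromosomal", "diploid"])
    def test_rows_are_martingale_and_stochastic(self, kind):
        k = 8
        K = division_kernel(at.build_model(kind, k))
        states = np.arange(k + 1)
        assert np.allclose(K.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(K @ states, states, atol=1e-10)

    def test_absorbing_boundaries(self):
        K = division_kernel(at.build_model("haploid", 6))
        assert K[0, 0] == pytest.approx(1.0)
        assert K[6, 6] == pytest.approx(1.0)


class TestPropagate:
    def test_zero_generations_point_mass(self):
        dist = at.propagate(at.build_model("haploid", 10), 0.5, 0)
        assert dist.probabilities[5] == 1.0

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError):
            at.propagate(at.build_model("haploid", 10), 0.5, -1)

    @pytest.mark.parametrize("gens", [1, 10, 100])
    def test_variance_matches_closed_form(self, gens):
        model = at.build_model("haploid", 60)
        dist = at.propagate(model, 0.4, gens)
        assert dist.sigma() ** 2 == pytest.approx(
            at.sigma_analytic(model, 0.4, gens) ** 2, abs=1e-9
        )

    def test_sigma_200_generations_closed_form(self, haploid_dist_200, haploid_model):
        expected = math.sqrt(0.25 * (1 - (1 - 1 / 1719) ** 200))
        assert haploid_dist_200.sigma() == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.1657, abs=2e-4)
        assert at.sigma_analytic(haploid_model, 0.5, 200) == pytest.approx(expected)


class TestSigmaAnalytic:
    def test_zero_generations(self, haploid_model):
        assert at.sigma_analytic(haploid_model, 0.3, 0) == 0.0

    def test_symmetric_in_irs0(self, haploid_model):
        for g in (1, 31, 200):
            assert at.sigma_analytic(haploid_model, 0.1, g) == pytest.approx(
                at.sigma_analytic(haploid_model, 0.9, g)
            )

    def test_value_at_31_generations(self, haploid_model):
        assert at.sigma_analytic(haploid_model, 0.5, 31) == pytest.approx(0.0668, abs=5e-4)

    def test_rate_peaks_at_half(self, haploid_model):
        grid = np.round(np.arange(0.1, 0.91, 0.1), 2)
        rates = at.sigma_rate(haploid_model, grid, 50)
        assert np.argmax(rates) == list(grid).index(0.5)


class TestHeterozygosityAndSwitch:
    def test_pure_start_has_no_heterozygosity(self):
        dist = at.propagate(at.build_model("haploid", 10), 1.0, 5)
        assert at.heterozygosity(dist) == pytest.approx(0.0, abs=1e-12)
        assert at.switch_fraction(dist) == pytest.approx(1.0, abs=1e-12)

    def test_switch_threshold_uses_ceiling(self):
        # ceil(0.85 * 860) = 731 copies: mass exactly at 731 counts, at 730 not
        k = 860
        p = np.zeros(k + 1)
        p[731] = 1.0
        d = at.CopyDistribution(p, generation=0, irs0=0.85)
        assert at.switch_fraction(d, 0.85) == 1.0
        p2 = np.zeros(k + 1)
        p2[730] = 1.0
        assert at.switch_fraction(at.CopyDistribution(p2, 0, 0.85), 0.85) == 0.0

    def test_multilocus_switch(self):
        assert at.multilocus_switch(0.3, 1) == pytest.approx(0.3)
        assert at.multilocus_switch(0.0, 100) == 0.0
        assert at.multilocus_switch(0.014, 50) == pytest.approx(0.506, abs=1e-3)

    def test_trajectory_monotonicity(self):
        traj = at.trajectory_stats(at.build_model("haploid", 60), 0.5, 120)
        assert (np.diff(traj["sigma"]) >= -1e-12).all()
        assert (np.diff(traj["H"]) <= 1e-12).all()
        assert traj["H"].iloc[0] == 1.0


class TestSimulations:
    def test_isolation_zero_start_stays_zero(self, haploid_model):
        traj = at.simulate_isolation(haploid_model, 0.0, days=3, n_lines=32, seed=1)
        assert (traj["sigma"] == 0).all()
        assert (traj["H"] == 0).all()
        assert (traj["mean"] == 0).all()

    def test_mass_day_produces_16_cells_per_founder(self, haploid_model):
        traj = at.simulate_mass(haploid_model, 0.5, days=1, founders=2, seed=2)
        assert traj.loc[4, "n_cells"] == 2 * 16

    def test_sampler_matches_kernel_moments(self):
        model = at.build_model("chromosomal", 40)
        rng = np.random.default_rng(0)
        m = np.full(20_000, 10)
        out = sample_division(model, m, rng)
        assert out.mean() == pytest.approx(10, abs=0.1)
        var_frac = out.var() / 40**2
        expected = (10 / 40) * (30 / 40) / (40 - 1)
        assert var_frac == pytest.approx(expected, rel=0.05)

    def test_invalid_parameters_rejected(self, haploid_model):
        with pytest.raises(ValueError):
            at.simulate_isolation(haploid_model, 0.5, days=0)
        with pytest.raises(ValueError):
            at.simulate_mass(haploid_model, 0.5, days=1, founders=0)
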