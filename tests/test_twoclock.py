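import math

import numpy as np
import pandas as pd
import pytest

import synclock as sc
from synclock.errors import DomainError


def pair_table(si, ppm, clique="C1"):
    n = len(si)
    return pd.DataFrame({
        "genome_a": [f"a{i}" for i in range(n)],
        "genome_b": [f"b{i}" for i in range(n)],
        "si_distance": np.asarray(si, dtype=float),
        "ppm_distance": np.asarray(ppm, dtype=float),
        "clique_id": [clique] * n,
    })


class TestBuildPairTable:
    @pytest.fixture
    def matrices(self):
        si = sc.DistanceMatrix(("x", "y", "z"),
                               np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]))
        jc = sc.DistanceMatrix(("z", "y", "x"),
                               np.array([[0, .05, .04], [.05, 0, .01], [.04, .01, 0]]))
        return si, jc

    def test_three_genomes_three_rows(self, matrices):
        table = sc.build_pair_table(*matrices)
        assert len(table) == 3
        row = table[(table.genome_a == "x") & (table.genome_b == "y")].iloc[0]
        assert (row.si_distance, row.ppm_distance) == (0.1, 0.01)

    def test_clique_id_requires_shared_clique(self, matrices):
        partition = sc.CliquePartition(
            (("C1", ("x", "y")), ("C2", ("z",))), ())
        table = sc.build_pair_table(*matrices, partition)
        by_pair = {(r.genome_a, r.genome_b): r.clique_id for r in table.itertuples()}
        assert by_pair[("x", "y")] == "C1"
        assert by_pair[("x", "z")] is None
        assert by_pair[("y", "z")] is None

    def test_label_order_does_not_change_pair_set(self, matrices):
        si, jc = matrices
        t1 = sc.build_pair_table(si, jc)
        si2 = si.submatrix(("z", "x", "y"))
        t2 = sc.build_pair_table(si2, jc)
        key = lambda t: set(zip(t.genome_a, t.genome_b, t.si_distance, t.ppm_distance))
        assert key(t1) == key(t2)

    def test_no_shared_labels_error(self):
        si = sc.DistanceMatrix(("a", "b"), np.array([[0, .1], [.1, 0]]))
        jc = sc.DistanceMatrix(("c", "d"), np.array([[0, .1], [.1, 0]]))
        with pytest.raises(ValueError, match="shared"):
            sc.build_pair_table(si, jc)


class TestPMTHRegression:
    def test_exact_linear_relation_recovers_slope(self):
        x = np.linspace(0.01, 0.7, 100)
        res = sc.pmth_regression(pair_table(x, 0.14 * x))
        assert res.slope == pytest.approx(0.14)
        assert res.r_squared == pytest.approx(1.0)
        assert res.pmth_ratio == pytest.approx(1 / 0.14)
        assert res.ci95[0] <= res.slope <= res.ci95[1]
        assert res.df == 99

    def test_filter_counts_removed_pairs(self):
        x = np.linspace(0.01, 0.7, 100)
        y = 0.14 * x
        y[:10] = 0.2  # above the 0.1 gene-distance cutoff
        res = sc.pmth_regression(pair_table(x, y))
        assert res.n_filtered == 10

    def test_pairs_outside_cliques_ignored(self):
        x = np.linspace(0.01, 0.7, 50)
        table = pair_table(x, 0.14 * x)
        noise = pair_table(x, np.ones(50), clique=None)
        noise["clique_id"] = None
        res = sc.pmth_regression(pd.concat([table, noise], ignore_index=True))
        assert res.slope == pytest.approx(0.14)

    def test_through_origin_slope_is_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.05, 0.5, 40)
        y = 0.2 * x + rng.normal(0, 0.01, 40)
        res = sc.pmth_regression(pair_table(x, y), ppm_filter=10.0)
        assert res.slope == pytest.approx(np.sum(x * y) / np.sum(x * x))

    def test_orientation_flip_inverts_exact_slope(self):
        x = np.linspace(0.01, 0.7, 50)
        res = sc.pmth_regression(pair_table(x, 0.14 * x), orientation="gr_on_ppm")
        assert res.slope == pytest.approx(1 / 0.14)

    def test_intercept_option(self):
        x = np.linspace(0.01, 0.7, 50)
        res = sc.pmth_regression(pair_table(x, 0.05 + 0.14 * x), through_origin=False,
                                 ppm_filter=10.0)
        assert res.slope == pytest.approx(0.14)

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError, match="usable"):
            sc.pmth_regression(pair_table([0.1, 0.2], [0.01, 0.02]))

    def test_model_axis_recovers_planted_clock_ratio(self):
        """CI-level recovery of a planted ratio on model-consistent tables.

        SI distances are generated from the closed form so its inversion is
        exact; the noisy point-mutation distances have expectation x/7.
        With 100 seeded runs the planted ratio must fall inside the
        regression's own 95% CI in at least 90 of them.
        """
        params = sc.ModelParams(n=500, k=10)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p_events = rng.integers(10, 100, size=60)
            si = np.array([sc.expected_si(float(p), params) for p in p_events])
            x = p_events / params.n
            y = x / 7.0 * (1 + rng.normal(0, 0.15, size=60))
            res = sc.pmth_regression(pair_table(si, y), gene_order_model=params)
            lo, hi = 1 / res.ci95[1], 1 / res.ci95[0]
            hits += lo <= 7.0 <= hi
        assert hits >= 90


class TestExponentialFit:
    def test_exact_recovery(self):
        si = np.linspace(0.1, 1.0, 60)
        fit = sc.fit_exponential(pair_table(si, 5e-5 * np.exp(8.3704 * si)))
        assert fit.A == pytest.approx(5e-5, rel=1e-6)
        assert fit.B == pytest.approx(8.3704, rel=1e-6)
        assert not fit.degenerate

    def test_constant_data_flagged_degenerate(self):
        si = np.linspace(0.1, 1.0, 30)
        fit = sc.fit_exponential(pair_table(si, np.full(30, 0.2)))
        assert abs(fit.B) < 1e-8
        assert fit.degenerate

    def test_noisy_recovery_within_5_percent(self):
        rng = np.random.default_rng(9)
        si = rng.uniform(0.0, 1.0, 500)
        ppm = 0.01 * np.exp(2.0 * si) * (1 + rng.normal(0, 0.01, 500))
        fit = sc.fit_exponential(pair_table(si, ppm))
        assert fit.A == pytest.approx(0.01, rel=0.05)
        assert fit.B == pytest.approx(2.0, rel=0.05)

    def test_scale_equivariance(self):
        si = np.linspace(0.1, 1.0, 40)
        ppm = 0.02 * np.exp(3.0 * si)
        f1 = sc.fit_exponential(pair_table(si, ppm))
        f2 = sc.fit_exponential(pair_table(si, 10 * ppm))
        assert f2.A == pytest.approx(10 * f1.A, rel=1e-9)
        assert f2.B == pytest.approx(f1.B, rel=1e-9)

    def test_nonpositive_rows_excluded(self):
        si = np.linspace(0.1, 1.0, 40)
        ppm = 0.01 * np.exp(2.0 * si)
        ppm[0] = 0.0
        fit = sc.fit_exponential(pair_table(si, ppm))
        assert fit.B == pytest.approx(2.0, rel=1e-6)

    def test_too_few_positive_rows_error(self):
        with pytest.raises(ValueError, match="positive"):
            sc.fit_exponential(pair_table([0.1, 0.2, 0.3], [0.0, 0.0, 0.1]))

    def test_nls_refinement_matches_on_noiseless_data(self):
        si = np.linspace(0.1, 1.0, 60)
        table = pair_table(si, 5e-5 * np.exp(8.3704 * si))
        fit = sc.fit_exponential(table, method="nls")
        assert fit.B == pytest.approx(8.3704, rel=1e-5)


class TestDerivativeUnityPoint:
    def test_fitted_curve_coefficients(self):
        fit = sc.ExponentialFit(A=5e-5, B=8.3704, residual_sse=0.0)
        assert round(sc.derivative_unity_point(fit), 4) == 0.9293

    def test_unit_coefficients(self):
        assert sc.derivative_unity_point(
            sc.ExponentialFit(A=1.0, B=1.0, residual_sse=0.0)) == 0.0

    def test_defining_equation_holds(self):
        fit = sc.ExponentialFit(A=0.003, B=4.2, residual_sse=0.0)
        x = sc.derivative_unity_point(fit)
        assert fit.A * fit.B * math.exp(fit.B * x) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_product_rejected(self):
        with pytest.raises(DomainError):
            sc.derivative_unity_point(sc.ExponentialFit(A=0.1, B=-2.0, residual_sse=0.0))


class TestElasticity:
    def test_moving_average(self):
        np.testing.assert_allclose(sc.moving_average(np.array([1, 2, 3, 4]), 3), [2, 3])

    def test_proportional_data_has_unit_elasticity(self):
        # 50 points per bin exactly, offset half a step so no point sits on a
        # bin boundary: binned means stay equally spaced
        si = 0.1 + (np.arange(800) + 0.5) * 0.001
        curve = sc.elasticity_curve(pair_table(si, 3.0 * si), bin_width=0.05)
        np.testing.assert_allclose(curve.elasticity, 1.0, rtol=1e-6)

    def test_power_law_elasticity_is_reciprocal_exponent(self):
        si = np.linspace(0.2, 1.0, 2000)
        curve = sc.elasticity_curve(pair_table(si, 2.0 * si ** 4), bin_width=0.02)
        assert np.median(curve.elasticity) == pytest.approx(0.25, rel=0.05)

    def test_unity_crossing_by_interpolation(self):
        curve = sc.ElasticityCurve(
            bin_centers=np.array([0.4, 0.6, 0.8, 1.0]),
            smoothed_ppm=np.array([0.1, 0.2, 0.3, 0.4]),
            elasticity=np.array([3.0, 2.0, 0.5]),
        )
        # crossing between midpoints 0.7 and 0.9, fraction (2-1)/(2-0.5)
        assert sc.elasticity_unity_point(curve) == pytest.approx(0.7 + 0.2 * 2 / 3)

    @pytest.mark.parametrize("elasticity", [[3.0, 2.0, 1.5], [0.5, 0.4, 0.3]])
    def test_no_crossing_returns_none(self, elasticity):
        curve = sc.ElasticityCurve(
            bin_centers=np.array([0.4, 0.6, 0.8, 1.0]),
            smoothed_ppm=np.array([0.1, 0.2, 0.3, 0.4]),
            elasticity=np.array(elasticity),
        )
        assert sc.elasticity_unity_point(curve) is None

    def test_too_few_bins_error(self):
        with pytest.raises(ValueError, match="bins"):
            sc.elasticity_curve(pair_table([0.1, 0.5, 0.9], [1, 2, 3]), bin_width=0.5)

    def test_crossing_points_concordant_on_phase_transition_data(self):
        """Derivative-of-fit and elasticity locate the same transition.

        Flat-then-exponential data with pair density concentrated on the
        steep flank (as in real two-clock pair data, where the vast majority
        of pairs are between distant genomes): the two independently defined
        crossing points agree to within 0.02 SI.
        """
        B, s0 = 12.0, 0.6
        A = (1.0 / B) * math.exp(-B * s0)
        c = (1.0 / B) * math.exp(-0.2 * s0)
        si = np.concatenate([
            np.linspace(0.2, s0, 34, endpoint=False),   # sparse pre-transition
            np.linspace(s0, 1.0, 966),                  # dense saturated flank
        ])
        ppm = np.where(si < s0, c * np.exp(0.2 * si), A * np.exp(B * si))
        table = pair_table(si, ppm)
        d = sc.derivative_unity_point(sc.fit_exponential(table))
        e = sc.elasticity_unity_point(sc.elasticity_curve(table))
        assert e is not None
        assert abs(d - e) <= 0.02
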