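"""Distribution fitting, seeded simulation, percentiles and risk curves."""

import numpy as np
import pandas as pd
import pytest

import breadrisk as br
from breadrisk.montecarlo import cumulative_curve, percentile


class TestFitDistribution:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(314)
        x = rng.lognormal(0.0, 1.0, size=10_000)
        spec = br.fit_distribution(x, "lognormal")
        assert spec.params[0] == pytest.approx(0.0, abs=0.05)
        assert spec.params[1] == pytest.approx(1.0, abs=0.05)

    def test_point_mass_at_constant(self):
        spec = br.fit_distribution([2.5] * 6, "point")
        assert spec.family == "point" and spec.params == (2.5,)
        assert not spec.is_stochastic

    def test_lognormal_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            br.fit_distribution([1.0, 2.0, 0.0, 3.0, 4.0], "lognormal")

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 5"):
            br.fit_distribution([1.0, 2.0], "normal")

    def test_uniform_fit_spans_sample(self):
        spec = br.fit_distribution([1.0, 4.0, 2.0, 3.0, 2.5], "uniform")
        assert spec.params == (1.0, 4.0)

    def test_censored_values_resolved_before_fit(self):
        x = [1.0, 2.0, 3.0, 4.0, np.nan, np.nan]
        censored = [False] * 4 + [True] * 2
        lods = [0.1] * 6
        spec = br.fit_distribution(x, "normal", censored=censored, lods=lods,
                                   policy=br.CensorPolicy.HALF_LOD)
        assert spec.params[0] == pytest.approx(np.mean([1, 2, 3, 4, .05, .05]))

    def test_dist_spec_validation(self):
        with pytest.raises(ValueError, match="lower <= mode"):
            br.DistSpec("x", "triangular", (0.0, 2.0, 1.0))
        with pytest.raises(ValueError, match="family"):
            br.DistSpec("x", "beta", (1.0, 1.0))


class TestSimulateRisk:
    def _point_setup(self, study, defaults):
        cdi = br.mean_cdi_by_element(study, {"adult": defaults.adult})
        pooled = cdi.groupby("element")["mean_concentration_mg_kg"].mean()
        return {el: br.DistSpec(f"C_{el}", "point", (float(v),))
                for el, v in pooled.items()}

    def test_point_masses_reproduce_deterministic_risk_exactly(self, study,
                                                               defaults):
        """Degenerate distributions collapse the simulation to the point
        estimate: every draw equals the deterministic HI/TCR bit-exactly."""
        dists = self._point_setup(study, defaults)
        pooled = {el: spec.params[0] for el, spec in dists.items()}
        tox = br.builtin_defaults().tox
        det_hi = br.hazard_index(
            [br.chronic_daily_intake(pooled[el], defaults.adult) / tox[el].rfd
             for el in sorted(pooled) if tox[el].rfd is not None])
        det_tcr = br.total_cancer_risk(
            [br.chronic_daily_intake(pooled[el], defaults.adult) * tox[el].osf
             for el in sorted(pooled) if tox[el].osf is not None])
        for n in (1, 7, 500):
            mc = br.simulate_risk(dists, tox, {"adult": defaults.adult},
                                  n=n, seed=11)
            assert (mc.hi("adult") == det_hi).all()
            assert (mc.tcr("adult") == det_tcr).all()
            assert percentile(mc.hi("adult"), 0.95) == det_hi

    def test_same_seed_is_bit_identical(self, study, defaults):
        dists = br.default_concentration_dists(study)
        tox = br.builtin_defaults().tox
        a = br.simulate_risk(dists, tox, {"adult": defaults.adult}, n=200, seed=5)
        b = br.simulate_risk(dists, tox, {"adult": defaults.adult}, n=200, seed=5)
        for key in a.outputs:
            assert (a.outputs[key] == b.outputs[key]).all()
        c = br.simulate_risk(dists, tox, {"adult": defaults.adult}, n=200, seed=6)
        assert not (a.hi("adult") == c.hi("adult")).all()

    def test_unknown_parameter_distribution_named(self, study, defaults):
        dists = br.default_concentration_dists(study)
        with pytest.raises(ValueError, match="adult.XX"):
            br.simulate_risk(dists, br.builtin_defaults().tox,
                             {"adult": defaults.adult}, n=10, seed=0,
                             param_dists={"adult.XX": br.DistSpec(
                                 "adult.XX", "point", (1.0,))})

    def test_missing_concentration_distributions_rejected(self, defaults):
        with pytest.raises(ValueError, match="no concentration"):
            br.simulate_risk({}, br.builtin_defaults().tox,
                             {"adult": defaults.adult}, n=10, seed=0)

    def test_single_stochastic_input_sd_matches_large_n_oracle(self, defaults):
        """Lognormal arsenic with all other inputs fixed: sd(HI) agrees with
        an independent million-draw oracle within 3 Monte Carlo SEs."""
        tox = br.builtin_defaults().tox
        mu, sigma = np.log(1.0), 0.2936  # cv ~ 0.30
        dists = {"As": br.DistSpec("C_As", "lognormal", (mu, sigma)),
                 "Fe": br.DistSpec("C_Fe", "point", (20.0,))}
        n = 10_000
        mc = br.simulate_risk(dists, tox, {"adult": defaults.adult},
                              n=n, seed=21)
        sd_hat = mc.hi("adult").std(ddof=1)

        oracle_rng = np.random.default_rng(987_654)
        factor = br.chronic_daily_intake(1.0, defaults.adult)
        oracle_hi = (oracle_rng.lognormal(mu, sigma, size=1_000_000)
                     * factor / tox["As"].rfd)
        sd_oracle = oracle_hi.std(ddof=1)
        # MC standard error of a sample sd, normal approximation
        se = sd_oracle / np.sqrt(2 * (n - 1))
        assert abs(sd_hat - sd_oracle) < 3 * se


class TestPercentileAndCurve:
    def test_point_mass_quantiles(self):
        x = np.full(100, 3.25)
        for q in (0.05, 0.5, 0.95):
            assert percentile(x, q) == 3.25

    def test_standard_normal_p95(self):
        rng = np.random.default_rng(2024)
        x = rng.normal(0, 1, size=100_000)
        assert percentile(x, 0.95) == pytest.approx(1.645, abs=0.02)

    def test_small_sample_median(self):
        assert percentile([1, 2, 3, 4, 5], 0.5) == 3.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            percentile([], 0.5)
        with pytest.raises(ValueError, match="between"):
            percentile([1.0], 1.0)

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1, 1000)
        qs = np.linspace(0.01, 0.99, 25)
        vals = [percentile(x, q) for q in qs]
        assert (np.diff(vals) >= 0).all()

    def test_curve_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(4)
        values, probs = cumulative_curve(rng.normal(size=333))
        assert probs[0] == 0.0 and probs[-1] == 1.0
        assert (np.diff(probs) >= 0).all()
        assert (np.diff(values) >= 0).all()

    def test_point_mass_is_step_function(self):
        values, probs = cumulative_curve([2.0, 2.0, 2.0])
        assert (values == 2.0).all()
        assert probs[0] == 0.0 and probs[-1] == 1.0

    def test_mixture_identity(self):
        """The ECDF of a concatenation is the half-weight average of the two
        sample ECDFs (equal sizes)."""
        rng = np.random.default_rng(8)
        a, b_ = rng.normal(0, 1, 400), rng.normal(2, 1, 400)
        both = np.concatenate([a, b_])

        def ecdf(sample, at):
            return np.searchsorted(np.sort(sample), at, side="right") / sample.size

        grid = np.linspace(-3, 5, 101)
        np.testing.assert_allclose(
            ecdf(both, grid), (ecdf(a, grid) + ecdf(b_, grid)) / 2, atol=1e-12)
        # and the curve of the concatenation reproduces those ECDF values
        values, probs = cumulative_curve(both)
        for x, p in zip(values[1:], probs[1:]):
            assert p == pytest.approx(ecdf(both, x), abs=1e-9)
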