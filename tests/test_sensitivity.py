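"""LHS designs, regression layer, and dose–response fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcisim.params import ParameterSet, ParameterSpec, table1_specs
from dcisim.sensitivity import (DESK_PROFILE, ScaleProfile, fit_linear_origin,
                                fit_michaelis_menten, lhs_design,
                                multivariate_ols, run_study)

UNIT = ParameterSpec("u", "uniform", 0.5, low=0.0, high=1.0)


class TestLHS:
    def test_one_draw_per_decile(self):
        d = lhs_design([UNIT], 10, seed=0)
        strata = np.sort(np.floor(d["u"].to_numpy() * 10).astype(int))
        assert strata.tolist() == list(range(10))

    def test_n2_splits_at_median(self):
        spec = table1_specs()["theta_e"]  # lognormal column
        d = lhs_design([spec], 2, seed=1)
        from dcisim.params import lognormal_underlying
        mu, sig = lognormal_underlying(spec.mean, spec.spread)
        median = np.exp(mu)
        v = np.sort(d["theta_e"].to_numpy())
        assert v[0] < median < v[1]

    def test_every_column_stratified(self):
        specs = {k: v for k, v in table1_specs().items() if not v.integer}
        n = 16
        d = lhs_design(specs, n, seed=3)
        for name, spec in specs.items():
            u = _quantiles(spec, d[name].to_numpy())
            strata = np.sort(np.floor(u * n).astype(int))
            assert strata.tolist() == list(range(n)), name

    def test_integer_columns_in_range(self):
        spec = table1_specs()["p_max"]
        d = lhs_design([spec], 20, seed=4)
        v = d["p_max"].to_numpy()
        assert np.issubdtype(v.dtype, np.integer)
        assert v.min() >= 11 and v.max() <= 25

    def test_stratum_uniformity_chi2(self):
        # positions of the draw inside each stratum are uniform across designs
        n = 10
        us = []
        for seed in range(300):
            d = lhs_design([UNIT], n, seed=seed)
            us.extend((d["u"].to_numpy() * n) % 1.0)
        counts, _ = np.histogram(us, bins=10, range=(0, 1))
        chi2 = ((counts - len(us) / 10) ** 2 / (len(us) / 10)).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=9)

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            lhs_design([UNIT], 1, seed=0)


def _quantiles(spec, values):
    from dcisim.params import lognormal_underlying
    if spec.distribution == "uniform":
        return (values - spec.low) / (spec.high - spec.low)
    mu, sig = lognormal_underlying(spec.mean, spec.spread)
    return stats.lognorm.cdf(values, sig, scale=np.exp(mu))


class TestOLS:
    def test_exact_linear_relation(self, rng):
        x = rng.normal(size=(50, 1))
        d = pd.DataFrame({"x1": x[:, 0]})
        res = multivariate_ols(d, 3.0 + 2.0 * x[:, 0], "y")
        assert res.r_squared == pytest.approx(1.0)
        assert res.table.loc["x1", "coef"] == pytest.approx(2.0)
        assert res.significant == ["x1"]

    def test_matches_closed_form_normal_equations(self, rng):
        n = 40
        X = rng.normal(size=(n, 2))
        y = 1.0 + 0.7 * X[:, 0] - 1.3 * X[:, 1] + rng.normal(0, 0.5, n)
        d = pd.DataFrame(X, columns=["a", "b"])
        res = multivariate_ols(d, y, "y")
        Xd = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert res.table.loc["a", "coef"] == pytest.approx(beta[1], abs=1e-10)
        assert res.table.loc["b", "coef"] == pytest.approx(beta[2], abs=1e-10)

    def test_independent_output_has_low_r2(self, rng):
        n = 2000
        d = pd.DataFrame({"x": rng.normal(size=n)})
        res = multivariate_ols(d, rng.normal(size=n), "y")
        assert res.r_squared < 0.01

    def test_standardized_effects_are_unitless(self, rng):
        n = 200
        x = rng.normal(size=n)
        d1 = pd.DataFrame({"x": x})
        d2 = pd.DataFrame({"x": 1000.0 * x})  # same design, different units
        y = 2.0 * x + rng.normal(0, 0.1, n)
        e1 = multivariate_ols(d1, y, "y").table.loc["x", "std_effect"]
        e2 = multivariate_ols(d2, y, "y").table.loc["x", "std_effect"]
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=20)
        d = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError):
            multivariate_ols(d, x, "y")


class TestMichaelisMenten:
    def test_noiseless_recovery_to_four_digits(self):
        from dcisim.io import make_fixture
        x, y = make_fixture("mm-curve")
        fit = fit_michaelis_menten(x, y)
        assert fit.params["v_max"] == pytest.approx(13.74, rel=1e-4)
        assert fit.params["k_m"] == pytest.approx(0.0262, rel=1e-4)
        assert fit.r_squared > 0.999999

    def test_constant_response_hits_boundary(self):
        x = np.array([0.1, 0.2, 0.5, 1.0])
        fit = fit_michaelis_menten(x, np.full(4, 7.0))
        assert fit.params["v_max"] == pytest.approx(7.0, rel=0.01)
        assert fit.params["k_m"] < 1e-5

    def test_noisy_recovery_within_spread(self, rng):
        x = np.array([0.0001, 0.00025, 0.0005, 0.001, 0.0025, 0.005,
                      0.0075, 0.01])
        truth = 13.74 * x / (0.0262 + x)
        vm = []
        for _ in range(100):
            y = truth * (1 + rng.normal(0, 0.05, len(x)))
            vm.append(fit_michaelis_menten(x, y).params["v_max"])
        assert np.median(vm) == pytest.approx(13.74, rel=0.15)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([0.1, 0.1], [1.0, 1.0])


class TestLinearOrigin:
    def test_exact_proportionality(self):
        x = np.array([0.01, 0.1, 0.5, 1.0])
        fit = fit_linear_origin(x, 0.189 * x)
        assert fit.params["slope"] == pytest.approx(0.189)
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_response(self):
        assert fit_linear_origin([1.0, 2.0], [0.0, 0.0]).params["slope"] == 0.0

    def test_matches_formula_oracle(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        fit = fit_linear_origin(x, y)
        assert fit.params["slope"] == pytest.approx(
            float(np.sum(x * y) / np.sum(x * x)), abs=1e-12)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_origin([0.0, 0.0], [1.0, 2.0])


SMOKE_PROFILE = ScaleProfile("smoke", duct_length=200.0,
                             duct_inner_diameter=60.0, grid_h=10.0,
                             t_end_days=2.0, analysis_t_min=0.5)


class TestStudies:
    def test_local_sweep_plumbing(self, baseline):
        res = run_study("dediff_local", 0, seed=9, profile=SMOKE_PROFILE,
                        sweep_pct=(0.1, 0.5, 1.0), n_replicates=2)
        assert len(res.runs) == 6
        assert set(res.fits) == {"summary", "michaelis_menten",
                                 "linear_origin"}
        assert (res.runs.groupby("omega_dd_pct").size() == 2).all()

    def test_global_study_design_and_outputs(self, baseline):
        res = run_study("no_dediff_global", 4, seed=9, profile=SMOKE_PROFILE)
        assert len(res.design) == 4
        from dcisim.params import GLOBAL_STUDY_PARAMS
        assert set(GLOBAL_STUDY_PARAMS) <= set(res.design.columns)
        # the dedifferentiation pathway is off in study 1
        assert "omega_dd" not in res.design.columns
        assert "advance_rate_um_d" in res.runs.columns

    def test_dediff_study_perturbs_reduced_set(self, baseline):
        res = run_study("dediff_global", 4, seed=10, profile=SMOKE_PROFILE)
        from dcisim.params import DEDIFF_STUDY_PARAMS
        assert set(DEDIFF_STUDY_PARAMS) == set(res.design.columns) - {"seed"}
        assert (res.design["omega_dd"] > 0).all()
        assert "tau_p" not in res.design.columns  # excluded from study 2

    def test_unknown_study_rejected(self):
        with pytest.raises(ValueError):
            run_study("bogus", 4, seed=0)
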