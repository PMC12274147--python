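import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ipsipanel as ip
from ipsipanel.propensity import propensity_terms
from ipsipanel.synthetic import LCoef, XCoef, YCoef, SyntheticConfig

from conftest import make_panel_with_pi


class TestShift:
    def test_identity_at_one(self):
        pis = np.linspace(0, 1, 21)
        np.testing.assert_allclose(ip.shift(pis, 1.0), pis, atol=0)

    def test_direct_evaluation(self):
        assert ip.shift(0.2, 4.0) == pytest.approx(0.5, abs=1e-15)
        assert ip.shift(0.5, 1.0) == pytest.approx(0.5, abs=0)

    def test_boundary_preserved(self):
        for d in (1 / 512, 0.3, 1.0, 7.0, 512.0):
            assert ip.shift(0.0, d) == 0.0
            assert ip.shift(1.0, d) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ip.shift(0.5, 0.0)
        with pytest.raises(ValueError):
            ip.shift(0.5, -2.0)
        with pytest.raises(ValueError):
            ip.shift(1.5, 2.0)

    @given(pi=st.floats(1e-6, 1 - 1e-6), d1=st.floats(0.01, 100), d2=st.floats(0.01, 100))
    @settings(max_examples=200, deadline=None)
    def test_odds_multiplicativity(self, pi, d1, d2):
        assert ip.shift(pi, d1 * d2) == pytest.approx(
            ip.shift(ip.shift(pi, d1), d2), rel=1e-9)

    @given(pi=st.floats(0.001, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_delta(self, pi):
        grid = [0.1, 0.5, 1.0, 2.0, 10.0]
        vals = [ip.shift(pi, d) for d in grid]
        assert np.all(np.diff(vals) > 0)


class TestImpliedDelta:
    def test_odds_ratio_arithmetic(self):
        assert ip.implied_delta(0.5, 0.2) == pytest.approx(4.0, rel=1e-12)

    def test_identity(self):
        assert ip.implied_delta(0.37, 0.37) == pytest.approx(1.0, rel=1e-12)

    def test_roundtrip(self):
        d = 2.0 ** -3
        assert ip.implied_delta(ip.shift(0.37, d), 0.37) == pytest.approx(d, rel=1e-12)

    @given(pi=st.floats(1e-5, 1 - 1e-5), d=st.floats(0.001, 1000))
    @settings(max_examples=200, deadline=None)
    def test_inverse_property(self, pi, d):
        # tolerance reflects cancellation in 1-q when the shift saturates
        assert ip.implied_delta(ip.shift(pi, d), pi) == pytest.approx(d, rel=1e-6)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            ip.implied_delta(0.0, 0.5)
        with pytest.raises(ValueError):
            ip.implied_delta(0.5, 1.0)


class TestDeltaGrid:
    def test_default_grid(self):
        g = ip.default_delta_grid()
        assert len(g) == 19
        vals = list(g)
        assert vals[0] == pytest.approx(1 / 512)
        assert vals[9] == 1.0
        assert vals[-1] == 512.0

    def test_log_symmetry(self):
        vals = list(ip.default_delta_grid())
        for i in range(19):
            assert vals[i] * vals[18 - i] == pytest.approx(1.0, rel=1e-12)

    def test_invalid_grids(self):
        with pytest.raises(ValueError):
            ip.DeltaGrid((1.0, 0.5))
        with pytest.raises(ValueError):
            ip.DeltaGrid((-1.0, 2.0))


class TestFitPropensity:
    def test_null_model_intercept(self):
        cfg = SyntheticConfig(n=2000, T=1, p_c=(0.5, 0.5),
                              coef_x=XCoef(intercept=np.log(0.6 / 0.4)),
                              coef_l=LCoef(sd=1.0), coef_y=YCoef(sd=1.0), seed=2)
        p = ip.generate_panel(cfg)
        fit = ip.fit_propensity(p, 1)
        coefs = fit.coefficients
        ses = dict(zip(fit.design.term_names, fit.se))
        assert abs(coefs["const"] - np.log(0.6 / 0.4)) < 3 * ses["const"]
        for name in fit.design.term_names:
            if name != "const":
                assert abs(coefs[name]) < 3 * ses[name]

    def test_score_identity(self, discrete_panel, discrete_fits):
        ps, _ = discrete_fits
        for fit, t in zip(ps, (1, 2)):
            assert fit.fitted_pi.mean() == pytest.approx(
                discrete_panel.x(t).mean(), abs=1e-8)

    def test_fitted_pi_interior(self, discrete_fits):
        for fit in discrete_fits[0]:
            assert np.all(fit.fitted_pi > 0)
            assert np.all(fit.fitted_pi < 1)

    def test_separation_fallback(self):
        # X_2 copies X_1 exactly: perfect separation at wave 2
        rng = np.random.default_rng(0)
        n = 200
        x1 = (rng.random(n) < 0.5).astype(float)
        df = pd.DataFrame({
            "id": np.arange(n), "c1": (rng.random(n) < 0.5).astype(float),
            "l_1": rng.standard_normal(n), "x_1": x1, "y_1": rng.standard_normal(n),
            "l_2": rng.standard_normal(n), "x_2": x1, "y_2": rng.standard_normal(n),
        })
        schema = ip.PanelSchema.from_dict({"id": "id", "T": 2, "C": ["c1"],
                                           "L": "l", "X": "x", "Y": "y"})
        p = ip.PanelDataset(df, schema)
        fit = ip.fit_propensity(p, 2)
        assert fit.regularization > 0
        assert np.all((fit.fitted_pi > 0) & (fit.fitted_pi < 1))

    def test_degenerate_exposure(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"id": range(50), "l_1": rng.standard_normal(50),
                           "x_1": np.ones(50), "y_1": rng.standard_normal(50)})
        schema = ip.PanelSchema.from_dict({"id": "id", "T": 1, "L": "l",
                                           "X": "x", "Y": "y"})
        p = ip.PanelDataset(df, schema)
        with pytest.raises(ip.DegenerateExposureError, match="wave 1"):
            ip.fit_propensity(p, 1)

    def test_coefficient_recovery(self):
        cfg = ip.discrete_config(n=20000, seed=13)
        p = ip.generate_panel(cfg)
        fit = ip.fit_propensity(p, 2)
        coefs, ses = fit.coefficients, dict(zip(fit.design.term_names, fit.se))
        b = cfg.coef_x
        truth = {"const": b.intercept, "c1": b.c[0], "l_2": b.l,
                 "x_1": b.x_prev, "y_1": b.y_prev}
        for name, tv in truth.items():
            assert abs(coefs[name] - tv) < 3 * ses[name], name

    def test_term_list_deterministic(self):
        terms = propensity_terms(["b", "a", "c"])
        assert terms[:3] == [("a",), ("b",), ("c",)]
        assert set(terms[3:]) == {("a", "b"), ("a", "c"), ("b", "c")}


class TestSummarizeShifted:
    def test_delta_one_matches_raw(self, discrete_panel, discrete_fits):
        ps, _ = discrete_fits
        df = ip.summarize_shifted(discrete_panel, ps, ip.DeltaGrid((0.5, 1.0, 2.0)))
        row = df[(df.t == 1) & (df.delta == 1.0)].iloc[0]
        pi = ps[0].fitted_pi
        assert row.mean_q == pytest.approx(pi.mean())
        assert row.p10 == pytest.approx(np.percentile(pi, 10))
        assert row.p90 == pytest.approx(np.percentile(pi, 90))

    def test_mean_nondecreasing_in_delta(self, discrete_panel, discrete_fits):
        ps, _ = discrete_fits
        df = ip.summarize_shifted(discrete_panel, ps)
        for t in (1, 2):
            means = df[df.t == t].sort_values("delta")["mean_q"].to_numpy()
            assert np.all(np.diff(means) >= -1e-12)

    def test_hand_enumeration(self, student_panel):
        # prescribed propensities, delta = 2, summaries by direct arithmetic
        pis = np.array([0.1, 0.2, 0.4, 0.5, 0.8, 0.9])
        fit = make_panel_with_pi(pis)
        df = ip.summarize_shifted(student_panel, [fit], ip.DeltaGrid((2.0,)))
        q = 2 * pis / (1 + pis)
        row = df.iloc[0]
        assert row.mean_q == pytest.approx(q.mean())
        assert row.p10 == pytest.approx(np.percentile(q, 10))
        assert row.p90 == pytest.approx(np.percentile(q, 90))
        assert row.frac_above == pytest.approx(np.mean(q > 0.05))


class TestOverlapDiagnostics:
    def test_constant_pi_full_overlap(self):
        # every (past-stratum, current-group) cell populated, constant pi
        rng = np.random.default_rng(8)
        n = 400
        df = pd.DataFrame({"id": range(n),
                           "l_1": rng.standard_normal(n),
                           "x_1": (rng.random(n) < 0.5).astype(float),
                           "y_1": rng.standard_normal(n),
                           "l_2": rng.standard_normal(n),
                           "x_2": (rng.random(n) < 0.5).astype(float),
                           "y_2": rng.standard_normal(n)})
        schema = ip.PanelSchema.from_dict({"id": "id", "T": 2, "L": "l",
                                           "X": "x", "Y": "y"})
        p = ip.PanelDataset(df, schema)
        fit = make_panel_with_pi(np.full(n, 0.5))
        fit = ip.PropensityFit(t=2, design=fit.design, coef=fit.coef, se=fit.se,
                               fitted_pi=fit.fitted_pi)
        diag = ip.overlap_diagnostics(p, fit, 2)
        assert (diag.n > 0).all()
        assert np.allclose(diag[["q1", "median", "q3"]], 0.5)
        assert not diag["no_overlap"].any()

    def test_positivity_violation_flagged(self):
        # X_2 = 1 whenever X_1 = 1 -> the (x1=1, group 0) cell is empty
        rng = np.random.default_rng(3)
        n = 300
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = np.where(x1 == 1, 1.0, (rng.random(n) < 0.4).astype(float))
        df = pd.DataFrame({"id": range(n), "l_1": rng.standard_normal(n),
                           "x_1": x1, "y_1": rng.standard_normal(n),
                           "l_2": rng.standard_normal(n), "x_2": x2,
                           "y_2": rng.standard_normal(n)})
        schema = ip.PanelSchema.from_dict({"id": "id", "T": 2, "L": "l",
                                           "X": "x", "Y": "y"})
        p = ip.PanelDataset(df, schema)
        fit = ip.fit_propensity(p, 2)
        diag = ip.overlap_diagnostics(p, fit, 2)
        empty = diag[(diag.stratum == "x1=1") & (diag.group == 0)].iloc[0]
        assert empty.n == 0
        assert diag[diag.stratum == "x1=1"]["no_overlap"].all()

    def test_proportions_sum_to_one(self, discrete_panel, discrete_fits):
        ps, _ = discrete_fits
        diag = ip.overlap_diagnostics(discrete_panel, ps[1], 2)
        assert diag["prop"].sum() == pytest.approx(1.0)

    def test_requires_t_at_least_two(self, discrete_panel, discrete_fits):
        with pytest.raises(ValueError):
            ip.overlap_diagnostics(discrete_panel, discrete_fits[0][0], 1)
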