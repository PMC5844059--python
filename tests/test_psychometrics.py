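"""Psychometric machinery: binarization, summaries, schemes, ML fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from ventriloquist import design, observer
from ventriloquist import psychometrics as psy
from ventriloquist.exceptions import (EmptySummaryError, InvalidDesignError,
                                      InvalidResponseError)


class TestBinarizeAndSummarize:
    @pytest.mark.parametrize("button,side", [(-10.0, "left"), (-3.3, "left"),
                                             (3.3, "right"), (10.0, "right")])
    def test_binarize(self, button, side):
        assert psy.binarize(button) == side

    def test_off_grid_button_rejected(self):
        with pytest.raises(InvalidResponseError):
            psy.binarize(0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(EmptySummaryError):
            psy.summarize(pd.DataFrame())

    def test_av_abscissa_is_midpoint_and_counts_conserved(self):
        grid = design.DEFAULT_GRID
        cond = design.ConditionSpec("AV", loc_a=3.3, loc_v=-3.3,
                                    visual_reliability="high", report="auditory",
                                    nominal_delta=6.0)
        trials = pd.DataFrame([{**design.condition_record(cond),
                                "button": 10.0 if i < 4 else -10.0}
                               for i in range(10)])
        summary = psy.summarize(trials)
        assert len(summary) == 1
        row = summary.iloc[0]
        assert row.x == pytest.approx(0.0)
        assert (row.n, row.k) == (10, 4)

    def test_total_n_conserved_over_experiment(self, behavior_fitted):
        trials, fitted = behavior_fitted
        full = psy.summarize(trials[0])
        assert full.n.sum() == len(trials[0])


class TestPsychometricValue:
    def test_half_at_pse_for_any_lapse(self):
        for lam in (0.0, 0.1, 0.4):
            p = psy.PsychFunParams(pse=2.0, sigma=3.0, lapse=lam)
            assert psy.psychometric_value(2.0, p) == pytest.approx(0.5)

    def test_limits_and_standard_normal_point(self):
        p = psy.PsychFunParams(pse=0.0, sigma=1.0, lapse=0.0)
        assert psy.psychometric_value(1e9, p) == pytest.approx(1.0)
        assert psy.psychometric_value(1.0, p) == pytest.approx(0.8413, abs=1e-4)

    def test_bounded_by_lapse_and_increasing(self):
        p = psy.PsychFunParams(pse=0.0, sigma=2.0, lapse=0.07)
        xs = np.linspace(-50, 50, 401)
        vals = psy.psychometric_value(xs, p)
        assert np.all(vals >= p.lapse - 1e-12)
        assert np.all(vals <= 1 - p.lapse + 1e-12)
        assert np.all(np.diff(vals) >= 0)


class TestSchemes:
    @pytest.mark.parametrize("scheme_id,n_free", [
        ("main17", 17), ("congruent21", 21), ("model_I", 8),
        ("model_II", 5), ("model_III", 11), ("model_IV", 17)])
    def test_free_parameter_counts(self, scheme_id, n_free):
        assert psy.build_scheme(scheme_id).n_free_parameters == n_free

    def test_model_iv_is_main17(self):
        a, b = psy.build_scheme("model_IV"), psy.build_scheme("main17")
        assert a.pse_map == b.pse_map and a.sigma_map == b.sigma_map

    def test_unknown_scheme_rejected(self):
        with pytest.raises(InvalidDesignError):
            psy.build_scheme("model_V")


def _exact_summary(mu, sigma, lam, xs, n):
    """Binomial summary whose counts equal the expected values under ψ."""
    p = lam + (1 - 2 * lam) * ndtr((np.asarray(xs) - mu) / sigma)
    return pd.DataFrame({"modality": "A", "visual_reliability": None, "report": None,
                         "delta_sign": None, "nominal_delta": None,
                         "x": xs, "n": n, "k": np.round(n * p).astype(int)})


class TestFitting:
    def test_recovers_generative_parameters_from_expected_counts(self):
        xs = [-12, -8, -4, 0, 4, 8, 12]
        summary = _exact_summary(0.0, 5.0, 0.02, xs, 10**6)
        fit = psy.fit(summary, psy.independent_scheme(summary),
                      psy.FitOptions(n_starts=6, seed=0))
        assert fit.params["pse_0"] == pytest.approx(0.0, abs=0.05)
        assert fit.params["sigma_0"] == pytest.approx(5.0, rel=0.01)
        assert fit.params["lapse"] == pytest.approx(0.02, rel=0.01)

    def test_symmetric_data_gives_zero_pse(self):
        summary = _exact_summary(0.0, 6.0, 0.0, [-9, -3, 3, 9], 100)
        fit = psy.fit(summary, psy.independent_scheme(summary, fix_lapse=0.0),
                      psy.FitOptions(n_starts=4, seed=0))
        assert fit.params["pse_0"] == pytest.approx(0.0, abs=1e-4)

    def test_model_iv_reports_17_parameters_52_points(self, fusion_fit_idealized):
        assert fusion_fit_idealized.n_free_parameters == 17
        assert fusion_fit_idealized.n_data_points == 52

    def test_refit_from_optimum_is_idempotent(self, fusion_fit_idealized):
        fit0 = fusion_fit_idealized
        refit = psy.fit(fit0.summary, fit0.scheme,
                        psy.FitOptions(n_starts=1, warm_start=fit0.params))
        assert refit.log_likelihood == pytest.approx(fit0.log_likelihood, abs=1e-6)

    def test_constrained_fit_with_distinct_slots_matches_separate_fits(self):
        """All-distinct slots must reach the same optimum as per-row fits."""
        rng = np.random.default_rng(5)
        xs = [-9, -3, 3, 9]
        rows = []
        for i, (mu, sg) in enumerate([(-1.0, 4.0), (2.0, 8.0)]):
            p = ndtr((np.asarray(xs) - mu) / sg)
            rows.append(pd.DataFrame({
                "modality": "V", "visual_reliability": "high" if i == 0 else "low",
                "report": None, "delta_sign": None, "nominal_delta": None,
                "x": xs, "n": 200, "k": rng.binomial(200, p)}))
        summary = pd.concat(rows, ignore_index=True)
        joint = psy.fit(summary, psy.independent_scheme(summary, fix_lapse=0.0),
                        psy.FitOptions(n_starts=6, seed=0))
        ll_sep = sum(
            psy.fit(part, psy.independent_scheme(part, fix_lapse=0.0),
                    psy.FitOptions(n_starts=6, seed=0)).log_likelihood
            for part in (rows[0], rows[1]))
        assert joint.log_likelihood == pytest.approx(ll_sep, abs=1e-5)

    def test_degenerate_one_sided_data_warns(self):
        summary = _exact_summary(0.0, 5.0, 0.0, [-9, -3, 3, 9], 10)
        summary["k"] = 0
        with pytest.warns(RuntimeWarning):
            psy.fit(summary, psy.independent_scheme(summary, fix_lapse=0.0),
                    psy.FitOptions(n_starts=2, seed=0))

    def test_probit_batch_matches_generic_optimizer(self):
        rng = np.random.default_rng(8)
        xs = np.array([-9.0, -3.0, 3.0, 9.0])
        k = rng.binomial(50, ndtr((xs - 1.0) / 5.0), size=(20, 4))
        mu_b, sg_b = psy.fit_probit_batch(xs, 50, k)
        for i in range(0, 20, 5):
            summary = pd.DataFrame({"modality": "A", "visual_reliability": None,
                                    "report": None, "delta_sign": None,
                                    "nominal_delta": None, "x": xs, "n": 50, "k": k[i]})
            f = psy.fit(summary, psy.independent_scheme(summary, fix_lapse=0.0),
                        psy.FitOptions(n_starts=6, seed=0))
            assert mu_b[i] == pytest.approx(f.params["pse_0"], abs=1e-3)
            assert sg_b[i] == pytest.approx(f.params["sigma_0"], rel=1e-3)


class TestModelII:
    def test_tethered_parameters_satisfy_fusion_equations_exactly(self):
        from ventriloquist.mle import (empirical_weight, predicted_sigma_av,
                                       predicted_weight)
        scheme = psy.build_scheme("model_II")
        summary = _exact_summary(0.0, 5.0, 0.0, [-9, -3, 3, 9], 100)
        # build a compiled view over the full 52-row layout
        conds = design.enumerate_mle_conditions(design.idealized_grid())
        rows = []
        for c in conds:
            rows.append({"modality": c.modality,
                         "visual_reliability": c.visual_reliability,
                         "report": c.report,
                         "delta_sign": None if c.nominal_delta is None
                         else float(np.sign(c.nominal_delta)),
                         "nominal_delta": c.nominal_delta,
                         "x": c.abscissa, "n": 10, "k": 5})
        full = pd.DataFrame(rows)
        compiled = psy._Compiled(scheme, full)
        params = {"pse_shared": 0.7, "sigma_a": 11.0, "sigma_v_high": 4.0,
                  "sigma_v_low": 9.0, "lapse": 0.03}
        mu, sigma, lam = compiled.expand(compiled.theta_from_params(params))
        for i, row in full.iterrows():
            if row.modality != "AV":
                continue
            sv = params[f"sigma_v_{row.visual_reliability}"]
            w = predicted_weight(params["sigma_a"], sv)
            assert sigma[i] == pytest.approx(predicted_sigma_av(params["sigma_a"], sv))
            assert mu[i] == pytest.approx(0.7 + (w - 0.5) * row.delta_sign * 6.0)
        # Eq. 2 applied to the tethered conflict PSEs returns w_V exactly
        i_pos = full.index[(full.delta_sign == 1) & (full.visual_reliability == "high")][0]
        i_neg = full.index[(full.delta_sign == -1) & (full.visual_reliability == "high")][0]
        w = predicted_weight(params["sigma_a"], params["sigma_v_high"])
        assert empirical_weight(mu[i_pos], mu[i_neg], 6.0) == pytest.approx(w)


class TestModelScores:
    def test_bic_arithmetic(self):
        f = psy.FitResult("x", {}, log_likelihood=-100.0, n_free_parameters=5,
                          n_data_points=52, pseudo_r2=0.5)
        assert psy.bic(f) == pytest.approx(-100 - 2.5 * np.log(52))
        f0 = psy.FitResult("x", {}, -100.0, 0, 52, 0.5)
        assert psy.bic(f0) == -100.0
        assert psy.relative_bic(f0, f0) == 0.0

    def test_pseudo_r2_chance_and_perfect(self):
        xs = [-9, -3, 3, 9]
        chance = _exact_summary(0.0, 1e6, 0.0, xs, 1000)  # flat ψ ≈ 0.5
        fit_c = psy.fit(chance, psy.independent_scheme(chance, fix_lapse=0.0),
                        psy.FitOptions(n_starts=4, seed=0))
        assert fit_c.pseudo_r2 == pytest.approx(0.0, abs=1e-3)
        perfect = _exact_summary(0.0, 0.2, 0.0, xs, 1000)  # step: k ∈ {0, n}
        fit_p = psy.fit(perfect, psy.independent_scheme(perfect, fix_lapse=0.0),
                        psy.FitOptions(n_starts=4, seed=0))
        assert fit_p.pseudo_r2 == pytest.approx(1.0, abs=1e-3)

    def test_pseudo_r2_monotone_in_likelihood(self, fusion_summary_idealized):
        """A richer nested model (higher LL) never has lower pseudo-R²."""
        summary = fusion_summary_idealized["summary"]
        grid = fusion_summary_idealized["grid"]
        conds = design.enumerate_mle_conditions(grid)
        fits = [psy.fit(summary, psy.build_scheme(sid, conds),
                        psy.FitOptions(n_starts=6, seed=1))
                for sid in ("model_I", "model_III", "model_IV")]
        lls = [f.log_likelihood for f in fits]
        r2s = [f.pseudo_r2 for f in fits]
        assert lls == sorted(lls)
        assert r2s == sorted(r2s)
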