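"""End-to-end synthetic replication: design → simulate → fit → infer.

`run_pipeline` executes the full analysis on synthetic participants and
writes delimited tables shaped like the study's three results tables
(model-based comparisons, 2×2 effects, model comparison), plus the
neurometric pipeline outputs, under ``config.out_dir``.  Every stage is
seeded from the config; rerunning with the same config reproduces every
number exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import design, mle, neural, observer
from . import psychometrics as psy
from .config import RunConfig
from .exceptions import DegenerateContrastError
from .inference import (bonferroni, bootstrap_test, group_bms,
                        parametric_bootstrap, rank_anova_2x2,
                        wilcoxon_signed_rank)

CELLS = [(rel, rep) for rel in ("high", "low") for rep in ("auditory", "visual")]


def _subject_observers(config: RunConfig) -> list[observer.ObserverParams]:
    rng = np.random.default_rng(config.seed + 101)
    out = []
    for _ in range(config.n_subjects):
        j = config.subject_jitter
        out.append(observer.ObserverParams(
            sigma_a=config.sigma_a * float(np.exp(rng.normal(0, j))),
            sigma_v_high=config.sigma_v_high * float(np.exp(rng.normal(0, j))),
            sigma_v_low=config.sigma_v_low * float(np.exp(rng.normal(0, j))),
            lapse=config.lapse, attention_gain=config.attention_gain,
            mode=config.observer_mode))
    return out


def _subject_plans(config: RunConfig, subject: int) -> list[design.SessionPlan]:
    return design.default_session_plans(
        grid=config.grid, delta=config.nominal_delta,
        n_av_sessions_per_report=config.n_av_sessions_per_report,
        n_auditory_sessions=config.n_auditory_sessions,
        n_visual_sessions=config.n_visual_sessions,
        null_fraction=config.null_fraction,
        seed=config.seed + 10_000 + subject)


def simulate_behavior(config: RunConfig) -> list[pd.DataFrame]:
    """Trial tables for each synthetic participant."""
    observers = _subject_observers(config)
    tables = []
    for s, obs in enumerate(observers):
        plans = _subject_plans(config, s)
        trials = observer.simulate_experiment(plans, obs, seed=config.seed + 20_000 + s,
                                              grid=config.grid)
        trials.insert(0, "subject", s)
        tables.append(trials)
    return tables


def fit_subjects(config: RunConfig, trial_tables: list[pd.DataFrame],
                 schemes: tuple[str, ...] | None = None) -> dict:
    """Per-subject binomial summaries and scheme fits."""
    schemes = schemes or config.schemes
    conditions = design.enumerate_mle_conditions(config.grid, config.nominal_delta)
    opts = psy.FitOptions(n_starts=config.n_starts, seed=config.seed + 1)
    summaries, fits = [], {sid: [] for sid in schemes}
    for trials in trial_tables:
        summary = psy.mle_subset(psy.summarize(trials, config.grid))
        summaries.append(summary)
        for sid in schemes:
            scheme = psy.build_scheme(sid, conditions, config.nominal_delta)
            fits[sid].append(psy.fit(summary, scheme, opts))
    return {"summaries": summaries, "fits": fits}


def behavior_tables(config: RunConfig, fitted: dict) -> dict:
    """Random-effects statistics shaped like the study's Tables 1–3."""
    fits = fitted["fits"]
    # --- per-subject weight/variance estimates
    per_cell = [mle.weight_variance_table(f) for f in fits["model_IV"]]
    pooled_rep = [mle.weight_variance_table(f) for f in fits["model_III"]]

    rows = []
    for rel in ("high", "low"):
        sub = [t[t.reliability == rel].iloc[0] for t in pooled_rep]
        comparisons = {
            "w_emp - w_pred": [r.w_v_empirical - r.w_v_predicted for r in sub],
            "sigma_av_emp - sigma_av_pred":
                [r.sigma_av_empirical - r.sigma_av_predicted for r in sub],
            "sigma_av_emp - sigma_uni_v":
                [r.sigma_av_empirical - r.sigma_uni_v for r in sub],
            "sigma_av_emp - sigma_uni_a":
                [r.sigma_av_empirical - r.sigma_uni_a for r in sub],
        }
        for label, diffs in comparisons.items():
            w, p = wilcoxon_signed_rank(diffs, tails="two")
            rows.append({"comparison": label, "reliability": rel,
                         "statistic": w, "p": p, "n": len(diffs)})
    # crossmodal-influence tests, pooled over reliability
    w_mean = [t.w_v_empirical.mean() for t in pooled_rep]
    w_lt1, p_lt1 = wilcoxon_signed_rank([w - 1.0 for w in w_mean], tails="less")
    w_gt0, p_gt0 = wilcoxon_signed_rank(w_mean, tails="greater")
    rows.append({"comparison": "w_emp < 1", "reliability": "pooled",
                 "statistic": w_lt1, "p": p_lt1, "n": len(w_mean)})
    rows.append({"comparison": "w_emp > 0", "reliability": "pooled",
                 "statistic": w_gt0, "p": p_gt0, "n": len(w_mean)})
    table1 = pd.DataFrame(rows)

    # --- 2×2 rank ANOVA on empirical weights and SDs
    def cell_array(attr):
        arr = np.empty((len(per_cell), 2, 2))
        for s, tab in enumerate(per_cell):
            for i, rel in enumerate(("high", "low")):
                for j, rep in enumerate(("auditory", "visual")):
                    row = tab[(tab.reliability == rel) & (tab.report == rep)].iloc[0]
                    arr[s, i, j] = getattr(row, attr)
        return arr

    t2_rows = []
    n_subj = len(per_cell)
    for measure, attr in [("w_v_empirical", "w_v_empirical"),
                          ("sigma_av_empirical", "sigma_av_empirical")]:
        try:
            effects = rank_anova_2x2(cell_array(attr))
        except DegenerateContrastError:
            # tied ranks can zero a contrast at very small n; keep the row
            effects = {e: {"F": np.nan, "p": np.nan, "df1": 1, "df2": n_subj - 1}
                       for e in ("reliability", "report", "reliability x report")}
        for effect, res in effects.items():
            t2_rows.append({"measure": measure, "effect": effect, **res})
    table2 = pd.DataFrame(t2_rows)

    # --- Bayesian model comparison over Models I–IV
    model_ids = ["model_I", "model_II", "model_III", "model_IV"]
    bics = np.array([[psy.bic(f) for f in (fits[mid])] for mid in model_ids]).T
    bms = group_bms(bics, seed=config.seed + 2)
    table3 = pd.DataFrame({
        "model": model_ids,
        "n_parameters": [fits[mid][0].n_free_parameters for mid in model_ids],
        "pseudo_r2_mean": [float(np.mean([f.pseudo_r2 for f in fits[mid]]))
                           for mid in model_ids],
        "relative_bic_sum": bms.relative_group_bic,
        "expected_posterior": bms.expected_posterior,
        "exceedance": bms.exceedance,
        "protected_exceedance": bms.protected_exceedance,
    })

    weights = pd.concat(
        [t.assign(subject=s) for s, t in enumerate(per_cell)], ignore_index=True)
    return {"table1": table1, "table2": table2, "table3": table3,
            "weights": weights, "bms": bms}


def _weight_stats(boot_fit) -> dict:
    """Per-reliability weight/SD statistics recorded on every bootstrap draw."""
    tab = mle.weight_variance_table(boot_fit)
    out = {}
    for _, row in tab.iterrows():
        tag = row.reliability if row.report is None else f"{row.reliability}_{row.report}"
        out[f"w_emp_{tag}"] = row.w_v_empirical
        out[f"w_pred_{tag}"] = row.w_v_predicted
        out[f"s_emp_{tag}"] = row.sigma_av_empirical
        out[f"s_pred_{tag}"] = row.sigma_av_predicted
        out[f"s_uni_v_{tag}"] = row.sigma_uni_v
        out[f"s_uni_a_{tag}"] = row.sigma_uni_a
    return out


def neural_analysis(config: RunConfig, n_boot: int | None = None) -> dict:
    """Decoding → neurometric fits → fixed-effects bootstrap tests."""
    enc = neural.EncodingParams(
        w_v_neural=config.w_v_neural, noise_sd=config.neural_noise_sd,
        reliability_noise_scale=dict(config.reliability_noise_scale),
        report_gain=dict(config.report_gain),
        voxel_gain_spread=config.voxel_gain_spread)
    decoded_all = []
    for s in range(config.n_subjects):
        plans = _subject_plans(config, s)
        patterns = neural.simulate_patterns(plans, enc, n_voxels=config.n_voxels,
                                            seed=config.seed + 30_000 + s)
        patterns = neural.znorm(patterns, config.znorm_scope)
        decoded = neural.decode_loso(patterns)
        decoded.insert(0, "subject", s)
        decoded_all.append(decoded)
    decoded_df = pd.concat(decoded_all, ignore_index=True)
    summary = psy.mle_subset(neural.neurometric_summary(decoded_df))

    conditions = design.enumerate_mle_conditions(config.grid, config.nominal_delta)
    opts = psy.FitOptions(n_starts=config.n_starts, seed=config.seed + 3)
    fit_iv = psy.fit(summary, psy.build_scheme("model_IV", conditions,
                                               config.nominal_delta), opts)
    fit_iii = psy.fit(summary, psy.build_scheme("model_III", conditions,
                                                config.nominal_delta), opts)
    weights = mle.weight_variance_table(fit_iii).assign(source="pooled_report")
    weights = pd.concat([weights,
                         mle.weight_variance_table(fit_iv).assign(source="per_cell")],
                        ignore_index=True)

    n_boot = n_boot if n_boot is not None else config.n_boot_test
    draws = parametric_bootstrap(fit_iii, n_boot=n_boot, seed=config.seed + 4,
                                 statistic=_weight_stats)
    obs = _weight_stats(fit_iii)
    rows = []
    for rel in ("high", "low"):
        for label, a, b in [("w_emp - w_pred", f"w_emp_{rel}", f"w_pred_{rel}"),
                            ("sigma_av_emp - sigma_av_pred", f"s_emp_{rel}", f"s_pred_{rel}"),
                            ("sigma_av_emp - sigma_uni_v", f"s_emp_{rel}", f"s_uni_v_{rel}"),
                            ("sigma_av_emp - sigma_uni_a", f"s_emp_{rel}", f"s_uni_a_{rel}")]:
            d_obs = obs[a] - obs[b]
            d_boot = (draws[a] - draws[b]).to_numpy()
            p = bootstrap_test(d_obs, d_boot, tails="two")
            rows.append({"comparison": label, "reliability": rel, "observed": d_obs,
                         "p": p, "p_bonferroni": bonferroni(p, config.bonferroni_m),
                         "n_boot": len(d_boot)})
    tests = pd.DataFrame(rows)

    draws_iv = parametric_bootstrap(fit_iv, n_boot=n_boot, seed=config.seed + 5,
                                    statistic=_weight_stats)
    obs_iv = _weight_stats(fit_iv)

    def contrast(frame_or_dict, meas, kind):
        g = lambda rel, rep: (frame_or_dict[f"{meas}_{rel}_{rep}"])
        if kind == "reliability":
            return (g("high", "auditory") + g("high", "visual")
                    - g("low", "auditory") - g("low", "visual")) / 2.0
        if kind == "report":
            return (g("high", "auditory") + g("low", "auditory")
                    - g("high", "visual") - g("low", "visual")) / 2.0
        return (g("high", "auditory") - g("high", "visual")
                - g("low", "auditory") + g("low", "visual"))

    rows = []
    for meas, label in [("w_emp", "w_v_empirical"), ("s_emp", "sigma_av_empirical")]:
        for kind in ("reliability", "report", "interaction"):
            d_obs = contrast(obs_iv, meas, kind)
            d_boot = contrast(draws_iv, meas, kind).to_numpy()
            p = bootstrap_test(d_obs, d_boot, tails="two")
            rows.append({"measure": label, "effect": kind, "observed": d_obs, "p": p,
                         "p_bonferroni": bonferroni(p, config.bonferroni_m),
                         "n_boot": len(d_boot)})
    effect_tests = pd.DataFrame(rows)

    return {"decoded": decoded_df, "summary": summary, "fit_model_IV": fit_iv,
            "fit_model_III": fit_iii, "weights": weights,
            "table1_neural": tests, "table2_neural": effect_tests}


def run_pipeline(config: RunConfig, n_boot_neural: int | None = None) -> dict:
    """Execute every stage and write the result bundle under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    bundle: dict = {}
    log_lines = [f"seed={config.seed}", f"mode={config.mode}"]
    for pkg in ("numpy", "scipy", "pandas", "sklearn"):
        mod = __import__(pkg)
        log_lines.append(f"{pkg}=={mod.__version__}")

    if config.mode in ("behavior", "both"):
        trials = simulate_behavior(config)
        pd.concat(trials, ignore_index=True).to_csv(out / "trials.csv", index=False)
        fitted = fit_subjects(config, trials)
        fit_rows = []
        for sid, fl in fitted["fits"].items():
            for s, f in enumerate(fl):
                fit_rows.append({"subject": s, **f.to_dict()["params"],
                                 "scheme_id": sid, "log_likelihood": f.log_likelihood,
                                 "bic": psy.bic(f), "pseudo_r2": f.pseudo_r2})
        pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
        tables = behavior_tables(config, fitted)
        for name in ("table1", "table2", "table3", "weights"):
            tables[name].to_csv(out / f"{name}.csv", index=False)
        # fixed-effects follow-up: pool counts across subjects, one fit
        pooled = psy.pool_summaries(fitted["summaries"])
        pooled_fit = psy.fit(pooled, psy.build_scheme(
            "model_IV", design.enumerate_mle_conditions(config.grid, config.nominal_delta),
            config.nominal_delta), psy.FitOptions(n_starts=config.n_starts,
                                                  seed=config.seed + 6))
        mle.weight_variance_table(pooled_fit).to_csv(out / "weights_fixed_effects.csv",
                                                     index=False)
        bundle.update(trials=trials, fitted=fitted, tables=tables,
                      pooled_fit=pooled_fit)
        log_lines.append(f"behavior: {sum(len(t) for t in trials)} trials, "
                         f"{len(fitted['summaries'])} subjects")

    if config.mode in ("neural", "both"):
        neural_out = neural_analysis(config, n_boot=n_boot_neural)
        neural_out["summary"].to_csv(out / "neurometric_summary.csv", index=False)
        neural_out["weights"].to_csv(out / "neural_weights.csv", index=False)
        neural_out["table1_neural"].to_csv(out / "table1_neural.csv", index=False)
        neural_out["table2_neural"].to_csv(out / "table2_neural.csv", index=False)
        bundle["neural"] = neural_out
        log_lines.append(f"neural: {len(neural_out['decoded'])} decoded patterns")

    main_results = {}
    if "tables" in bundle:
        main_results["bms_expected_posterior"] = \
            bundle["tables"]["table3"]["expected_posterior"].tolist()
        main_results["behavior_weights"] = \
            bundle["tables"]["weights"].groupby(["reliability", "report"])[
                ["w_v_empirical", "w_v_predicted"]].mean().reset_index().to_dict("records")
    if "neural" in bundle:
        main_results["neural_tests"] = \
            bundle["neural"]["table1_neural"].to_dict("records")
    (out / "results.json").write_text(json.dumps(main_results, indent=2, default=float))
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return bundle
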