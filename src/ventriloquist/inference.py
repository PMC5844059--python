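"""Inferential machinery: parametric bootstrap, nonparametric tests, and
group-level Bayesian model selection.

Parametric bootstrap: binomial counts are resampled from the fitted
psychometric probabilities, the same parameter scheme is refitted to every
draw, and derived statistics (weights, SDs, predictions) are recorded.
Hypothesis tests shift the bootstrap distribution by the observed value to
form a null distribution and use the closed inequality (fraction of null
draws with |value| ≥ |observed|) — no smoothing term, so p-values live on
the grid j/n_boot.

Classic statistics: exact Wilcoxon signed-rank (full enumeration of sign
assignments up to n = 15, midranks for ties, normal approximation above)
and a rank-transformed 2×2 repeated-measures ANOVA in which each
df1 = 1 effect's F equals the squared paired t on the per-subject contrast
of jointly ranked values.

Random-effects Bayesian model selection uses the variational Dirichlet
scheme over model frequencies (uniform prior), exceedance probabilities by
Monte-Carlo sampling of the posterior Dirichlet, and protected exceedance
probabilities blending with chance via the Bayes omnibus risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, ndtr
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata

from .exceptions import (DegenerateContrastError, InvalidDesignError,
                         UndefinedTestError)
from .psychometrics import (FitOptions, FitResult, fit, fit_probit_batch,
                            predicted_psi)

# ---------------------------------------------------------------------------
# parametric bootstrap


@dataclass
class BootstrapResult:
    """Observed statistic with its bootstrap distribution and test summary."""

    label: str
    observed: float
    draws: np.ndarray
    ci_low: float
    ci_high: float
    coverage: float
    p_value: float | None
    tails: str | None
    n_boot: int
    seed: int | None = None


def bootstrap_ci(draws: np.ndarray, coverage: float = 0.68) -> tuple[float, float]:
    """Percentile interval of the bootstrap draws (default 68%)."""
    lo = 100 * (0.5 - coverage / 2)
    return (float(np.percentile(draws, lo)),
            float(np.percentile(draws, 100 - lo)))


def bootstrap_test(observed_diff: float, boot_diffs: np.ndarray,
                   tails: str = "two") -> float:
    """Shifted-null bootstrap p-value.

    The null distribution is ``boot_diffs − observed_diff``.  Two-tailed:
    fraction of null draws whose absolute value is ≥ |observed|.
    One-tailed (``"greater"``/``"less"``): the signed inequality;
    ``"one"`` tests in the direction of the observed difference.
    """
    boot_diffs = np.asarray(boot_diffs, float)
    if boot_diffs.size == 0:
        raise InvalidDesignError("bootstrap test needs at least one draw")
    null = boot_diffs - observed_diff
    if tails == "two":
        return float(np.mean(np.abs(null) >= abs(observed_diff)))
    if tails == "one":
        tails = "greater" if observed_diff >= 0 else "less"
    if tails == "greater":
        return float(np.mean(null >= observed_diff))
    if tails == "less":
        return float(np.mean(null <= observed_diff))
    raise InvalidDesignError(f"unknown tails {tails!r}")


def bonferroni(p: float, m: int = 3) -> float:
    """Bonferroni-adjusted p-value: min(1, m·p)."""
    if m < 1:
        raise InvalidDesignError("m must be ≥ 1")
    return min(1.0, m * p)


def parametric_bootstrap(fit_result: FitResult, n_boot: int = 1000, seed: int = 0,
                         statistic=None,
                         fit_options: FitOptions | None = None) -> pd.DataFrame:
    """Resample counts from the fitted ψ and refit the same scheme.

    For each draw, k* ~ Binomial(n, ψ_fit(x)) per summary row; the scheme is
    refitted (warm-started at the observed optimum) and the draw's parameter
    estimates are recorded, together with ``statistic(fit)`` values if a
    callable is given (it may return a scalar or a dict of scalars).
    Returns one row per successful draw; warns if more than 5% of refits
    fail.
    """
    if n_boot < 1:
        raise InvalidDesignError("n_boot must be ≥ 1")
    if fit_result.summary is None or fit_result.scheme is None:
        raise InvalidDesignError("fit result must carry its summary and scheme")
    summary = fit_result.summary
    psi = np.clip(predicted_psi(fit_result), 1e-12, 1 - 1e-12)
    n = summary["n"].to_numpy(int)
    rng = np.random.default_rng(seed)
    opts = fit_options or FitOptions(n_starts=3, warm_start=fit_result.params)
    if opts.warm_start is None:
        opts.warm_start = fit_result.params

    rows, failures = [], 0
    for b in range(n_boot):
        boot_summary = summary.copy()
        boot_summary["k"] = rng.binomial(n, psi)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                boot_fit = fit(boot_summary, fit_result.scheme,
                               FitOptions(n_starts=opts.n_starts,
                                          seed=int(rng.integers(2**31)),
                                          warm_start=opts.warm_start))
        except Exception:
            failures += 1
            continue
        row = {"draw": b, **boot_fit.params}
        if statistic is not None:
            value = statistic(boot_fit)
            if isinstance(value, dict):
                row.update(value)
            else:
                row["statistic"] = float(value)
        rows.append(row)
    if failures > 0.05 * n_boot:
        warnings.warn(f"{failures}/{n_boot} bootstrap refits failed", RuntimeWarning)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


def wilcoxon_signed_rank(differences, tails: str = "two",
                         exact_max_n: int = 15) -> tuple[float, float]:
    """Signed-rank test on paired differences.

    Zeros are dropped; |differences| are midranked.  The statistic is W⁺,
    the rank sum of positive differences.  For n ≤ *exact_max_n* the exact
    null distribution is built by enumerating all 2ⁿ sign assignments;
    above that a normal approximation with tie-corrected variance is used.
    ``tails``: "two", "greater" (median > 0), or "less".
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    eps = 1e-9
    if n <= exact_max_n:
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = signs @ ranks
        if tails == "two":
            p = np.mean(np.abs(w_all - mu) >= abs(w - mu) - eps)
        elif tails == "greater":
            p = np.mean(w_all >= w - eps)
        elif tails == "less":
            p = np.mean(w_all <= w + eps)
        else:
            raise InvalidDesignError(f"unknown tails {tails!r}")
        return w, float(p)
    var = float(np.sum(ranks**2)) / 4.0
    z = (w - mu) / np.sqrt(var)
    if tails == "two":
        p = 2.0 * norm.sf(abs(z))
    elif tails == "greater":
        p = norm.sf(z)
    elif tails == "less":
        p = norm.cdf(z)
    else:
        raise InvalidDesignError(f"unknown tails {tails!r}")
    return w, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# rank-transformed 2×2 repeated-measures ANOVA


def rank_anova_2x2(values: np.ndarray,
                   factor_names: tuple[str, str] = ("reliability", "report")) -> dict:
    """Nonparametric 2×2 within-subject ANOVA on jointly ranked values.

    *values* has shape (n_subjects, 2, 2), axes = (subject, factor A level,
    factor B level).  All 4n values are midranked jointly; each effect's F
    (df1 = 1, df2 = n − 1) is the squared paired t on the per-subject
    contrast of ranked values.  Monotone transformations of the input leave
    the result unchanged.
    """
    values = np.asarray(values, float)
    if values.ndim != 3 or values.shape[1:] != (2, 2):
        raise InvalidDesignError("values must have shape (n_subjects, 2, 2)")
    n = values.shape[0]
    if n < 2:
        raise InvalidDesignError("need at least 2 subjects")
    ranks = rankdata(values.ravel()).reshape(values.shape)
    contrasts = {
        factor_names[0]: ranks[:, 1, :].mean(axis=1) - ranks[:, 0, :].mean(axis=1),
        factor_names[1]: ranks[:, :, 1].mean(axis=1) - ranks[:, :, 0].mean(axis=1),
        f"{factor_names[0]} x {factor_names[1]}":
            ranks[:, 1, 1] - ranks[:, 1, 0] - ranks[:, 0, 1] + ranks[:, 0, 0],
    }
    out = {}
    for effect, c in contrasts.items():
        sd = np.std(c, ddof=1)
        if sd == 0:
            raise DegenerateContrastError(f"zero contrast variance for effect {effect!r}")
        t = np.mean(c) / (sd / np.sqrt(n))
        f_val = float(t**2)
        out[effect] = {"F": f_val, "p": float(f_dist.sf(f_val, 1, n - 1)),
                       "df1": 1, "df2": n - 1}
    return out


# ---------------------------------------------------------------------------
# group-level Bayesian model selection


@dataclass
class BMSResult:
    """Group Bayesian model selection over K models."""

    expected_posterior: np.ndarray
    exceedance: np.ndarray
    protected_exceedance: np.ndarray
    fixed_effects_posterior: np.ndarray
    relative_group_bic: np.ndarray  # summed evidence relative to the first model
    alpha: np.ndarray               # posterior Dirichlet parameters
    bor: float                      # Bayes omnibus risk


def group_bms(log_evidences: np.ndarray, alpha0: float = 1.0,
              n_samples: int = 1_000_000, seed: int = 0,
              tol: float = 1e-12, max_iter: int = 10_000) -> BMSResult:
    """Random- and fixed-effects model selection from subject × model evidences.

    Variational posterior over model frequencies r ~ Dirichlet(α), uniform
    prior α₀; exceedance probabilities estimated by Monte-Carlo sampling of
    the posterior; protected exceedance blends with chance 1/K via the
    Bayes omnibus risk BOR = 1/(1 + exp(F1 − F0)).
    """
    ev = np.asarray(log_evidences, float)
    if ev.ndim != 2 or ev.shape[1] < 2:
        raise InvalidDesignError("need a (n_subjects, K≥2) evidence array")
    if not np.all(np.isfinite(ev)):
        raise InvalidDesignError("log evidences must be finite")
    n_subj, n_models = ev.shape
    ev_c = ev - ev.max(axis=1, keepdims=True)  # per-subject shift; cancels throughout

    # fixed effects: pooled evidence
    total = ev.sum(axis=0)
    ffx = np.exp(total - logsumexp(total))
    rel_bic = total - total[0]

    # random effects: variational Dirichlet updates
    alpha = np.full(n_models, alpha0, float)
    for _ in range(max_iter):
        log_u = ev_c + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    expected = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    samples = rng.gamma(shape=alpha, size=(n_samples, n_models))
    ep = np.bincount(np.argmax(samples, axis=1), minlength=n_models) / n_samples

    # Bayes omnibus risk: free energy of the frequency model vs equal frequencies
    e_lnr = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_g = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    f1 = (np.sum(g * (ev_c + e_lnr[None, :])) + entropy_g
          + gammaln(n_models * alpha0) - n_models * gammaln(alpha0)
          + np.sum((alpha0 - 1.0) * e_lnr)
          - (gammaln(alpha.sum()) - np.sum(gammaln(alpha))
             + np.sum((alpha - 1.0) * e_lnr)))
    f0 = float(np.sum(logsumexp(ev_c, axis=1) - np.log(n_models)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / n_models

    return BMSResult(expected_posterior=expected, exceedance=ep,
                     protected_exceedance=pxp, fixed_effects_posterior=ffx,
                     relative_group_bic=rel_bic, alpha=alpha, bor=bor)


# ---------------------------------------------------------------------------
# bootstrap calibration study


@dataclass
class CalibrationResult:
    p_values: np.ndarray
    rejection_rate: float
    ci_coverage: float
    alpha: float
    n_replicates: int
    n_boot: int


def pse_bootstrap_calibration(n_replicates: int = 500, n_boot: int = 500,
                              n_per_abscissa: int = 110, sigma: float = 6.0,
                              mu_true: float = 0.0, alpha: float = 0.05,
                              ci_coverage: float = 0.68,
                              seed: int = 1, grid=None) -> CalibrationResult:
    """Type-I error of the two-tailed bootstrap test under a generative null.

    Each replicate experiment simulates two conditions from the *same*
    cumulative Gaussian (so the true PSE difference is zero), fits each
    condition's lapse-free psychometric function by maximum likelihood,
    parametrically bootstraps the counts from the fitted functions, refits
    every draw, and computes the shifted-null two-tailed p-value of the PSE
    difference via :func:`bootstrap_test`.  Also records how often the
    percentile interval (default 68%) of a condition's bootstrapped PSE
    covers the generative PSE.  Refits run through the vectorized probit
    path, which computes the same ML estimate as the generic optimizer.
    """
    if grid is None:
        from .design import idealized_grid
        grid = idealized_grid()
    x = np.asarray(grid, float)
    rng = np.random.default_rng(seed)
    psi_true = ndtr((x - mu_true) / sigma)

    k_obs = rng.binomial(n_per_abscissa, psi_true, size=(n_replicates, 2, x.size))
    mu_obs, sg_obs = fit_probit_batch(x, n_per_abscissa, k_obs)
    d_obs = mu_obs[:, 0] - mu_obs[:, 1]

    psi_hat = ndtr((x[None, None, :] - mu_obs[..., None]) / sg_obs[..., None])
    psi_hat = np.clip(psi_hat, 1e-12, 1 - 1e-12)
    k_boot = rng.binomial(n_per_abscissa,
                          np.broadcast_to(psi_hat[:, None, :, :],
                                          (n_replicates, n_boot, 2, x.size)))
    mu_boot, _ = fit_probit_batch(x, n_per_abscissa, k_boot)
    d_boot = mu_boot[:, :, 0] - mu_boot[:, :, 1]

    p_values = np.array([bootstrap_test(d_obs[i], d_boot[i], tails="two")
                         for i in range(n_replicates)])
    lo_q = 100 * (0.5 - ci_coverage / 2)
    ci_lo = np.percentile(mu_boot[:, :, 0], lo_q, axis=1)
    ci_hi = np.percentile(mu_boot[:, :, 0], 100 - lo_q, axis=1)
    covered = float(np.mean((ci_lo <= mu_true) & (mu_true <= ci_hi)))

    return CalibrationResult(p_values=p_values,
                             rejection_rate=float(np.mean(p_values < alpha)),
                             ci_coverage=covered, alpha=alpha,
                             n_replicates=n_replicates, n_boot=n_boot)
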