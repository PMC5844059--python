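"""Binarization, binomial summaries, and constrained psychometric fits.

Responses are binarized into left/right, tallied per condition into a
binomial summary (abscissa x, n trials, k "right"), and fitted with
lapse-adjusted cumulative Gaussians

    ψ(x) = λ + (1 − 2λ) Φ((x − μ) / σ)

by maximizing the product-binomial log-likelihood.  The guess rate equals
the lapse rate λ (symmetric tails), shared across conditions.  Parameter
*schemes* tie μ (PSE), σ (slope's inverse scale) and λ across conditions:

``main17``       1 shared PSE (unisensory + AV-congruent) + 8 conflict PSEs
                 (2 reliability × 2 report × 2 conflict signs); slopes for
                 auditory, high/low-reliability visual, and 4 AV cells
                 (shared over congruent and ±conflict); 1 lapse — 17 free.
``congruent21``  main17 plus 4 extra slopes for the AV-congruent cells — 21.
``model_I``      null model: AV parameters blind to reliability and report — 8.
``model_II``     cue-combination (MLE) model: AV PSEs and slopes computed
                 from the unisensory parameters each likelihood evaluation
                 (weights from inverse variances, fused SD, conflict PSE
                 μ₀ + (w_V − ½)ΔAV) — 5 free.
``model_III``    reliability-weighting model: AV parameters vary with
                 reliability only, unconstrained by MLE — 11.
``model_IV``     alias of main17.

Optimization uses an internal reparameterization (μ raw, log σ, logit of
2λ) and seeded multi-start L-BFGS-B.  ``fit_probit_batch`` is a vectorized
Fisher-scoring path for the λ = 0 single-condition fit (a binomial probit
GLM), used where very many refits of independent conditions are needed; it
computes the same maximum-likelihood estimate as the generic optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

from .design import (DEFAULT_GRID, NOMINAL_DELTA, RELIABILITIES, REPORTS,
                     ConditionSpec, enumerate_mle_conditions, validate_grid)
from .exceptions import (EmptySummaryError, FitFailureError, InvalidDesignError,
                         InvalidResponseError)
from .mle import predicted_sigma_av, predicted_weight

SCHEME_IDS = ("main17", "congruent21", "model_I", "model_II", "model_III", "model_IV")

SUMMARY_KEYS = ["modality", "visual_reliability", "report", "delta_sign"]
SUMMARY_COLUMNS = SUMMARY_KEYS + ["nominal_delta", "x", "n", "k"]


# ---------------------------------------------------------------------------
# binarization and summaries

def binarize(button: float, grid: Sequence[float] = DEFAULT_GRID) -> str:
    """Map a button location to "left"/"right" (two leftmost vs two rightmost)."""
    grid = validate_grid(grid)
    matches = [g for g in grid if np.isclose(button, g)]
    if not matches:
        raise InvalidResponseError(f"button {button!r} is not on the grid {grid}")
    return "left" if grid.index(matches[0]) < 2 else "right"


def _delta_sign(nominal_delta) -> float | None:
    if nominal_delta is None or (isinstance(nominal_delta, float) and np.isnan(nominal_delta)):
        return None
    return float(np.sign(nominal_delta))


def summarize(trials: pd.DataFrame, grid: Sequence[float] = DEFAULT_GRID) -> pd.DataFrame:
    """Tally trial responses into a per-condition binomial summary.

    One row per condition with columns ``modality, visual_reliability,
    report, delta_sign, nominal_delta, x, n, k``.  The abscissa x is the
    true location for unisensory conditions and the mean of the true
    auditory and visual locations for audiovisual conditions.  Unisensory
    rows carry no report (sessions are report-pure by construction).
    """
    if trials is None or len(trials) == 0:
        raise EmptySummaryError("cannot summarize an empty trial table")
    grid = validate_grid(grid)
    df = trials.copy()
    df["right"] = [binarize(b, grid) == "right" for b in df["button"]]
    is_av = df["modality"] == "AV"
    loc_a = pd.to_numeric(df["loc_a"], errors="coerce").to_numpy()
    loc_v = pd.to_numeric(df["loc_v"], errors="coerce").to_numpy()
    x = np.where(df["modality"] == "A", loc_a,
                 np.where(df["modality"] == "V", loc_v, 0.5 * (loc_a + loc_v)))
    df["x"] = np.round(x, 6)
    df["visual_reliability"] = df["visual_reliability"].where(df["modality"] != "A", None)
    df["report"] = df["report"].where(is_av, None)
    df["delta_sign"] = [
        _delta_sign(nd) if m == "AV" else None
        for m, nd in zip(df["modality"], df["nominal_delta"])]
    grouped = (df.groupby(SUMMARY_KEYS + ["nominal_delta", "x"], dropna=False)
               .agg(n=("right", "size"), k=("right", "sum")).reset_index())
    grouped["k"] = grouped["k"].astype(int)
    return grouped[SUMMARY_COLUMNS]


def mle_subset(summary: pd.DataFrame) -> pd.DataFrame:
    """Drop audiovisual rows outside the congruent/small-conflict subset."""
    keep = (summary["modality"] != "AV") | summary["delta_sign"].notna()
    return summary[keep].reset_index(drop=True)


def pool_summaries(summaries: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects pooling: sum n and k across participants per condition."""
    stacked = pd.concat(list(summaries), ignore_index=True)
    pooled = (stacked.groupby(SUMMARY_KEYS + ["nominal_delta", "x"], dropna=False)
              .agg(n=("n", "sum"), k=("k", "sum")).reset_index())
    return pooled[SUMMARY_COLUMNS]


# ---------------------------------------------------------------------------
# psychometric function

@dataclass(frozen=True)
class PsychFunParams:
    """Cumulative-Gaussian parameters: PSE μ, SD σ, shared guess/lapse λ."""

    pse: float
    sigma: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidDesignError("sigma must be positive")
        if not 0 <= self.lapse < 0.5:
            raise InvalidDesignError("lapse must lie in [0, 0.5)")


def psychometric_value(x, p: PsychFunParams):
    """ψ(x) = λ + (1 − 2λ) Φ((x − μ)/σ)."""
    return p.lapse + (1.0 - 2.0 * p.lapse) * ndtr((np.asarray(x, float) - p.pse) / p.sigma)


# ---------------------------------------------------------------------------
# parameter schemes

Key = tuple  # (modality, visual_reliability, report, delta_sign)


def condition_key(cond: ConditionSpec) -> Key:
    if cond.modality == "A":
        return ("A", None, None, None)
    if cond.modality == "V":
        return ("V", cond.visual_reliability, None, None)
    return ("AV", cond.visual_reliability, cond.report, _delta_sign(cond.nominal_delta))


def _row_key(row) -> Key:
    rel = row["visual_reliability"]
    rep = row["report"]
    ds = row["delta_sign"]
    return (row["modality"],
            None if pd.isna(rel) else rel,
            None if pd.isna(rep) else rep,
            None if pd.isna(ds) else float(ds))


_TETHER = "__tether__"


@dataclass
class ParameterScheme:
    """Maps condition keys to shared parameter slots.

    ``pse_map``/``sigma_map`` assign each condition key a slot name, or the
    sentinel ``__tether__`` for parameters computed from the unisensory
    slots via the cue-combination equations (model_II).  ``fix_lapse`` pins
    λ to a constant instead of fitting it.
    """

    scheme_id: str
    pse_map: dict = field(default_factory=dict)
    sigma_map: dict = field(default_factory=dict)
    fix_lapse: float | None = None
    nominal_delta: float = NOMINAL_DELTA

    @property
    def tethered(self) -> bool:
        return any(v == _TETHER for v in self.pse_map.values()) or \
            any(v == _TETHER for v in self.sigma_map.values())

    @property
    def pse_slots(self) -> list[str]:
        return sorted({v for v in self.pse_map.values() if v != _TETHER})

    @property
    def sigma_slots(self) -> list[str]:
        return sorted({v for v in self.sigma_map.values() if v != _TETHER})

    @property
    def free_slots(self) -> list[str]:
        slots = self.pse_slots + self.sigma_slots
        if self.fix_lapse is None:
            slots.append("lapse")
        return slots

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_slots)


def _sign_tag(sign: float) -> str:
    return "pos" if sign > 0 else "neg"


def build_scheme(scheme_id: str,
                 conditions: Sequence[ConditionSpec] | None = None,
                 nominal_delta: float = NOMINAL_DELTA,
                 fix_lapse: float | None = None) -> ParameterScheme:
    """Construct one of the named parameter-sharing schemes over *conditions*."""
    if scheme_id not in SCHEME_IDS:
        raise InvalidDesignError(f"unknown scheme {scheme_id!r}")
    if conditions is None:
        conditions = enumerate_mle_conditions(delta=nominal_delta)
    keys = []
    for cond in conditions:
        key = condition_key(cond)
        if key[0] == "AV" and key[3] is None:
            raise InvalidDesignError("schemes cover only the congruent/small-conflict AV subset")
        if key not in keys:
            keys.append(key)

    pse_map: dict = {}
    sigma_map: dict = {}
    for key in keys:
        modality, rel, rep, sign = key
        if modality == "A":
            pse_map[key] = "pse_shared"
            sigma_map[key] = "sigma_a"
            continue
        if modality == "V":
            pse_map[key] = "pse_shared"
            sigma_map[key] = f"sigma_v_{rel}"
            continue
        # audiovisual
        if scheme_id in ("main17", "model_IV", "congruent21"):
            pse_map[key] = ("pse_shared" if sign == 0
                            else f"pse_{rel}_{rep}_{_sign_tag(sign)}")
            if scheme_id == "congruent21" and sign == 0:
                sigma_map[key] = f"sigma_av_congruent_{rel}_{rep}"
            else:
                sigma_map[key] = f"sigma_av_{rel}_{rep}"
        elif scheme_id == "model_I":
            pse_map[key] = "pse_shared" if sign == 0 else f"pse_conflict_{_sign_tag(sign)}"
            sigma_map[key] = "sigma_av"
        elif scheme_id == "model_II":
            pse_map[key] = _TETHER
            sigma_map[key] = _TETHER
        elif scheme_id == "model_III":
            pse_map[key] = "pse_shared" if sign == 0 else f"pse_{rel}_{_sign_tag(sign)}"
            sigma_map[key] = f"sigma_av_{rel}"
    return ParameterScheme(scheme_id=scheme_id, pse_map=pse_map, sigma_map=sigma_map,
                           fix_lapse=fix_lapse, nominal_delta=nominal_delta)


def independent_scheme(summary: pd.DataFrame, fix_lapse: float | None = None,
                       nominal_delta: float = NOMINAL_DELTA) -> ParameterScheme:
    """One free (μ, σ) pair per condition key, lapse shared (or fixed).

    Not one of the named schemes; used for unconstrained per-condition fits
    and as the oracle counterpart of fully-distinct slot assignments.
    """
    pse_map: dict = {}
    sigma_map: dict = {}
    for i, key in enumerate(dict.fromkeys(_row_key(r) for _, r in summary.iterrows())):
        pse_map[key] = f"pse_{i}"
        sigma_map[key] = f"sigma_{i}"
    return ParameterScheme(scheme_id="independent", pse_map=pse_map, sigma_map=sigma_map,
                           fix_lapse=fix_lapse, nominal_delta=nominal_delta)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitOptions:
    n_starts: int = 20
    seed: int = 0
    tol: float = 1e-10
    maxiter: int = 1000
    warm_start: dict | None = None  # slot -> value, natural scale


@dataclass
class FitResult:
    """Maximum-likelihood fit of one scheme to one binomial summary."""

    scheme_id: str
    params: dict  # slot name -> estimate on the natural scale
    log_likelihood: float
    n_free_parameters: int
    n_data_points: int
    pseudo_r2: float
    scheme: ParameterScheme | None = None
    summary: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"scheme_id": self.scheme_id, "params": dict(self.params),
                "log_likelihood": self.log_likelihood,
                "n_free_parameters": self.n_free_parameters,
                "n_data_points": self.n_data_points,
                "pseudo_r2": self.pseudo_r2,
                "bic": bic(self)}


class _Compiled:
    """Scheme × summary compiled to index arrays for fast likelihood evaluation."""

    def __init__(self, scheme: ParameterScheme, summary: pd.DataFrame):
        self.scheme = scheme
        self.x = summary["x"].to_numpy(float)
        self.n = summary["n"].to_numpy(float)
        self.k = summary["k"].to_numpy(float)
        slots = scheme.free_slots
        self.slots = slots
        pos = {s: i for i, s in enumerate(slots)}
        n_pse = len(scheme.pse_slots)
        self.n_pse = n_pse
        keys = [_row_key(row) for _, row in summary.iterrows()]
        for key in keys:
            if key not in scheme.pse_map:
                raise InvalidDesignError(f"summary condition {key} has no slot in scheme "
                                         f"{scheme.scheme_id!r}")
        self.mu_idx = np.array([pos.get(scheme.pse_map[key], -1) for key in keys])
        self.sg_idx = np.array([pos.get(scheme.sigma_map[key], -1) for key in keys])
        self.teth = np.array([scheme.pse_map[key] == _TETHER or
                              scheme.sigma_map[key] == _TETHER for key in keys])
        if self.teth.any():
            for needed in ("pse_shared", "sigma_a"):
                if needed not in pos:
                    raise InvalidDesignError("tethered scheme requires unisensory slots")
            self.i_mu0 = pos["pse_shared"]
            self.i_sa = pos["sigma_a"]
            self.teth_sv_idx = np.array([
                pos[f"sigma_v_{key[1]}"] if t else -1 for key, t in zip(keys, self.teth)])
            self.signed_delta = np.array([
                (key[3] or 0.0) * scheme.nominal_delta if t else 0.0
                for key, t in zip(keys, self.teth)])
        self.lapse_idx = pos.get("lapse")

    def expand(self, theta: np.ndarray):
        """Free vector -> per-row (μ, σ, λ)."""
        mu = np.where(self.mu_idx >= 0, theta[np.clip(self.mu_idx, 0, None)], 0.0)
        log_sg = np.where(self.sg_idx >= 0, theta[np.clip(self.sg_idx, 0, None)], 0.0)
        sigma = np.exp(log_sg)
        if self.teth.any():
            sa = np.exp(theta[self.i_sa])
            sv = np.exp(np.where(self.teth_sv_idx >= 0,
                                 theta[np.clip(self.teth_sv_idx, 0, None)], 0.0))
            w_v = (1.0 / sv**2) / (1.0 / sa**2 + 1.0 / sv**2)
            mu_t = theta[self.i_mu0] + (w_v - 0.5) * self.signed_delta
            sg_t = np.sqrt(sa**2 * sv**2 / (sa**2 + sv**2))
            mu = np.where(self.teth, mu_t, mu)
            sigma = np.where(self.teth, sg_t, sigma)
        if self.lapse_idx is not None:
            lam = 0.5 * expit(theta[self.lapse_idx])
        else:
            lam = self.scheme.fix_lapse
        return mu, sigma, lam

    def nll(self, theta: np.ndarray) -> float:
        mu, sigma, lam = self.expand(theta)
        psi = lam + (1.0 - 2.0 * lam) * ndtr((self.x - mu) / sigma)
        psi = np.clip(psi, 1e-12, 1.0 - 1e-12)
        return -float(np.sum(self.k * np.log(psi) + (self.n - self.k) * np.log1p(-psi)))

    def nll_grad(self, theta: np.ndarray):
        """Objective with its analytic gradient (chain rule through slots,
        the log/logit reparameterization, and any tethered MLE parameters)."""
        mu, sigma, lam = self.expand(theta)
        z = (self.x - mu) / sigma
        phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
        big_phi = ndtr(z)
        psi = np.clip(lam + (1.0 - 2.0 * lam) * big_phi, 1e-12, 1.0 - 1e-12)
        f = -float(np.sum(self.k * np.log(psi) + (self.n - self.k) * np.log1p(-psi)))
        dpsi = -(self.k / psi - (self.n - self.k) / (1.0 - psi))  # d(nll)/dψ per row
        g_mu = dpsi * (-(1.0 - 2.0 * lam) * phi / sigma)          # d(nll)/dμ_row
        g_sg = dpsi * (-(1.0 - 2.0 * lam) * phi * z / sigma)      # d(nll)/dσ_row

        grad = np.zeros_like(theta)
        free = ~self.teth if self.teth.any() else np.ones(len(self.x), bool)
        np.add.at(grad, self.mu_idx[free & (self.mu_idx >= 0)],
                  g_mu[free & (self.mu_idx >= 0)])
        sel = free & (self.sg_idx >= 0)
        np.add.at(grad, self.sg_idx[sel], (g_sg * sigma)[sel])  # slot is log σ
        if self.teth.any():
            t = self.teth
            sa = np.exp(theta[self.i_sa])
            sv = np.exp(np.where(self.teth_sv_idx >= 0,
                                 theta[np.clip(self.teth_sv_idx, 0, None)], 0.0))
            a2, v2 = sa**2, sv**2
            dw_dlsa = 2.0 * a2 * v2 / (a2 + v2) ** 2   # ∂w_V/∂log σ_A
            dsg_dlsa = sigma * (v2 / (a2 + v2))        # ∂σ_AV/∂log σ_A
            dsg_dlsv = sigma * (a2 / (a2 + v2))
            grad[self.i_mu0] += np.sum(g_mu[t])
            grad[self.i_sa] += np.sum((g_mu * self.signed_delta * dw_dlsa
                                       + g_sg * dsg_dlsa)[t])
            for slot_idx in np.unique(self.teth_sv_idx[t]):
                rows = t & (self.teth_sv_idx == slot_idx)
                grad[slot_idx] += np.sum((-g_mu * self.signed_delta * dw_dlsa
                                          + g_sg * dsg_dlsv)[rows])
        if self.lapse_idx is not None:
            dlam_dt = lam * (1.0 - 2.0 * lam)
            grad[self.lapse_idx] = np.sum(dpsi * (1.0 - 2.0 * big_phi)) * dlam_dt
        return f, grad

    def loglik(self, theta: np.ndarray) -> float:
        return -self.nll(theta)

    def theta_from_params(self, params: dict) -> np.ndarray:
        theta = np.empty(len(self.slots))
        for i, slot in enumerate(self.slots):
            v = params[slot]
            if slot == "lapse":
                theta[i] = logit(np.clip(2.0 * v, 1e-9, 1 - 1e-9))
            elif slot.startswith("sigma"):
                theta[i] = np.log(v)
            else:
                theta[i] = v
        return theta

    def params_from_theta(self, theta: np.ndarray) -> dict:
        params = {}
        for i, slot in enumerate(self.slots):
            if slot == "lapse":
                params[slot] = 0.5 * expit(theta[i])
            elif slot.startswith("sigma"):
                params[slot] = float(np.exp(theta[i]))
            else:
                params[slot] = float(theta[i])
        return params


def _chance_loglik(summary: pd.DataFrame) -> float:
    n_total = float(summary["n"].sum())
    return n_total * np.log(0.5)


def _nagelkerke(ll: float, ll0: float, n_total: float) -> float:
    r2_cs = 1.0 - np.exp(2.0 * (ll0 - ll) / n_total)
    r2_max = 1.0 - np.exp(2.0 * ll0 / n_total)
    if r2_max <= 0:
        return 0.0
    return float(np.clip(r2_cs / r2_max, 0.0, 1.0))


def pseudo_r2(fit: FitResult) -> float:
    """Likelihood-ratio R², rescaled for the binary response ceiling."""
    if fit.summary is None:
        return fit.pseudo_r2
    return _nagelkerke(fit.log_likelihood, _chance_loglik(fit.summary),
                       float(fit.summary["n"].sum()))


def _initial_thetas(compiled: _Compiled, summary: pd.DataFrame, opts: FitOptions):
    rng = np.random.default_rng(opts.seed)
    x = summary["x"].to_numpy(float)
    spread = max(np.ptp(x), 1.0)
    base = {}
    for slot in compiled.slots:
        if slot == "lapse":
            base[slot] = 0.02
        elif slot.startswith("sigma"):
            base[slot] = 0.5 * spread
        else:
            base[slot] = 0.0
    thetas = []
    if opts.warm_start is not None:
        thetas.append(compiled.theta_from_params({**base, **opts.warm_start}))
    thetas.append(compiled.theta_from_params(base))
    while len(thetas) < max(opts.n_starts, 1):
        jitter = {}
        for slot in compiled.slots:
            if slot == "lapse":
                jitter[slot] = float(np.clip(0.02 * np.exp(rng.normal(0, 1)), 1e-4, 0.4))
            elif slot.startswith("sigma"):
                jitter[slot] = float(base[slot] * np.exp(rng.normal(0, 0.7)))
            else:
                jitter[slot] = float(rng.normal(0, 0.3 * spread))
        thetas.append(compiled.theta_from_params(jitter))
    return thetas


def fit(summary: pd.DataFrame, scheme: ParameterScheme,
        opts: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of *scheme* to a binomial summary.

    Multi-start L-BFGS-B on the reparameterized objective; returns the best
    candidate.  Raises :class:`FitFailureError` (carrying the best-so-far
    result) only if every restart fails outright; warns on degenerate
    all-left/all-right data.
    """
    opts = opts or FitOptions()
    if len(summary) == 0:
        raise EmptySummaryError("cannot fit an empty summary")
    if (summary["n"] < 1).any():
        raise InvalidDesignError("every summary row needs n ≥ 1")
    if (summary["k"] == 0).all() or (summary["k"] == summary["n"]).all():
        warnings.warn("degenerate summary: every response on one side; "
                      "fit will sit on the parameter boundary", RuntimeWarning)
    compiled = _Compiled(scheme, summary)
    n_free = scheme.n_free_parameters

    bounds = []
    spread = max(float(np.ptp(summary["x"])), 1.0)
    for slot in compiled.slots:
        if slot == "lapse":
            bounds.append((-16.0, 5.0))
        elif slot.startswith("sigma"):
            bounds.append((np.log(1e-2), np.log(100.0 * spread)))
        else:
            bounds.append((-10.0 * spread, 10.0 * spread))

    best_theta, best_nll, any_success = None, np.inf, False
    for theta0 in _initial_thetas(compiled, summary, opts):
        res = minimize(compiled.nll_grad, theta0, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": opts.maxiter, "ftol": opts.tol,
                                "gtol": 1e-10})
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best_theta = float(res.fun), res.x
        any_success = any_success or bool(res.success)
    if best_theta is None:
        raise FitFailureError("all optimizer restarts diverged", best_result=None)

    params = compiled.params_from_theta(best_theta)
    ll = -best_nll
    result = FitResult(
        scheme_id=scheme.scheme_id, params=params, log_likelihood=ll,
        n_free_parameters=n_free, n_data_points=len(summary),
        pseudo_r2=_nagelkerke(ll, _chance_loglik(summary), float(summary["n"].sum())),
        scheme=scheme, summary=summary.reset_index(drop=True))
    if not any_success:
        raise FitFailureError("no optimizer restart converged", best_result=result)
    return result


def bic(fit_result: FitResult) -> float:
    """LL − 0.5·M·ln(N) (larger is better); N is the number of summary rows."""
    n = fit_result.n_data_points
    if n == 0:
        raise InvalidDesignError("BIC undefined for zero data points")
    return fit_result.log_likelihood - 0.5 * fit_result.n_free_parameters * np.log(n)


def relative_bic(fit_result: FitResult, null_fit: FitResult) -> float:
    return bic(fit_result) - bic(null_fit)


def predicted_psi(fit_result: FitResult, summary: pd.DataFrame | None = None) -> np.ndarray:
    """Fitted ψ value for each summary row (used for parametric resampling)."""
    summary = summary if summary is not None else fit_result.summary
    compiled = _Compiled(fit_result.scheme, summary)
    theta = compiled.theta_from_params(fit_result.params)
    mu, sigma, lam = compiled.expand(theta)
    return lam + (1.0 - 2.0 * lam) * ndtr((compiled.x - mu) / sigma)


# ---------------------------------------------------------------------------
# fast path: λ = 0 single-condition fits as a batched probit GLM

def fit_probit_batch(x: np.ndarray, n: np.ndarray, k: np.ndarray,
                     max_iter: int = 100, tol: float = 1e-12):
    """Vectorized ML fit of Φ((x − μ)/σ) to batches of binomial data.

    ``k`` has shape (..., R) over the R abscissae in ``x``; a Fisher-scoring
    probit fit runs independently for every leading index.  Returns
    ``(mu, sigma)`` arrays with the leading shape of ``k``.  Identical
    estimator to :func:`fit` with a lapse-free independent scheme; exists
    because bootstrap calibration needs hundreds of thousands of refits.
    """
    x = np.asarray(x, float)
    k = np.asarray(k, float)
    n = np.broadcast_to(np.asarray(n, float), k.shape)
    lead = k.shape[:-1]
    beta0 = np.zeros(lead)
    beta1 = np.full(lead, 0.2)
    for _ in range(max_iter):
        eta = beta0[..., None] + beta1[..., None] * x
        p = np.clip(ndtr(eta), 1e-10, 1 - 1e-10)
        phi = np.exp(-0.5 * eta**2) / np.sqrt(2 * np.pi)
        v = phi / (p * (1 - p))
        resid = (k - n * p) * v
        u0 = resid.sum(-1)
        u1 = (resid * x).sum(-1)
        w = n * phi * v
        i00 = w.sum(-1)
        i01 = (w * x).sum(-1)
        i11 = (w * x * x).sum(-1)
        det = i00 * i11 - i01 * i01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        d0 = (i11 * u0 - i01 * u1) / det
        d1 = (i00 * u1 - i01 * u0) / det
        # damp huge steps (near-separation)
        step = np.maximum(np.abs(d0) / 50.0, np.abs(d1) / 5.0)
        damp = np.where(step > 1.0, step, 1.0)
        beta0 = np.clip(beta0 + d0 / damp, -200.0, 200.0)
        beta1 = np.clip(beta1 + d1 / damp, 1e-4, 50.0)
        if np.max(np.abs(d0 / damp)) < tol and np.max(np.abs(d1 / damp)) < tol:
            break
    sigma = 1.0 / beta1
    mu = -beta0 * sigma
    return mu, sigma
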