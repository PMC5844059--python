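"""Maximum-likelihood (forced-fusion) cue-combination predictions.

For auditory and visual location estimates with sensory SDs σ_A and σ_V,
the reliability-weighted fusion model predicts

    w_V = (1/σ_V²) / (1/σ_A² + 1/σ_V²),        w_A = 1 − w_V
    σ_AV² = σ_A² σ_V² / (σ_A² + σ_V²)

and, for psychometric functions plotted against the mean audiovisual
location, a conflict-condition PSE of μ₀ + (w_V − ½)·ΔAV.  The empirical
weight inverts that relation from the two fitted conflict PSEs:

    w_V,emp = (PSE₊ − PSE₋) / (2ΔAV) + ½.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import InvalidDesignError


def _check_sds(sigma_a: float, sigma_v: float) -> None:
    if sigma_a <= 0 or sigma_v <= 0:
        raise InvalidDesignError("sensory SDs must be positive")


def predicted_weight(sigma_a: float, sigma_v: float) -> float:
    """Visual weight w_V from the unisensory SDs (relative reliability)."""
    _check_sds(sigma_a, sigma_v)
    r_a, r_v = 1.0 / sigma_a**2, 1.0 / sigma_v**2
    return r_v / (r_a + r_v)


def predicted_sigma_av(sigma_a: float, sigma_v: float) -> float:
    """Fused audiovisual SD; always below min(σ_A, σ_V)."""
    _check_sds(sigma_a, sigma_v)
    return math.sqrt(sigma_a**2 * sigma_v**2 / (sigma_a**2 + sigma_v**2))


def empirical_weight(pse_plus: float, pse_minus: float, delta: float) -> float:
    """Empirical visual weight from the two conflict-condition PSEs.

    ``pse_plus``/``pse_minus`` are the PSEs for ΔAV = +delta / −delta with
    the abscissa being the mean audiovisual location.  Values can fall
    outside [0, 1] under noise; they are returned unclipped.
    """
    if delta <= 0:
        raise InvalidDesignError("delta must be positive")
    return (pse_plus - pse_minus) / (2.0 * delta) + 0.5


def predicted_conflict_pse(mu0: float, w_v: float, delta_signed: float) -> float:
    """PSE of a conflict condition under fusion: μ₀ + (w_V − ½)·ΔAV.

    Inverse of :func:`empirical_weight`: applying that to the two predicted
    PSEs returns w_V exactly.
    """
    if not 0.0 <= w_v <= 1.0:
        raise InvalidDesignError("w_v must lie in [0, 1]")
    return mu0 + (w_v - 0.5) * delta_signed


@dataclass(frozen=True)
class WeightVarianceEstimate:
    """Empirical and MLE-predicted weight/variance for one design cell."""

    reliability: str
    report: str | None  # None for report-pooled cells
    w_v_empirical: float
    w_v_predicted: float
    sigma_av_empirical: float
    sigma_av_predicted: float
    sigma_uni_a: float
    sigma_uni_v: float
    sigma_av_congruent: float | None = None

    @property
    def w_v_empirical_in_range(self) -> bool:
        return 0.0 <= self.w_v_empirical <= 1.0


def weight_variance_table(fit_result, delta: float | None = None) -> pd.DataFrame:
    """Derive empirical and predicted weights/SDs from a fitted scheme.

    Works for any scheme exposing unisensory slots plus per-cell conflict
    PSEs (main17/model_IV, congruent21: one cell per reliability × report;
    model_III: one report-pooled cell per reliability; model_I: a single
    pooled cell).  ``delta`` defaults to the scheme's nominal disparity; a
    caller wanting the physical grid disparity passes it explicitly.
    """
    params = fit_result.params
    scheme = fit_result.scheme
    if delta is None:
        delta = scheme.nominal_delta if scheme is not None else 6.0
    sigma_a = params["sigma_a"]

    cells: list[tuple[str, str | None]] = []
    if f"pse_high_auditory_pos" in params:
        cells = [(rel, rep) for rel in ("high", "low") for rep in ("auditory", "visual")]
    elif "pse_high_pos" in params:
        cells = [("high", None), ("low", None)]
    elif "pse_conflict_pos" in params:
        cells = [("pooled", None)]
    else:
        raise InvalidDesignError(
            f"scheme {fit_result.scheme_id!r} exposes no conflict PSE slots")

    rows = []
    for rel, rep in cells:
        if rep is not None:
            p_pos = params[f"pse_{rel}_{rep}_pos"]
            p_neg = params[f"pse_{rel}_{rep}_neg"]
            s_emp = params[f"sigma_av_{rel}_{rep}"]
            s_cong = params.get(f"sigma_av_congruent_{rel}_{rep}")
        elif rel != "pooled":
            p_pos = params[f"pse_{rel}_pos"]
            p_neg = params[f"pse_{rel}_neg"]
            s_emp = params[f"sigma_av_{rel}"]
            s_cong = None
        else:
            p_pos = params["pse_conflict_pos"]
            p_neg = params["pse_conflict_neg"]
            s_emp = params["sigma_av"]
            s_cong = None
        if rel == "pooled":
            sigma_v = math.sqrt(0.5 * (params["sigma_v_high"]**2 + params["sigma_v_low"]**2))
        else:
            sigma_v = params[f"sigma_v_{rel}"]
        est = WeightVarianceEstimate(
            reliability=rel, report=rep,
            w_v_empirical=empirical_weight(p_pos, p_neg, delta),
            w_v_predicted=predicted_weight(sigma_a, sigma_v),
            sigma_av_empirical=s_emp,
            sigma_av_predicted=predicted_sigma_av(sigma_a, sigma_v),
            sigma_uni_a=sigma_a, sigma_uni_v=sigma_v,
            sigma_av_congruent=s_cong)
        rows.append({**est.__dict__, "w_v_empirical_in_range": est.w_v_empirical_in_range})
    return pd.DataFrame(rows)
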