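"""Generative observers producing 4-button localization responses.

The core observer implements forced-fusion cue combination: on each trial it
draws internal auditory and visual location estimates as Gaussian
perturbations of the true locations, combines them weighted by their
reliabilities (inverse variances), and presses the button nearest the
combined estimate.  A ``report_weighted`` variant scales the reported
modality's sensory SD by 1/√attention_gain in audiovisual trials before
weighting, emulating a top-down boost of the attended modality's
reliability; with ``attention_gain = 1`` it reduces to pure fusion.  A
``null`` observer presses uniformly random buttons and is used for
calibration checks.

Lapses: with probability 2λ a response is replaced by a uniformly random
button, which matches the symmetric guess-equals-lapse tail (each tail of
the psychometric function receives λ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ConditionSpec, SessionPlan, plans_to_frame, validate_grid, DEFAULT_GRID
from .exceptions import InvalidDesignError, ReproducibilityError

MODES = ("fusion", "report_weighted", "null")


@dataclass(frozen=True)
class ObserverParams:
    """Sensory noise and response parameters of a simulated participant.

    sigma_a : auditory sensory SD, degrees
    sigma_v_high, sigma_v_low : visual sensory SD per reliability level, degrees
    lapse : λ, stimulus-independent error probability per tail, in [0, 0.5)
    attention_gain : reliability multiplier (≥ 1) for the reported modality
        in audiovisual trials; only active in ``report_weighted`` mode
    mode : "fusion", "report_weighted" or "null"
    """

    sigma_a: float = 12.0
    sigma_v_high: float = 2.5
    sigma_v_low: float = 10.0
    lapse: float = 0.03
    attention_gain: float = 1.0
    mode: str = "fusion"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidDesignError(f"unknown observer mode {self.mode!r}")
        if min(self.sigma_a, self.sigma_v_high, self.sigma_v_low) <= 0:
            raise InvalidDesignError("sensory SDs must be positive")
        if not 0 <= self.lapse < 0.5:
            raise InvalidDesignError("lapse must lie in [0, 0.5)")
        if self.attention_gain < 1:
            raise InvalidDesignError("attention_gain must be ≥ 1")

    def sigma_v(self, reliability: str) -> float:
        if reliability == "high":
            return self.sigma_v_high
        if reliability == "low":
            return self.sigma_v_low
        raise InvalidDesignError(f"unknown visual reliability {reliability!r}")


@dataclass(frozen=True)
class TrialResponse:
    condition: ConditionSpec
    button: float
    is_lapse: bool


def nearest_button(estimate: float | np.ndarray, grid=DEFAULT_GRID) -> np.ndarray:
    """Grid location nearest the internal estimate; midpoint ties go outward."""
    grid_arr = np.asarray(validate_grid(grid))
    est = np.atleast_1d(np.asarray(estimate, dtype=float))
    dist = np.abs(est[:, None] - grid_arr[None, :])
    # tiny outward preference only breaks exact ties
    score = dist - 1e-9 * np.abs(grid_arr)[None, :]
    return grid_arr[np.argmin(score, axis=1)]


def _effective_sigmas(cond: ConditionSpec, obs: ObserverParams) -> tuple[float | None, float | None]:
    sig_a = obs.sigma_a if cond.loc_a is not None else None
    sig_v = obs.sigma_v(cond.visual_reliability) if cond.loc_v is not None else None
    if (obs.mode == "report_weighted" and cond.modality == "AV"
            and cond.report is not None and obs.attention_gain != 1.0):
        g = np.sqrt(obs.attention_gain)
        if cond.report == "auditory":
            sig_a = sig_a / g
        elif cond.report == "visual":
            sig_v = sig_v / g
    return sig_a, sig_v


def simulate_trial(cond: ConditionSpec, obs: ObserverParams,
                   rng: np.random.Generator, grid=DEFAULT_GRID) -> TrialResponse:
    """Simulate a single 4-button response for one condition."""
    if not isinstance(rng, np.random.Generator):
        raise ReproducibilityError("simulate_trial requires a seeded numpy Generator")
    grid = validate_grid(grid)
    if obs.mode == "null":
        return TrialResponse(cond, float(rng.choice(grid)), False)
    sig_a, sig_v = _effective_sigmas(cond, obs)
    if cond.modality == "A":
        est = cond.loc_a + sig_a * rng.standard_normal()
    elif cond.modality == "V":
        est = cond.loc_v + sig_v * rng.standard_normal()
    else:
        a_hat = cond.loc_a + sig_a * rng.standard_normal()
        v_hat = cond.loc_v + sig_v * rng.standard_normal()
        w_v = (1.0 / sig_v**2) / (1.0 / sig_a**2 + 1.0 / sig_v**2)
        est = (1.0 - w_v) * a_hat + w_v * v_hat
    button = float(nearest_button(est, grid)[0])
    is_lapse = bool(rng.random() < 2.0 * obs.lapse)
    if is_lapse:
        button = float(rng.choice(grid))
    return TrialResponse(cond, button, is_lapse)


def simulate_experiment(plans: list[SessionPlan], obs: ObserverParams,
                        seed: int, grid=DEFAULT_GRID) -> pd.DataFrame:
    """Simulate every stimulus trial of *plans*; one row per response.

    Vectorized over trials; deterministic given *seed*.  Null events are
    dropped (they carry no stimulus and no response).
    """
    if not plans:
        raise InvalidDesignError("simulate_experiment needs at least one session plan")
    grid_arr = np.asarray(validate_grid(grid))
    rng = np.random.default_rng(seed)
    frame = plans_to_frame(plans)
    frame = frame[frame["modality"] != "null"].reset_index(drop=True)
    n = len(frame)

    if obs.mode == "null":
        buttons = grid_arr[rng.integers(0, len(grid_arr), size=n)]
        out = frame.copy()
        out["button"] = buttons
        out["is_lapse"] = False
        return out

    loc_a = frame["loc_a"].to_numpy(dtype=float)
    loc_v = frame["loc_v"].to_numpy(dtype=float)
    modality = frame["modality"].to_numpy()
    rel = frame["visual_reliability"].to_numpy(dtype=object)
    report = frame["report"].to_numpy(dtype=object)

    sig_a = np.full(n, obs.sigma_a)
    sig_v = np.where(rel == "high", obs.sigma_v_high,
                     np.where(rel == "low", obs.sigma_v_low, np.nan))
    if obs.mode == "report_weighted" and obs.attention_gain != 1.0:
        g = np.sqrt(obs.attention_gain)
        is_av = modality == "AV"
        sig_a = np.where(is_av & (report == "auditory"), sig_a / g, sig_a)
        sig_v = np.where(is_av & (report == "visual"), sig_v / g, sig_v)

    a_hat = loc_a + sig_a * rng.standard_normal(n)
    v_hat = loc_v + sig_v * rng.standard_normal(n)
    with np.errstate(invalid="ignore"):
        w_v = (1.0 / sig_v**2) / (1.0 / sig_a**2 + 1.0 / sig_v**2)
    est = np.where(modality == "A", a_hat,
                   np.where(modality == "V", v_hat, (1.0 - w_v) * a_hat + w_v * v_hat))
    buttons = nearest_button(est, grid_arr)

    is_lapse = rng.random(n) < 2.0 * obs.lapse
    lapse_buttons = grid_arr[rng.integers(0, len(grid_arr), size=n)]
    buttons = np.where(is_lapse, lapse_buttons, buttons)

    out = frame.copy()
    out["button"] = buttons
    out["is_lapse"] = is_lapse
    return out
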