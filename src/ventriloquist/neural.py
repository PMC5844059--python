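"""Synthetic voxel patterns and the decoding → neurometric pipeline.

Emulates the regional analysis: condition-level activation patterns are
z-normalized across voxels, a linear support-vector classifier is trained
on audiovisual spatially congruent conditions to separate left from right
stimuli, and in a leave-one-session-out scheme it labels the held-out
session's congruent and conflict patterns; a final classifier trained on
all audiovisual sessions labels the unisensory-session patterns.  The
fraction decoded "right" per condition, pooled (fixed effects) over
sessions and simulated participants, forms a neurometric binomial summary
fitted with the same machinery as the behavioral data.

The pattern generator is a synthetic surrogate for BOLD activation: each
voxel responds linearly to an encoded location — for audiovisual
conditions a mixture w_V·loc_V + (1 − w_V)·loc_A with a configurable
neural visual weight — signed by its hemisphere's contralateral preference
and scaled by a per-voxel gain, plus Gaussian noise.  Heterogeneous voxel
gains put location information *within* each hemisphere; with a zero gain
spread the only signal is the global hemispheric offset, which the
per-hemisphere normalization control is designed to remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .design import SessionPlan
from .exceptions import (DecodingError, IncompleteSummaryError,
                         InvalidDesignError, NormalizationError)
from .psychometrics import SUMMARY_COLUMNS, SUMMARY_KEYS, _delta_sign

INDEX_COLUMNS = ["session_id", "modality", "loc_a", "loc_v",
                 "visual_reliability", "report", "nominal_delta"]


@dataclass(frozen=True)
class EncodingParams:
    """Synthetic regional encoding of audiovisual space.

    w_v_neural : weight of the visual location in the encoded AV mixture
    reliability_noise_scale : per-reliability multiplier on the noise SD
    report_gain : per-report multiplier on the signal
    noise_sd : voxelwise Gaussian noise SD (activation units)
    voxel_gain_spread : SD of per-voxel log-gains; 0 makes every voxel in a
        hemisphere identical, leaving only a global hemispheric offset
    """

    w_v_neural: float = 0.7
    reliability_noise_scale: dict = field(default_factory=lambda: {"high": 1.0, "low": 1.5})
    report_gain: dict = field(default_factory=lambda: {"auditory": 1.0, "visual": 1.0})
    noise_sd: float = 20.0
    signal_gain: float = 1.0
    voxel_gain_spread: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_v_neural <= 1.0:
            raise InvalidDesignError("w_v_neural must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise InvalidDesignError("noise_sd must be positive")


@dataclass
class VoxelPatternSet:
    """Activation patterns indexed by (session, condition) rows × voxels."""

    data: np.ndarray            # (n_observations, n_voxels)
    index: pd.DataFrame         # one row per observation, INDEX_COLUMNS
    hemisphere: np.ndarray      # per-voxel "L"/"R"
    tuning: pd.DataFrame        # per-voxel preferred_side (±1) and gain

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.index):
            raise InvalidDesignError("pattern/index length mismatch")
        for h in ("L", "R"):
            if np.sum(self.hemisphere == h) < 2:
                raise InvalidDesignError("need ≥ 2 voxels per hemisphere")
        if not np.all(np.isfinite(self.data)):
            raise InvalidDesignError("patterns must be finite")


def encoded_location(row, enc: EncodingParams) -> float:
    if row["modality"] == "AV":
        return enc.w_v_neural * row["loc_v"] + (1.0 - enc.w_v_neural) * row["loc_a"]
    if row["modality"] == "A":
        return row["loc_a"]
    return row["loc_v"]


def simulate_patterns(plans: list[SessionPlan], enc: EncodingParams,
                      n_voxels: int = 40, seed: int = 0) -> VoxelPatternSet:
    """One pattern per condition per session (condition-level estimates)."""
    if n_voxels < 8:
        raise InvalidDesignError("n_voxels must be ≥ 8")
    rng = np.random.default_rng(seed)
    half = n_voxels // 2
    hemisphere = np.array(["L"] * half + ["R"] * (n_voxels - half))
    # contralateral preference: left hemisphere codes right space
    preferred_side = np.where(hemisphere == "L", 1.0, -1.0)
    gain = np.exp(enc.voxel_gain_spread * rng.standard_normal(n_voxels))
    if enc.signal_gain == 0 or np.all(gain * enc.signal_gain == 0):
        warnings.warn("degenerate zero-gain tuning: patterns carry no signal",
                      RuntimeWarning)

    rows, slabs = [], []
    for plan in plans:
        conditions = list(dict.fromkeys(plan.stimulus_trials))
        for cond in conditions:
            rec = {"session_id": plan.session_id, "modality": cond.modality,
                   "loc_a": cond.loc_a, "loc_v": cond.loc_v,
                   "visual_reliability": cond.visual_reliability,
                   "report": cond.report if cond.report is not None else plan.report,
                   "nominal_delta": cond.nominal_delta}
            e = encoded_location(rec, enc)
            rg = enc.report_gain.get(rec["report"], 1.0)
            ns = enc.noise_sd * enc.reliability_noise_scale.get(cond.visual_reliability, 1.0)
            mu = enc.signal_gain * gain * preferred_side * e * rg
            slabs.append(mu + ns * rng.standard_normal(n_voxels))
            rows.append(rec)
    index = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    tuning = pd.DataFrame({"preferred_side": preferred_side, "gain": gain})
    return VoxelPatternSet(np.asarray(slabs), index, hemisphere, tuning)


def znorm(patterns: VoxelPatternSet, scope: str = "region") -> VoxelPatternSet:
    """Z-normalize each observation across voxels.

    ``scope="region"`` normalizes over all voxels of the region;
    ``scope="per_hemisphere"`` normalizes the left- and right-hemisphere
    voxels separately (the interhemispheric-offset control).
    """
    if scope not in ("region", "per_hemisphere"):
        raise InvalidDesignError(f"unknown normalization scope {scope!r}")
    groups = ([np.ones(len(patterns.hemisphere), bool)] if scope == "region"
              else [patterns.hemisphere == "L", patterns.hemisphere == "R"])
    data = patterns.data.astype(float).copy()
    for mask in groups:
        slab = data[:, mask]
        sd = slab.std(axis=1, ddof=0)
        if np.any(sd == 0):
            raise NormalizationError("zero-variance pattern slice in normalization group")
        data[:, mask] = (slab - slab.mean(axis=1, keepdims=True)) / sd[:, None]
    return VoxelPatternSet(data, patterns.index.copy(), patterns.hemisphere,
                           patterns.tuning.copy())


def _true_side(index: pd.DataFrame) -> np.ndarray:
    """Left/right of the congruent audiovisual stimulus (loc_a == loc_v)."""
    return np.where(index["loc_a"].to_numpy(float) > 0, "right", "left")


def _make_classifier(C: float) -> SVC:
    # libsvm linear SVC: deterministic for fixed inputs
    return SVC(kernel="linear", C=C)


def decode_loso(patterns: VoxelPatternSet, C: float = 1.0) -> pd.DataFrame:
    """Leave-one-session-out left/right decoding.

    Training uses only audiovisual congruent conditions (ΔAV = 0) of the
    other audiovisual sessions, across both report conditions, labeled by
    the true stimulus side.  The held-out session's congruent and conflict
    patterns are labeled by the trained classifier.  Unisensory sessions
    are decoded by a final classifier trained on all audiovisual sessions'
    congruent patterns.  Returns the index with a ``decoded`` column.
    """
    idx = patterns.index
    is_av = (idx["modality"] == "AV").to_numpy()
    is_congruent = is_av & (idx["nominal_delta"].to_numpy(float) == 0.0)
    av_sessions = sorted(idx.loc[is_av, "session_id"].unique())
    if len(av_sessions) < 2:
        raise DecodingError("leave-one-session-out needs ≥ 2 audiovisual sessions")
    for sid in av_sessions:
        if not np.any(is_congruent & (idx["session_id"] == sid).to_numpy()):
            raise DecodingError(f"session {sid} has no congruent conditions")

    decoded = np.empty(len(idx), dtype=object)
    sides = _true_side(idx)
    for sid in av_sessions:
        in_sess = (idx["session_id"] == sid).to_numpy()
        train = is_congruent & ~in_sess
        labels = sides[train]
        if len(np.unique(labels)) < 2:
            raise DecodingError("training labels contain a single class")
        clf = _make_classifier(C).fit(patterns.data[train], labels)
        test = in_sess & is_av
        decoded[test] = clf.predict(patterns.data[test])

    uni = ~is_av
    if uni.any():
        labels = sides[is_congruent]
        if len(np.unique(labels)) < 2:
            raise DecodingError("training labels contain a single class")
        clf = _make_classifier(C).fit(patterns.data[is_congruent], labels)
        decoded[uni] = clf.predict(patterns.data[uni])

    out = idx.copy()
    out["decoded"] = decoded
    return out


def neurometric_summary(decoded: pd.DataFrame,
                        conditions=None) -> pd.DataFrame:
    """Binomial summary of decoded labels, pooled over sessions/participants.

    ``decoded`` may be the concatenation of several participants' decoded
    tables (fixed-effects pooling).  If *conditions* is given, every
    condition must be covered, else an incomplete-summary error is raised.
    """
    df = decoded.copy()
    df["right"] = df["decoded"] == "right"
    loc_a = pd.to_numeric(df["loc_a"], errors="coerce").to_numpy()
    loc_v = pd.to_numeric(df["loc_v"], errors="coerce").to_numpy()
    x = np.where(df["modality"] == "A", loc_a,
                 np.where(df["modality"] == "V", loc_v, 0.5 * (loc_a + loc_v)))
    df["x"] = np.round(x, 6)
    df["visual_reliability"] = df["visual_reliability"].where(df["modality"] != "A", None)
    df["report"] = df["report"].where(df["modality"] == "AV", None)
    df["delta_sign"] = [
        _delta_sign(nd if not pd.isna(nd) else None) if m == "AV" else None
        for m, nd in zip(df["modality"], df["nominal_delta"])]
    grouped = (df.groupby(SUMMARY_KEYS + ["nominal_delta", "x"], dropna=False)
               .agg(n=("right", "size"), k=("right", "sum")).reset_index())
    grouped["k"] = grouped["k"].astype(int)
    grouped = grouped[SUMMARY_COLUMNS]
    if conditions is not None:
        from .psychometrics import condition_key, _row_key
        have = {(_row_key(row), row["x"]) for _, row in grouped.iterrows()}
        for cond in conditions:
            want = (condition_key(cond), round(cond.abscissa, 6))
            if want not in have:
                raise IncompleteSummaryError(f"no decoded labels for condition {want}")
    return grouped
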