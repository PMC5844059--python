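"""Voxel-pattern simulation, normalization, and the decoding pipeline."""

import numpy as np
import pytest

from ventriloquist import design, mle, neural
from ventriloquist import psychometrics as psy
from ventriloquist.exceptions import (DecodingError, IncompleteSummaryError,
                                      InvalidDesignError, NormalizationError)


def _plans(n_av=4, n_aud=1, n_vis=1, seed=0, grid=design.DEFAULT_GRID):
    return design.default_session_plans(
        grid=grid, n_av_sessions_per_report=n_av, n_auditory_sessions=n_aud,
        n_visual_sessions=n_vis, seed=seed)


@pytest.fixture(scope="module")
def patterns_default():
    return neural.simulate_patterns(_plans(), neural.EncodingParams(), seed=1)


class TestSimulatePatterns:
    def test_same_seed_identical(self):
        enc = neural.EncodingParams()
        a = neural.simulate_patterns(_plans(), enc, seed=2)
        b = neural.simulate_patterns(_plans(), enc, seed=2)
        assert np.array_equal(a.data, b.data)

    def test_pure_visual_encoding_ignores_auditory_location(self):
        enc = neural.EncodingParams(w_v_neural=1.0, noise_sd=1e-9)
        ps = neural.simulate_patterns(_plans(n_av=2, n_aud=0, n_vis=0), enc, seed=3)
        av = ps.index[ps.index.modality == "AV"]
        same_v = av[(av.loc_v == 10.0) & (av.session_id == av.session_id.iloc[0])
                    & (av.visual_reliability == "high")]
        assert len(same_v) >= 2  # several auditory locations share loc_v = 10
        slab = ps.data[same_v.index.to_numpy()]
        assert np.allclose(slab - slab[0], 0.0, atol=1e-6)

    def test_hemispheres_receive_sign_flipped_effects(self):
        enc = neural.EncodingParams(noise_sd=1e-9, voxel_gain_spread=0.0)
        ps = neural.simulate_patterns(_plans(n_av=2, n_aud=0, n_vis=0), enc, seed=4)
        left = ps.data[:, ps.hemisphere == "L"].mean(axis=1)
        right = ps.data[:, ps.hemisphere == "R"].mean(axis=1)
        assert np.allclose(left, -right, atol=1e-6)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(InvalidDesignError):
            neural.simulate_patterns(_plans(n_av=2), neural.EncodingParams(),
                                     n_voxels=4, seed=0)

    def test_zero_gain_warns(self):
        with pytest.warns(RuntimeWarning):
            neural.simulate_patterns(_plans(n_av=2), neural.EncodingParams(signal_gain=0.0),
                                     seed=0)


class TestZNorm:
    def test_region_scope_gives_zero_mean_unit_sd(self, patterns_default):
        z = neural.znorm(patterns_default, "region")
        assert np.allclose(z.data.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.data.std(axis=1), 1.0, atol=1e-12)

    def test_per_hemisphere_scope(self, patterns_default):
        z = neural.znorm(patterns_default, "per_hemisphere")
        for h in ("L", "R"):
            slab = z.data[:, z.hemisphere == h]
            assert np.allclose(slab.mean(axis=1), 0.0, atol=1e-12)
            assert np.allclose(slab.std(axis=1), 1.0, atol=1e-12)

    def test_constant_slice_rejected(self, patterns_default):
        bad = neural.VoxelPatternSet(np.zeros_like(patterns_default.data),
                                     patterns_default.index,
                                     patterns_default.hemisphere,
                                     patterns_default.tuning)
        with pytest.raises(NormalizationError):
            neural.znorm(bad, "region")


def _accuracy(decoded):
    av = decoded[(decoded.modality == "AV") & (decoded.nominal_delta == 0.0)]
    truth = np.where(av.loc_a > 0, "right", "left")
    return np.mean(av.decoded.to_numpy() == truth)


class TestDecoding:
    def test_noiseless_patterns_decode_perfectly(self):
        enc = neural.EncodingParams(noise_sd=1e-6)
        ps = neural.znorm(neural.simulate_patterns(_plans(n_av=3), enc, seed=5))
        assert _accuracy(neural.decode_loso(ps)) == 1.0

    def test_pure_noise_decodes_at_chance_with_flat_neurometric(self):
        with pytest.warns(RuntimeWarning):
            ps = neural.simulate_patterns(_plans(n_av=6, n_aud=0, n_vis=0),
                                          neural.EncodingParams(signal_gain=0.0),
                                          seed=6)
        decoded = neural.decode_loso(neural.znorm(ps))
        acc = _accuracy(decoded)
        n = ((decoded.modality == "AV") & (decoded.nominal_delta == 0.0)).sum()
        assert abs(acc - 0.5) < 3.5 * np.sqrt(0.25 / n)
        summary = psy.mle_subset(neural.neurometric_summary(decoded))
        av = summary[summary.modality == "AV"]
        fit = psy.fit(av, psy.independent_scheme(av, fix_lapse=0.0),
                      psy.FitOptions(n_starts=4, seed=0))
        slopes = [1.0 / v for k, v in fit.params.items() if k.startswith("sigma")]
        assert np.max(slopes) < 0.25  # near-flat neurometric functions

    def test_single_av_session_rejected(self):
        plan = design.build_session_plan(design.av_session_conditions("auditory"),
                                         1, seed=0, session_id=0, report="auditory")
        ps = neural.simulate_patterns([plan], neural.EncodingParams(), seed=7)
        with pytest.raises(DecodingError):
            neural.decode_loso(neural.znorm(ps))

    def test_hemisphere_normalization_removes_global_offset_signal(self):
        """If the only signal is a hemisphere-wide offset, per-hemisphere
        z-normalization drives decoding to chance; heterogeneous within-
        hemisphere gains survive it."""
        offset_only = neural.EncodingParams(voxel_gain_spread=0.0, noise_sd=1.0)
        ps = neural.simulate_patterns(_plans(n_av=6, n_aud=0, n_vis=0),
                                      offset_only, seed=8)
        acc_region = _accuracy(neural.decode_loso(neural.znorm(ps, "region")))
        acc_hemi = _accuracy(neural.decode_loso(neural.znorm(ps, "per_hemisphere")))
        n = 6 * 8  # congruent patterns
        assert acc_region > 0.9
        assert abs(acc_hemi - 0.5) < 3.5 * np.sqrt(0.25 / n)

        hetero = neural.EncodingParams(voxel_gain_spread=1.0, noise_sd=1.0)
        ps2 = neural.simulate_patterns(_plans(n_av=6, n_aud=0, n_vis=0), hetero, seed=9)
        acc2 = _accuracy(neural.decode_loso(neural.znorm(ps2, "per_hemisphere")))
        assert acc2 > 0.8  # within-hemisphere pattern information preserved


class TestNeurometricSummary:
    def test_all_right_labels_give_k_equals_n(self, patterns_default):
        decoded = patterns_default.index.copy()
        decoded["decoded"] = "right"
        summary = neural.neurometric_summary(decoded)
        assert (summary.k == summary.n).all()

    def test_pooled_n_counts_sessions_and_participants(self):
        enc = neural.EncodingParams()
        frames = []
        for participant in range(3):
            ps = neural.simulate_patterns(_plans(n_av=2, n_aud=0, n_vis=0),
                                          enc, seed=10 + participant)
            decoded = neural.decode_loso(neural.znorm(ps))
            frames.append(decoded)
        import pandas as pd
        summary = psy.mle_subset(neural.neurometric_summary(pd.concat(frames)))
        av = summary[summary.modality == "AV"]
        # 2 sessions with this report × 3 participants per condition
        assert (av.n == 6).all()

    def test_missing_condition_detected(self, patterns_default):
        decoded = patterns_default.index.copy()
        decoded["decoded"] = "left"
        decoded = decoded[decoded.modality != "A"]
        conds = design.enumerate_mle_conditions()
        with pytest.raises(IncompleteSummaryError):
            neural.neurometric_summary(decoded, conditions=conds)


class TestEndToEnd:
    def test_neural_weight_monotone_in_encoding_weight(self):
        """Fitted neural visual weight rises with the encoded visual weight."""
        weights = []
        for w_enc in (0.1, 0.5, 0.9):
            enc = neural.EncodingParams(w_v_neural=w_enc, noise_sd=2.0)
            frames = []
            for participant in range(2):
                ps = neural.simulate_patterns(_plans(n_av=5, n_aud=0, n_vis=0,
                                                     seed=20 + participant),
                                              enc, seed=30 + participant)
                frames.append(neural.decode_loso(neural.znorm(ps)))
            import pandas as pd
            summary = psy.mle_subset(neural.neurometric_summary(pd.concat(frames)))
            av = summary[summary.modality == "AV"]
            scheme = psy.build_scheme("model_I",
                                      [c for c in design.enumerate_mle_conditions()
                                       if c.modality == "AV"])
            fit = psy.fit(av, scheme, psy.FitOptions(n_starts=6, seed=0))
            weights.append(mle.empirical_weight(fit.params["pse_conflict_pos"],
                                                fit.params["pse_conflict_neg"], 6.0))
        assert weights[0] < weights[1] < weights[2]

    def test_pure_visual_encoding_yields_unit_neural_weight(self):
        enc = neural.EncodingParams(w_v_neural=1.0, noise_sd=0.5)
        ps = neural.simulate_patterns(_plans(n_av=6, n_aud=0, n_vis=0), enc, seed=11)
        decoded = neural.decode_loso(neural.znorm(ps))
        summary = psy.mle_subset(neural.neurometric_summary(decoded))
        av = summary[summary.modality == "AV"]
        scheme = psy.build_scheme("model_I",
                                  [c for c in design.enumerate_mle_conditions()
                                   if c.modality == "AV"])
        fit = psy.fit(av, scheme, psy.FitOptions(n_starts=6, seed=0))
        w = mle.empirical_weight(fit.params["pse_conflict_pos"],
                                 fit.params["pse_conflict_neg"], 6.0)
        assert w == pytest.approx(1.0, abs=0.15)
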