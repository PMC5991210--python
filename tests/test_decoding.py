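"""Population analyses: PCA of the ILD x ABL matrix and the
opponent-channel decoder."""

import numpy as np
import pytest
from scipy import stats

from ildpipe import RunConfig
from ildpipe.calibration import mirrored_step_population
from ildpipe.decoding import (
    assign_channel,
    build_population_matrix,
    chance_mue_db,
    decode_curve,
    noise_trial_responses,
    opponent_decode,
    run_pca,
)

ILDS = np.array([-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0])


class TestPopulationMatrix:
    def test_rows_normalized_to_unit_max(self, small_tensor):
        pop = build_population_matrix(small_tensor)
        assert pop.matrix.shape[1] == 21
        assert np.allclose(pop.matrix.max(axis=1), 1.0)

    def test_nonpositive_rows_excluded(self, small_tensor):
        t = small_tensor
        import copy
        tt = copy.deepcopy(t)
        tt.responses[3, :] = -1.0
        pop = build_population_matrix(tt)
        assert 3 in pop.excluded
        assert 3 not in pop.neuron_ids


class TestPca:
    def test_variance_fractions_sum_to_one(self, small_tensor):
        pop = build_population_matrix(small_tensor)
        res = run_pca(pop)
        assert res.variance_explained.sum() == pytest.approx(1.0)
        assert res.coefficients.shape[1:] == (7, 3)

    def test_single_motif_population_concentrates_variance(self):
        # neurons differ along one response motif only -> PC1 carries ~100%
        rng = np.random.default_rng(0)
        base = rng.uniform(0.4, 0.6, 21)
        motif = rng.standard_normal(21) * 0.1
        w = rng.standard_normal(40)
        mat = base + w[:, None] * motif
        from ildpipe.decoding import PopulationMatrix
        pop = PopulationMatrix(mat, np.arange(40), ILDS, np.array([40, 60, 80]))
        res = run_pca(pop)
        assert res.variance_explained[0] > 0.999

    def test_two_orthogonal_motifs_split_variance(self):
        # equal-power random loadings on two orthonormal motifs: the two
        # leading components carry ~50% of the variance each
        rng = np.random.default_rng(1)
        a = np.concatenate([np.ones(10), np.zeros(11)]) / np.sqrt(10)
        b = np.concatenate([np.zeros(10), np.ones(11)]) / np.sqrt(11)
        w1 = rng.standard_normal(2000)
        w2 = rng.standard_normal(2000)
        mat = w1[:, None] * a + w2[:, None] * b
        from ildpipe.decoding import PopulationMatrix
        pop = PopulationMatrix(mat, np.arange(2000), ILDS, np.array([40, 60, 80]))
        res = run_pca(pop)
        assert res.variance_explained[0] == pytest.approx(0.5, abs=0.05)
        assert res.variance_explained[1] == pytest.approx(0.5, abs=0.05)
        assert res.variance_explained[2] == pytest.approx(0.0, abs=1e-9)

    def test_constant_matrix_flagged_degenerate(self):
        from ildpipe.decoding import PopulationMatrix
        pop = PopulationMatrix(np.ones((5, 21)), np.arange(5), ILDS,
                               np.array([40, 60, 80]))
        assert run_pca(pop).degenerate


class TestAssignChannel:
    def _tensor(self, responses, ilds_per_trial):
        import pandas as pd
        from ildpipe.signal_extraction import ResponseTensor
        trials = pd.DataFrame({
            "stim_class": "noise_binaural", "ild_db": ilds_per_trial,
            "abl_db": 60.0, "freq_hz": np.nan, "level_db": np.nan,
            "onset_frame": np.arange(len(ilds_per_trial)) * 46 + 46,
        })
        r = np.atleast_2d(responses)
        return ResponseTensor(r, np.zeros_like(r), r, trials)

    def test_linear_antitonic_response_is_contra(self):
        ilds = np.tile(ILDS, 12)
        t = self._tensor(-ilds, ilds)
        chan = assign_channel(t)
        assert chan.slope[0] == pytest.approx(-1.0)
        assert chan.sign[0] == "contra" and chan.monotonic[0]

    def test_step_response_is_contra(self):
        ilds = np.tile(ILDS, 12)
        t = self._tensor((ilds <= 0).astype(float), ilds)
        chan = assign_channel(t)
        assert chan.sign[0] == "contra" and chan.slope[0] < 0

    def test_null_responses_rarely_monotonic(self):
        rng = np.random.default_rng(2)
        ilds = np.tile(ILDS, 12)
        resp = rng.normal(size=(400, ilds.size))
        chan = assign_channel(self._tensor(resp, ilds))
        # nominal 5% type-I rate, binomial 99% band for n=400
        assert 0.02 < chan.monotonic.mean() < 0.09

    def test_zero_variance_neuron_excluded(self):
        ilds = np.tile(ILDS, 2)
        chan = assign_channel(self._tensor(np.ones(ilds.size), ilds))
        assert not chan.monotonic[0] and chan.sign[0] == "none"


class TestOpponentDecode:
    def test_mirrored_step_population_decodes_perfectly(self):
        resp, ilds_t, signs = mirrored_step_population(ILDS)
        res = opponent_decode(resp, ilds_t, signs)
        assert res.mue_db == 0.0
        assert res.mue_normalized == 0.0

    def test_confusion_rows_sum_to_100(self):
        resp, ilds_t, signs = mirrored_step_population(ILDS)
        res = opponent_decode(resp, ilds_t, signs)
        assert np.allclose(res.confusion_pct.sum(axis=1), 100.0)

    def test_invariant_to_positive_neuron_rescaling(self):
        rng = np.random.default_rng(3)
        resp, ilds_t, signs = mirrored_step_population(ILDS)
        noisy = resp + rng.normal(0, 0.2, resp.shape) + 1.0
        scale = rng.uniform(0.5, 5.0, (resp.shape[0], 1))
        a = opponent_decode(noisy, ilds_t, signs)
        b = opponent_decode(noisy * scale, ilds_t, signs)
        assert np.array_equal(a.predicted_ild, b.predicted_ild)

    def test_leak_changes_results(self):
        rng = np.random.default_rng(4)
        resp, ilds_t, signs = mirrored_step_population(ILDS)
        noisy = resp[:2] + rng.normal(0, 0.8, (2, resp.shape[1])) + 0.5
        fair = opponent_decode(noisy, ilds_t, signs[:2])
        leak = opponent_decode(noisy, ilds_t, signs[:2], _leak_own_trial=True)
        assert np.any(fair.predicted_ild != leak.predicted_ild)

    def test_random_channel_labels_decode_at_chance(self):
        # iid random channel labels on a large mixed-slope population:
        # both channels share the same expected tuning, the opponent value
        # carries no ILD information, and the decoder falls to chance
        rng = np.random.default_rng(5)
        n = 200
        ilds_t = np.tile(ILDS, 36)
        slopes = rng.uniform(0.3, 1.0, n) * rng.choice([-1, 1], n)
        resp = slopes[:, None] * ilds_t[None, :] / 30.0 + 1.5
        resp += rng.normal(0, 1.0, resp.shape)
        mues = []
        for _ in range(30):
            labels = rng.choice(np.array(["contra", "ipsi"], dtype=object), size=n)
            if not ((labels == "contra").any() and (labels == "ipsi").any()):
                continue
            mues.append(opponent_decode(resp, ilds_t, labels).mue_db)
        assert np.mean(mues) == pytest.approx(chance_mue_db(), rel=0.2)

    def test_single_channel_rejected(self):
        resp, ilds_t, signs = mirrored_step_population(ILDS)
        with pytest.raises(ValueError):
            opponent_decode(resp, ilds_t, np.array(["contra"] * len(signs)))


class TestDecodeCurve:
    def _noisy_population(self, n=120, seed=6):
        rng = np.random.default_rng(seed)
        ilds_t = np.tile(ILDS, 36)
        slopes = rng.uniform(0.3, 1.0, n) * rng.choice([-1, 1], n)
        resp = slopes[:, None] * ilds_t[None, :] / 30.0 + 1.5
        resp = resp + rng.normal(0, 1.0, resp.shape)
        signs = np.where(slopes < 0, "contra", "ipsi").astype(object)
        return resp, ilds_t, signs

    def test_mue_non_increasing_with_population_size(self):
        resp, ilds_t, signs = self._noisy_population()
        curve = decode_curve(resp, ilds_t, signs, np.ones(len(signs), bool),
                             [10, 30, 60, 120], n_resamples=50, seed=1)
        mue = curve["mue_db_mean"].to_numpy()
        sd = curve["mue_db_sd"].to_numpy() / np.sqrt(curve["n_resamples"].to_numpy())
        tol = 3 * np.sqrt(sd[:-1] ** 2 + sd[1:] ** 2)
        assert np.all(np.diff(mue) <= tol)

    def test_chance_level_bracketed(self):
        resp, ilds_t, signs = self._noisy_population()
        curve = decode_curve(resp, ilds_t, signs, np.ones(len(signs), bool),
                             [120], n_resamples=10, seed=2)
        assert 0 < curve["mue_db_mean"].iloc[0] < chance_mue_db()

    def test_normalized_mue_bounded(self):
        resp, ilds_t, signs = self._noisy_population()
        curve = decode_curve(resp, ilds_t, signs, np.ones(len(signs), bool),
                             [10], n_resamples=10, seed=3)
        assert 0 <= curve["mue_norm_mean"].iloc[0] <= 1


def test_end_to_end_channels_on_synthetic_population(small_tensor):
    """Channel assignment and decoding run end-to-end on pipeline output."""
    cfg = RunConfig()
    chan = assign_channel(small_tensor, alpha=cfg.alpha_anova)
    resp, ilds_t = noise_trial_responses(small_tensor)
    if chan.monotonic.sum() >= 2 and \
            (chan.sign[chan.monotonic] == "contra").any() and \
            (chan.sign[chan.monotonic] == "ipsi").any():
        pool = np.flatnonzero(chan.monotonic)
        res = opponent_decode(resp[pool], ilds_t, np.array(chan.sign)[pool])
        assert res.mue_db < chance_mue_db()
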