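"""Generator tests: schedule structure, rate model, determinism, and
planted spatial structure."""

import numpy as np
import pandas as pd
import pytest

from ildpipe import extract_responses, process_recording
from ildpipe.spatial import noise_correlation
from ildpipe.synthetic import (
    NOISE_BINAURAL,
    NOISE_MON_CONTRA,
    NOISE_MON_IPSI,
    TONE,
    GroundTruthNeuron,
    SimParams,
    StimulusSpec,
    build_stimulus_schedule,
    expected_rate,
    load_experiment,
    make_population,
    plant_spatial_structure,
    save_experiment,
    simulate_fluorescence,
)


class TestStimulusSchedule:
    def test_trial_counts(self):
        spec = StimulusSpec()
        tt = build_stimulus_schedule(spec, seed=1)
        noise = tt[tt.stim_class != TONE]
        tones = tt[tt.stim_class == TONE]
        # (7 ILDs + 2 monaural sides) x 3 ABLs x 12 reps
        assert len(noise) == (7 + 2) * 3 * 12 == 324
        assert len(tones) == 18 * 4 * 10 == 720

    def test_every_condition_exact_repetitions(self):
        tt = build_stimulus_schedule(StimulusSpec(), seed=3)
        noise = tt[tt.stim_class == NOISE_BINAURAL]
        counts = noise.groupby(["ild_db", "abl_db"]).size()
        assert (counts == 12).all() and len(counts) == 21
        tones = tt[tt.stim_class == TONE]
        assert (tones.groupby(["freq_hz", "level_db"]).size() == 10).all()

    def test_blocks_contiguous_and_onsets_spaced(self):
        spec = StimulusSpec()
        tt = build_stimulus_schedule(spec, seed=2)
        is_tone = (tt.stim_class == TONE).to_numpy()
        assert not is_tone[: spec.n_noise_trials].any()
        assert is_tone[spec.n_noise_trials:].all()
        assert (np.diff(tt.onset_frame) == spec.frames_per_trial).all()
        assert spec.frames_per_trial == 46  # round(30 / 0.65)

    def test_seed_determinism_and_variation(self):
        a = build_stimulus_schedule(StimulusSpec(), seed=5)
        b = build_stimulus_schedule(StimulusSpec(), seed=5)
        c = build_stimulus_schedule(StimulusSpec(), seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(n_noise_reps=0)
        with pytest.raises(ValueError):
            StimulusSpec(ild_values=(-30.0, -10.0, 0.0, 10.0, 30.0, 40.0))


class TestExpectedRate:
    def _stim(self, cls, ild=0.0, abl=60.0):
        return {"stim_class": cls, "ild_db": ild, "abl_db": abl,
                "freq_hz": np.nan, "level_db": np.nan}

    def test_untuned_rate_is_baseline_plus_scaled_gain(self):
        n = GroundTruthNeuron(tuning_type="untuned", baseline_rate_hz=2.0,
                              response_gain=30.0, carryover_comp=0.0)
        for ild in (-30.0, 0.0, 30.0):
            r = expected_rate(n, self._stim(NOISE_BINAURAL, ild, 80.0))
            assert r == pytest.approx(2.0 + 30.0 * n.abl_gain[80.0])

    def test_monotonic_contra_prefers_negative_ild(self):
        n = GroundTruthNeuron(tuning_type="monotonic-contra")
        assert expected_rate(n, self._stim(NOISE_BINAURAL, -30.0)) > \
            expected_rate(n, self._stim(NOISE_BINAURAL, 30.0))

    def test_oof_neuron_monaural_rates_at_baseline(self):
        n = GroundTruthNeuron(binaural_class_truth="OO/F", baseline_rate_hz=1.5)
        assert expected_rate(n, self._stim(NOISE_MON_CONTRA)) == pytest.approx(1.5)
        assert expected_rate(n, self._stim(NOISE_MON_IPSI)) == pytest.approx(1.5)
        assert expected_rate(n, self._stim(NOISE_BINAURAL)) > 1.5

    def test_rates_clamped_nonnegative(self):
        n = GroundTruthNeuron(baseline_rate_hz=0.0)
        assert expected_rate(n, self._stim(NOISE_MON_IPSI)) >= 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthNeuron(baseline_rate_hz=-1.0)
        with pytest.raises(ValueError):
            GroundTruthNeuron(tuning_type="peaked", ild_width_db=0.0)
        with pytest.raises(ValueError):
            GroundTruthNeuron(binaural_class_truth="XX")


class TestSimulation:
    def test_seed_reproducibility_bit_identical(self):
        pop = make_population(5, seed=1)
        p = SimParams(include_tones=False)
        a = simulate_fluorescence(pop, p, seed=9)
        b = simulate_fluorescence(make_population(5, seed=1), p, seed=9)
        assert np.array_equal(a.recording.traces, b.recording.traces)
        assert np.array_equal(a.recording.neuropil, b.recording.neuropil)
        c = simulate_fluorescence(pop, p, seed=10)
        assert not np.array_equal(a.recording.traces, c.recording.traces)

    def test_zero_gain_noiseless_trace_constant(self):
        n = GroundTruthNeuron(binaural_class_truth="unresponsive",
                              baseline_rate_hz=0.0)
        exp = simulate_fluorescence(
            [n], SimParams(noiseless=True, include_tones=False), seed=1)
        tr = exp.recording.traces[:, 0]
        assert np.ptp(tr) == pytest.approx(0.0)

    def test_negative_kernel_times_rejected(self):
        from ildpipe.synthetic import calcium_kernel
        with pytest.raises(ValueError):
            calcium_kernel(30.0, rise_s=-0.1, decay_s=0.6)

    def test_shared_latent_drives_noise_correlation_to_one(self):
        # two neurons, full latent share, no private noise
        neurons = [
            GroundTruthNeuron(tuning_type="untuned", baseline_rate_hz=0.0,
                              response_gain=0.0, noise_share=1.0,
                              binaural_class_truth="unresponsive")
            for _ in range(2)
        ]
        for n in neurons:
            n.response_gain = 0.0
        params = SimParams(include_tones=False, white_noise_sd=0.0,
                           drift_amp=0.0, poisson_spikes=False, latent_sd=0.2)
        exp = simulate_fluorescence(neurons, params, seed=3)
        tensor = process_recording(exp.recording, exp.trials, r_neuropil=0.0)
        labels = list(zip(tensor.trials.stim_class, tensor.trials.ild_db,
                          tensor.trials.abl_db))
        r = noise_correlation(tensor.responses[0], tensor.responses[1], labels)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_response_scales_with_gain_noiseless(self):
        # doubling the response gain doubles the extracted response
        def mean_resp(gain):
            n = GroundTruthNeuron(tuning_type="untuned", baseline_rate_hz=0.0,
                                  response_gain=gain, carryover_comp=0.0,
                                  abl_gain={40.0: 1.0, 60.0: 1.0, 80.0: 1.0})
            exp = simulate_fluorescence(
                [n], SimParams(noiseless=True, include_tones=False), seed=4)
            t = process_recording(exp.recording, exp.trials, r_neuropil=0.0)
            m = t.trials.stim_class == NOISE_BINAURAL
            return t.responses[0, m.to_numpy()].mean()

        # small-transient regime: F0 is essentially unaffected by the
        # stimulus-evoked fluorescence, so responses scale linearly
        r1, r2 = mean_resp(4.0), mean_resp(8.0)
        assert r2 / r1 == pytest.approx(2.0, rel=0.05)
        # at high rates the baseline estimate absorbs part of the evoked
        # signal and the scaling becomes mildly sublinear, but stays monotone
        r3, r4 = mean_resp(20.0), mean_resp(40.0)
        assert r3 > r2 and r4 > r3
        assert r4 / r3 == pytest.approx(2.0, rel=0.15)


class TestSpatialStructure:
    def test_perfect_gradient_recovered_exactly(self):
        pop = make_population(50, seed=2, with_bf=1.0)
        pop = plant_spatial_structure(pop, seed=2, gradient_angle_deg=30.0,
                                      bf_jitter_oct=0.0)
        pos = np.array([n.position[:2] for n in pop])
        proj = pos @ np.array([np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30))])
        log_bf = np.log2([n.bf_hz for n in pop])
        r = np.corrcoef(proj, log_bf)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_positions_inside_field(self):
        pop = plant_spatial_structure(make_population(30, seed=3), seed=3,
                                      field_extent_um=(400.0, 200.0))
        pos = np.array([n.position for n in pop])
        assert (pos[:, 0] <= 400).all() and (pos[:, 1] <= 200).all()
        assert (pos >= 0).all()

    def test_cluster_center_outside_field_rejected(self):
        with pytest.raises(ValueError):
            plant_spatial_structure(make_population(10, seed=4), seed=4,
                                    field_extent_um=(400.0, 200.0),
                                    ild_cluster_centers=[(900.0, 100.0, 0.0)])

    def test_planted_clusters_make_local_pairs_similar(self):
        from scipy.spatial.distance import pdist
        pop = make_population(60, seed=5)
        pop = plant_spatial_structure(
            pop, seed=5, field_extent_um=(500.0, 250.0),
            ild_cluster_centers=[(50.0, 125.0, -15.0), (450.0, 125.0, 15.0)],
            cluster_spread_db=2.0)
        pos = np.array([n.position[:2] for n in pop])
        truth = np.array([n.weighted_ild_truth() for n in pop])
        d = pdist(pos)
        pref = pdist(truth[:, None], metric="cityblock")
        assert pref[d <= 150].mean() < pref[d > 150].mean()


class TestIO:
    def test_params_yaml_export(self, tmp_path):
        import yaml
        from ildpipe.synthetic import save_params_yaml
        p = tmp_path / "params.yaml"
        save_params_yaml(SimParams(), p)
        d = yaml.safe_load(p.read_text())
        assert d["spec"]["frame_rate_hz"] == 30.0
        assert d["kernel_decay_s"] == 0.6

    def test_hdf5_round_trip(self, tmp_path):
        pop = plant_spatial_structure(make_population(4, seed=6), seed=6)
        exp = simulate_fluorescence(
            pop, SimParams(include_tones=False), seed=6)
        path = tmp_path / "exp.h5"
        save_experiment(exp, path)
        rec, trials, gt = load_experiment(path)
        assert np.array_equal(rec.traces, exp.recording.traces)
        assert np.array_equal(rec.positions, exp.recording.positions)
        assert len(trials) == len(exp.trials)
        assert list(gt["binaural_class"]) == [n.binaural_class_truth for n in pop]
        pd.testing.assert_series_equal(
            trials["onset_frame"].astype(int),
            exp.trials["onset_frame"].astype(int), check_names=False)
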