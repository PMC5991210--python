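"""Validation scenarios: the study conditions under which the pipeline's
statistical behavior is characterized.

Each function builds a synthetic scenario with the generator's default
conditions, runs the relevant pipeline stage from scratch, and returns the
measured quantity (a rejection rate, a recovery fraction, a decoder error
curve). They are used both by the test suite and by the acceptance script.

Scenario definitions (rationale in docs/methods.md):

* type-I calibration uses *silent* null neurons (no spikes), so traces
  carry only measurement noise — the natural no-signal null for a
  responsiveness test;
* the two-way ANOVA null is a response-grid simulation (iid normal
  responses on the 18 x 4 x 10 grid);
* parameter recovery uses 300-neuron experiments: full Poisson noise for
  peak-ILD recovery and the decoder, deterministic spike counts (leaving
  white measurement noise, ~response/10 at the FRA peak) for exact BF
  recovery;
* binaural-class recovery runs in the fully deterministic (noise-free)
  limit on amplitude-homogeneous neurons, one per class;
* cluster-test calibration uses per-mouse fields of 30 neurons over
  1000 x 250 um (spatially random values), and the power scenario plants
  two ILD clusters 400 um apart (2 dB within-cluster spread, 30 dB gap);
* gradient recovery plants a 37-degree tonotopic axis over a 500 x 250 um
  region (4-octave span, 0.3-octave BF jitter, 120 neurons).
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .decoding import assign_channel, decode_curve, noise_trial_responses, opponent_decode
from .signal_extraction import process_recording
from .spatial import cluster_test
from .synthetic import (
    BINAURAL_CLASSES,
    NOISE_BINAURAL,
    GroundTruthNeuron,
    SimParams,
    StimulusSpec,
    default_tone_freqs,
    make_population,
    plant_spatial_structure,
    simulate_fluorescence,
)
from .tuning import (
    compute_neuron_profiles,
    paired_onetailed_p,
    test_ild_sensitivity,
    tonotopic_gradient,
    twoway_anova_balanced,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


def silent_null_rates(
    seed: int, n_neurons: int = 3500, batch: int = 500,
    alpha_t: float = 0.01, alpha_anova: float = 0.05,
) -> dict:
    """Type-I rates of the responsiveness t-test and the ILD ANOVA.

    Simulates silent neurons (no spikes; white measurement noise only)
    through the full trace pipeline and runs the per-condition one-tailed
    paired t-tests (21 ILD x ABL conditions per neuron) and the per-ABL
    one-way ILD ANOVA (3 per neuron).
    """
    seeds = _child_seeds(seed, (n_neurons + batch - 1) // batch)
    t_ps, a_ps = [], []
    for b, s in enumerate(seeds):
        nb = min(batch, n_neurons - b * batch)
        neurons = [GroundTruthNeuron(binaural_class_truth="unresponsive",
                                     baseline_rate_hz=0.0, noise_share=0.0,
                                     bf_hz=None) for _ in range(nb)]
        exp = simulate_fluorescence(neurons, SimParams(include_tones=False), seed=s)
        tensor = process_recording(exp.recording, exp.trials)
        tr = tensor.trials
        abls = sorted(tr["abl_db"].dropna().unique())
        ilds = np.sort(tr.loc[tr["stim_class"] == NOISE_BINAURAL, "ild_db"].dropna().unique())
        for abl in abls:
            groups = []
            for ild in ilds:
                cols = tr.index[(tr["stim_class"] == NOISE_BINAURAL)
                                & (tr["abl_db"] == abl) & (tr["ild_db"] == ild)].to_numpy()
                t_ps.append(paired_onetailed_p(
                    tensor.pre_peaks[:, cols], tensor.post_peaks[:, cols], axis=1))
                groups.append(tensor.responses[:, cols])
            _, p = test_ild_sensitivity(groups, alpha=alpha_anova)
            a_ps.append(p)
    t_ps = np.concatenate(t_ps)
    a_ps = np.concatenate(a_ps)
    return {
        "ttest_rate_pct": float(100 * np.mean(t_ps < alpha_t)),
        "ttest_n": int(t_ps.size),
        "anova_rate_pct": float(100 * np.mean(a_ps < alpha_anova)),
        "anova_n": int(a_ps.size),
    }


def twoway_null_grid_rate(seed: int, n_grids: int = 10000,
                          alpha: float = 0.05) -> dict:
    """Type-I rate of the two-way frequency x level ANOVA on null grids.

    Responses are iid normal on the default 18-frequency x 4-level x
    10-repetition grid (no frequency or level effect).
    """
    rng = np.random.default_rng(seed)
    out_f, out_l = [], []
    for start in range(0, n_grids, 2000):
        nb = min(2000, n_grids - start)
        cells = rng.normal(size=(nb, 18, 4, 10))
        res = twoway_anova_balanced(cells)
        out_f.append(res["p_freq"])
        out_l.append(res["p_level"])
    p_f = np.concatenate(out_f)
    p_l = np.concatenate(out_l)
    return {
        "freq_rate_pct": float(100 * np.mean(p_f < alpha)),
        "level_rate_pct": float(100 * np.mean(p_l < alpha)),
        "n": int(p_f.size),
    }


def recovery_experiment(seed: int, n_neurons: int = 300) -> dict:
    """Peak-ILD and BF recovery on 300-neuron synthetic experiments.

    Peak ILD: full-noise experiment; among planted-tuned neurons flagged
    ILD-sensitive at 60 dB ABL, fraction with recovered peak within 10 dB
    of the planted peak. BF: deterministic-spike experiment (white
    measurement noise only, ~response/10 at the FRA peak) with planted BFs
    snapped to the tone grid; among planted-BF neurons flagged
    frequency-sensitive, fraction with the exact grid BF recovered.
    """
    s1, s2, s3, s4 = _child_seeds(seed, 4)
    cfg = RunConfig()
    grid = default_tone_freqs()

    pop = make_population(n_neurons, seed=s1)
    exp = simulate_fluorescence(pop, SimParams(include_tones=False), seed=s2)
    tensor = process_recording(exp.recording, exp.trials)
    prof = compute_neuron_profiles(tensor, cfg)
    gt = exp.ground_truth_frame()
    tuned = (gt["tuning_type"] != "untuned").to_numpy()
    det = prof["ild_sensitive_abl60"].to_numpy(dtype=bool)
    both = tuned & det
    err = np.abs(prof["peak_ild_abl60"].to_numpy()[both]
                 - gt["peak_ild_truth"].to_numpy()[both])
    peak_pct = float(100 * np.mean(err <= 10)) if both.any() else np.nan

    pop2 = make_population(n_neurons, seed=s3)
    for n in pop2:
        if n.bf_hz is not None:
            n.bf_hz = float(grid[np.argmin(np.abs(np.log2(grid / n.bf_hz)))])
    exp2 = simulate_fluorescence(pop2, SimParams(poisson_spikes=False), seed=s4)
    tensor2 = process_recording(exp2.recording, exp2.trials)
    prof2 = compute_neuron_profiles(tensor2, cfg)
    gt2 = exp2.ground_truth_frame()
    has_bf = np.isfinite(gt2["bf_hz"].to_numpy())
    fs = prof2["freq_sensitive"].to_numpy(dtype=bool)
    b2 = has_bf & fs
    bf_match = np.isclose(prof2["bf_hz"].to_numpy()[b2], gt2["bf_hz"].to_numpy()[b2])
    return {
        "peak_ild_within_10db_pct": peak_pct,
        "peak_ild_n": int(both.sum()),
        "ild_detection_pct": float(100 * det[tuned].mean()),
        "bf_exact_pct": float(100 * np.mean(bf_match)) if b2.any() else np.nan,
        "bf_n": int(b2.sum()),
        "tensor": tensor,
        "profiles": prof,
        "experiment": exp,
    }


def class_recovery_rate(seed: int, abl_db: float = 60.0) -> dict:
    """Noise-free binaural-class recovery on amplitude-homogeneous neurons.

    One untuned neuron per planted class (flat ABL gain so the carryover
    compensation is exact at every ABL); fully deterministic simulation;
    classification at the reference ABL must reproduce every planted class.
    """
    from .binaural import categorize_population

    classes = [c for c in BINAURAL_CLASSES]
    neurons = [GroundTruthNeuron(
        tuning_type="untuned", binaural_class_truth=c, baseline_rate_hz=2.0,
        response_gain=40.0, noise_share=0.0, bf_hz=None,
        abl_gain={40.0: 1.0, 60.0: 1.0, 80.0: 1.0}) for c in classes]
    exp = simulate_fluorescence(
        neurons, SimParams(noiseless=True, include_tones=False), seed=seed)
    tensor = process_recording(exp.recording, exp.trials)
    cats = categorize_population(tensor, RunConfig()).set_index(["neuron", "abl_db"])
    got = [cats.loc[(i, abl_db), "category"] for i in range(len(classes))]
    ok = sum(g == c for g, c in zip(got, classes))
    return {
        "recovered_pct": float(100 * ok / len(classes)),
        "n_classes": len(classes),
        "mismatches": [(c, g) for c, g in zip(classes, got) if c != g],
    }


def mirrored_step_population(ilds: np.ndarray, n_reps: int = 12):
    """Noiseless opponent-separable population: mirrored step pairs.

    One contra-preferring step neuron per inter-ILD threshold (response 1
    for ILDs at or below the threshold) and its ipsi mirror, so the
    population opponent value is strictly monotonic in ILD and every ILD
    is decodable without error.

    Returns (responses (n_neurons, n_trials), trial ILDs, channel signs).
    """
    ilds = np.asarray(ilds, dtype=float)
    trial_ilds = np.repeat(ilds, n_reps)
    thresholds = (ilds[:-1] + ilds[1:]) / 2
    rows, signs = [], []
    for th in thresholds:
        rows.append((trial_ilds <= th).astype(float))
        signs.append("contra")
        rows.append((trial_ilds >= -th).astype(float))
        signs.append("ipsi")
    return np.vstack(rows), trial_ilds, np.array(signs)


def decoder_suite(seed: int, n_neurons: int = 300, n_resamples: int = 100,
                  population_sizes=(10, 25, 50, 100, 200, 300),
                  tensor=None) -> dict:
    """Decoder behavior: noiseless separable MUE, the MUE-vs-size curve on
    a noisy 300-neuron experiment, the chance level under shuffled channel
    labels, and the effect of deliberately breaking the leave-one-out
    discipline."""
    s1, s2, s3 = _child_seeds(seed, 3)
    cfg = RunConfig()
    ilds = np.array(StimulusSpec().ild_values)

    resp_s, ild_s, signs_s = mirrored_step_population(ilds)
    noiseless = opponent_decode(resp_s, ild_s, signs_s, max_error_db=cfg.max_decoder_error_db)

    if tensor is None:
        pop = make_population(n_neurons, seed=s1)
        exp = simulate_fluorescence(pop, SimParams(include_tones=False), seed=s2)
        tensor = process_recording(exp.recording, exp.trials)
    prof = compute_neuron_profiles(tensor, cfg)
    responsive = prof["noise_responsive_any"].to_numpy(dtype=bool)
    chan = assign_channel(tensor, responsive, alpha=cfg.alpha_anova)
    resp, ild_t = noise_trial_responses(tensor)
    curve = decode_curve(resp, ild_t, chan.sign, chan.monotonic,
                         population_sizes, n_resamples=n_resamples, seed=s3,
                         max_error_db=cfg.max_decoder_error_db)

    # chance level: channel labels randomized (iid) on the tuned population,
    # so both channels have the same expected tuning and the opponent value
    # carries no ILD information
    rng = np.random.default_rng(s3)
    pool = np.flatnonzero(chan.monotonic)
    mues = []
    for _ in range(20):
        labels = rng.choice(np.array(["contra", "ipsi"], dtype=object), size=len(pool))
        if not ((labels == "contra").any() and (labels == "ipsi").any()):
            continue
        mues.append(opponent_decode(resp[pool], ild_t, labels).mue_db)
    shuffled_mue = float(np.mean(mues))

    # leave-one-out discipline: with a small noisy population, leaking the
    # decoded trial into its own reference must change the outcome
    signs_pool = np.array(chan.sign, dtype=object)[pool]
    small = np.concatenate([pool[signs_pool == "contra"][:1],
                            pool[signs_pool == "ipsi"][:1]])
    small_signs = np.array(chan.sign, dtype=object)[small]
    # restrict to one ABL (12 reps per ILD) so each trial carries real
    # weight in its own reference
    one_abl = (tensor.trials["stim_class"] == NOISE_BINAURAL) \
        & (tensor.trials["abl_db"] == 60.0)
    cols = np.flatnonzero(one_abl.to_numpy())
    r_small = tensor.responses[np.ix_(small, cols)]
    i_small = tensor.trials["ild_db"].to_numpy(dtype=float)[cols]
    leak = opponent_decode(r_small, i_small, small_signs, _leak_own_trial=True)
    fair = opponent_decode(r_small, i_small, small_signs)
    return {
        "noiseless_mue_db": noiseless.mue_db,
        "curve": curve,
        "shuffled_mue_db": shuffled_mue,
        "leak_changes_predictions": bool(
            np.any(leak.predicted_ild != fair.predicted_ild)
            or leak.mue_db != fair.mue_db),
        "monotonic_n": int(chan.monotonic.sum()),
    }


def cluster_fp_rate(seed: int, n_fields: int = 400, n_neurons: int = 30,
                    field_extent=(1000.0, 250.0), n_boot: int = 1000) -> dict:
    """False-positive rate of the spatial clustering bootstrap under
    spatially random values, at per-mouse realistic density."""
    rng = np.random.default_rng(seed)
    hits = 0
    conclusive = 0
    for _ in range(n_fields):
        pos = rng.uniform([0, 0], list(field_extent), size=(n_neurons, 2))
        vals = rng.uniform(-30, 30, n_neurons)
        r = cluster_test(vals, pos, n_boot=n_boot, seed=int(rng.integers(2**31)))
        if r.conclusive:
            conclusive += 1
            hits += r.significant
    return {"fp_rate_pct": float(100 * hits / max(1, conclusive)),
            "n_fields": conclusive}


def cluster_power(seed: int, n_fields: int = 200, n_neurons: int = 30,
                  field_extent=(1000.0, 250.0), gap_db: float = 30.0,
                  spread_db: float = 2.0, separation_um: float = 400.0,
                  n_boot: int = 1000) -> dict:
    """Power of the clustering bootstrap for two planted ILD clusters."""
    rng = np.random.default_rng(seed)
    w, h = field_extent
    cx = (w - separation_um) / 2
    centers = np.array([[cx, h / 2], [cx + separation_um, h / 2]])
    hits = 0
    conclusive = 0
    for _ in range(n_fields):
        pos = rng.uniform([0, 0], [w, h], size=(n_neurons, 2))
        cid = np.linalg.norm(pos[:, None] - centers[None], axis=2).argmin(axis=1)
        vals = np.where(cid == 0, -gap_db / 2, gap_db / 2) + rng.normal(0, spread_db, n_neurons)
        r = cluster_test(vals, pos, n_boot=n_boot, seed=int(rng.integers(2**31)))
        if r.conclusive:
            conclusive += 1
            hits += r.significant
    return {"power_pct": float(100 * hits / max(1, conclusive)),
            "n_fields": conclusive}


def gradient_recovery_rate(seed: int, n_sims: int = 200, n_neurons: int = 120,
                           angle_deg: float = 37.0, jitter_oct: float = 0.3,
                           field_extent=(500.0, 250.0),
                           tol_deg: float = 5.0) -> dict:
    """Fraction of simulations recovering a planted tonotopic axis within
    ``tol_deg`` of the true angle."""
    seeds = _child_seeds(seed, 2 * n_sims)
    ok = 0
    for i in range(n_sims):
        pop = make_population(n_neurons, seed=seeds[2 * i], with_bf=1.0)
        pop = plant_spatial_structure(
            pop, seed=seeds[2 * i + 1], field_extent_um=field_extent,
            gradient_angle_deg=angle_deg, gradient_span_oct=4.0,
            bf_jitter_oct=jitter_oct)
        pos = np.array([n.position[:2] for n in pop])
        bfs = np.array([n.bf_hz for n in pop])
        fit = tonotopic_gradient(pos, bfs)
        err = abs((fit.angle_deg - angle_deg + 180) % 360 - 180)
        ok += err <= tol_deg
    return {"recovered_pct": float(100 * ok / n_sims), "n_sims": n_sims}
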