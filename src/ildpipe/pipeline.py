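"""End-to-end orchestration: extract -> tune -> categorize -> decode -> spatial.

``run_pipeline`` executes the enabled stages in order on one experiment
(an HDF5 file produced by :mod:`ildpipe.synthetic` or equivalent real
data), writes intermediate CSV/JSON artifacts if an output directory is
given, and returns a :class:`RunReport` with per-stage counts, summary
tables, exclusion logs, timings, and the configuration hash. Reruns with
the same inputs and config are deterministic (seed-identical for the
stochastic stages).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binaural import categorize_population, category_summary
from .config import RunConfig
from .decoding import (assign_channel, build_population_matrix, decode_curve,
                       noise_trial_responses, run_pca)
from .signal_extraction import FluorescenceRecording, ResponseTensor, process_recording
from .spatial import (cluster_tests_for_experiment, correlation_vs_distance,
                      pairwise_correlations)
from .synthetic import NOISE_BINAURAL, load_experiment
from .tuning import compute_neuron_profiles

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str, record=None):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.record = record


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    config_hash: str
    version: str
    counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "config_hash": self.config_hash,
            "version": self.version,
            "counts": self.counts,
            "exclusions": self.exclusions,
            "summaries": self.summaries,
            "timings_s": self.timings_s,
        }, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    return str(o)


def validate_inputs(path) -> list[dict]:
    """Check the HDF5 layout and trial/trace alignment; returns diagnostics.

    Each diagnostic is a dict with keys (severity, code, message, hint);
    an empty list means the file is well-formed.
    """
    import h5py

    issues: list[dict] = []

    def issue(sev, code, msg, hint=""):
        issues.append({"severity": sev, "code": code, "message": msg, "hint": hint})

    try:
        f = h5py.File(path, "r")
    except OSError as e:
        issue("error", "unreadable", f"cannot open {path}: {e}")
        return issues
    with f:
        for ds in ("traces", "neuropil", "positions"):
            if ds not in f:
                issue("error", f"missing_{ds}", f"dataset /{ds} not found",
                      "regenerate the file with ildpipe.synthetic.save_experiment")
        if "trial_table" not in f:
            issue("error", "missing_trial_table", "group /trial_table not found")
            return issues
        if "traces" in f and "neuropil" in f and f["traces"].shape != f["neuropil"].shape:
            issue("error", "shape_mismatch", "traces and neuropil shapes differ")
        needed = {"stim_class", "onset_frame", "ild_db", "abl_db"}
        have = set(f["trial_table"].keys())
        for col in needed - have:
            issue("error", f"missing_col_{col}", f"trial table lacks column {col}")
        if "onset_frame" in have and "traces" in f:
            onsets = f["trial_table"]["onset_frame"][()]
            n_frames = f["traces"].shape[0]
            bad = onsets[onsets + 1 > n_frames]
            if len(bad):
                issue("error", "onset_beyond_trace",
                      f"{len(bad)} trial onsets beyond trace length {n_frames}")
        if {"stim_class", "ild_db", "abl_db"} <= have:
            cls = f["trial_table"]["stim_class"][()].astype(str)
            ild = f["trial_table"]["ild_db"][()]
            abl = f["trial_table"]["abl_db"][()]
            m = cls == NOISE_BINAURAL
            if m.any():
                df = pd.DataFrame({"ild": ild[m], "abl": abl[m]})
                counts = df.groupby(["abl", "ild"]).size()
                if counts.nunique() > 1:
                    issue("warning", "unbalanced_noise",
                          "unequal repetition counts across ILD x ABL conditions")
    return issues


def run_pipeline(
    config: RunConfig,
    input_path=None,
    recording: FluorescenceRecording | None = None,
    trials: pd.DataFrame | None = None,
    output_dir=None,
) -> tuple[RunReport, dict]:
    """Run the enabled stages on one experiment.

    Provide either ``input_path`` (HDF5) or an in-memory ``recording`` +
    ``trials`` pair. Returns (report, artifacts) where artifacts maps stage
    names to their in-memory products (tensor, profiles, categories, pca,
    decoder curve, correlation/cluster results).
    """
    report = RunReport(config_hash=config.config_hash(), version=__version__)
    artifacts: dict = {}
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    if recording is None or trials is None:
        if input_path is None:
            raise StageError("extract", "no input provided")
        try:
            recording, trials, _ = load_experiment(input_path)
        except Exception as e:
            raise StageError("extract", f"cannot load {input_path}: {e}") from e

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info(json.dumps({"stage": stage, "event": "start"}))
                return self

            def __exit__(self, *exc):
                report.timings_s[stage] = round(time.perf_counter() - self.t0, 3)
                logger.info(json.dumps({"stage": stage, "event": "end",
                                        "seconds": report.timings_s[stage]}))
        return _T()

    tensor: ResponseTensor | None = None
    profiles = None
    categories = pd.DataFrame()

    if "extract" in config.stages:
        with timed("extract"):
            tensor = process_recording(
                recording, trials,
                cutoff_hz=config.highpass_cutoff_hz,
                r_neuropil=config.r_neuropil,
                window_frames=config.window_frames,
                stat=config.response_stat,
            )
            report.counts["neurons_in"] = recording.n_neurons
            report.counts["neurons_excluded_extract"] = len(tensor.excluded_neurons)
            report.counts["neurons_analyzed"] = recording.n_neurons - len(tensor.excluded_neurons)
            report.counts["trials_in"] = len(trials)
            report.counts["trials_dropped"] = len(tensor.dropped_trials)
            report.exclusions["extract"] = [
                {"neuron": i, "reason": "non-finite trace or non-positive F0"}
                for i in tensor.excluded_neurons
            ] + [{"trial": int(t), "reason": "incomplete response window"}
                 for t in tensor.dropped_trials]
            artifacts["tensor"] = tensor
            if outdir is not None:
                tensor.to_tidy().to_csv(outdir / "responses.csv", index=False)
    if tensor is None:
        raise StageError("extract", "later stages require the extract stage")

    if "tune" in config.stages:
        with timed("tune"):
            profiles = compute_neuron_profiles(tensor, config)
            artifacts["profiles"] = profiles
            abl_cols = [c for c in profiles.columns if c.startswith("noise_responsive_abl")]
            report.summaries["responsive_pct_by_abl"] = {
                c.removeprefix("noise_responsive_"): float(100 * profiles[c].mean())
                for c in abl_cols
            }
            sens_cols = [c for c in profiles.columns if c.startswith("ild_sensitive_")]
            report.summaries["ild_sensitive_pct_by_abl"] = {
                c.removeprefix("ild_sensitive_"): float(100 * profiles[c].mean())
                for c in sens_cols
            }
            report.summaries["tone_responsive_pct"] = float(100 * profiles["tone_responsive"].mean())
            report.summaries["freq_sensitive_pct"] = float(100 * profiles["freq_sensitive"].mean())
            if outdir is not None:
                profiles.to_csv(outdir / "neuron_profiles.csv")

    if "categorize" in config.stages:
        if profiles is None:
            raise StageError("categorize", "requires the tune stage")
        with timed("categorize"):
            categories = categorize_population(tensor, config)
            artifacts["categories"] = categories
            if len(categories):
                summary = category_summary(categories)
                report.summaries["binaural_category_pct"] = {
                    f"abl{int(r.abl_db)}:{r.category}": float(r.percent)
                    for r in summary.itertuples()
                }
            if outdir is not None:
                categories.to_csv(outdir / "binaural_categories.csv", index=False)

    if "decode" in config.stages:
        if profiles is None:
            raise StageError("decode", "requires the tune stage")
        with timed("decode"):
            responsive = profiles["noise_responsive_any"].to_numpy(dtype=bool)
            pop = build_population_matrix(tensor, responsive)
            if pop.matrix.shape[0] >= 2:
                pca = run_pca(pop)
                artifacts["pca"] = pca
                report.summaries["pca_variance_explained_top3_pct"] = float(
                    100 * pca.variance_explained[:3].sum())
            resp, ild = noise_trial_responses(tensor)
            chan = assign_channel(tensor, responsive, alpha=config.alpha_anova)
            artifacts["channels"] = chan
            report.counts["monotonic_neurons"] = int(chan.monotonic.sum())
            if chan.monotonic.sum() >= 2 and \
                    (chan.sign[chan.monotonic] == "contra").any() and \
                    (chan.sign[chan.monotonic] == "ipsi").any():
                sizes = [s for s in config.decoder_population_sizes
                         if s <= max(10, int(chan.monotonic.sum()))]
                curve = decode_curve(
                    resp, ild, chan.sign, chan.monotonic, sizes,
                    n_resamples=config.decoder_resamples, seed=config.seed,
                    max_error_db=config.max_decoder_error_db)
                artifacts["decoder_curve"] = curve
                report.summaries["decoder_mue_db"] = {
                    str(int(r.population_size)): float(r.mue_db_mean)
                    for r in curve.itertuples()
                }
                if outdir is not None:
                    curve.to_csv(outdir / "decoder_curve.csv", index=False)
            else:
                logger.warning("decoder skipped: not enough monotonic neurons in both channels")

    if "spatial" in config.stages:
        if profiles is None:
            raise StageError("spatial", "requires the tune stage")
        with timed("spatial"):
            responsive = profiles["noise_responsive_any"].to_numpy(dtype=bool)
            noise_mask = (tensor.trials["stim_class"] == NOISE_BINAURAL).to_numpy()
            idx = np.flatnonzero(noise_mask)
            labels = list(zip(tensor.trials["ild_db"].to_numpy()[idx],
                              tensor.trials["abl_db"].to_numpy()[idx]))
            sel = np.flatnonzero(responsive)
            if len(sel) >= 2:
                pairs = pairwise_correlations(
                    tensor.responses[np.ix_(sel, idx)], labels,
                    tensor.positions[sel] if tensor.positions is not None else np.zeros((len(sel), 2)),
                    neuron_ids=sel)
                artifacts["pairs"] = pairs
                if len(pairs) >= 3:
                    fits = correlation_vs_distance(pairs)
                    artifacts["correlation_distance_fits"] = fits
                    report.summaries["correlation_vs_distance"] = {
                        f"{r.axis}:{r.kind}": {"slope_per_um": float(r.slope_per_um),
                                               "p": float(r.p)}
                        for r in fits.itertuples()
                    }
                if outdir is not None:
                    pairs.to_csv(outdir / "pairwise_correlations.csv", index=False)
            if tensor.positions is not None:
                abls = sorted(tensor.trials.loc[noise_mask, "abl_db"].dropna().unique())
                mid_abl = abls[len(abls) // 2] if abls else 60.0
                clusters = cluster_tests_for_experiment(
                    profiles, categories, tensor.positions, config,
                    abl_db=mid_abl, seed=config.seed)
                artifacts["cluster_tests"] = clusters
                report.summaries["cluster_tests"] = {
                    k: {"significant": v.significant, "conclusive": v.conclusive,
                        "observed": v.observed_local_mean,
                        "fifth_percentile": v.boot_fifth_percentile}
                    for k, v in clusters.items()
                }

    if outdir is not None:
        report.to_json(outdir / "report.json")
    return report, artifacts
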