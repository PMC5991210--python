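"""Raw fluorescence -> dF/F0 -> per-trial scalar responses.

The processing chain mirrors standard two-photon somatic imaging practice:

1. high-pass filter each neuron's raw trace (cut-off 0.02 Hz) to remove slow
   drift, realized as subtraction of a zero-phase moving average (phase
   preservation matters because responses are peak-based);
2. baseline F0 = median of the 10th-70th percentile of trace values (the top
   30% is excluded so calcium transients do not inflate the baseline);
3. dF/F0 = (F - F0) / F0;
4. neuropil decontamination: corrected = dF/F - r * neuropil dF/F (r = 0.6
   by default);
5. per-trial response = (peak dF/F in the 14 frames from stimulus onset)
   minus (peak dF/F in the 14 frames immediately before onset).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

CONDITION_COLUMNS = ["stim_class", "ild_db", "abl_db", "freq_hz", "level_db"]


@dataclass
class FluorescenceRecording:
    """Per-field raw data: cell traces, neuropil traces, geometry.

    traces, neuropil : (n_frames, n_neurons) arrays in raw fluorescence units
    frame_rate_hz    : imaging frame rate
    positions        : (n_neurons, 3) cortical coordinates in um
                       (rostro-caudal, dorso-ventral, depth)
    """

    traces: np.ndarray
    neuropil: np.ndarray
    frame_rate_hz: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.neuropil = np.asarray(self.neuropil, dtype=float)
        if self.traces.shape != self.neuropil.shape:
            raise ValueError("traces and neuropil must have the same shape")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not np.all(np.isfinite(self.traces)):
            logger.warning("recording contains non-finite trace samples")

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[1]


@dataclass
class DffTrace:
    """A baseline-normalized fluorescence trace with its F0."""

    values: np.ndarray
    f0: float


def highpass(trace: np.ndarray, cutoff_hz: float, frame_rate_hz: float) -> np.ndarray:
    """Remove fluctuations slower than ``cutoff_hz``, preserving the offset.

    Implemented as subtraction of a zero-phase moving average whose window
    spans one cut-off period (reflect padding at the edges), with the trace
    mean restored afterwards so downstream F0 stays positive. Works on 1-D
    traces or (n_frames, n_neurons) matrices (filtering along axis 0).
    """
    trace = np.asarray(trace, dtype=float)
    if cutoff_hz >= frame_rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    window = int(round(frame_rate_hz / cutoff_hz))
    n = trace.shape[0]
    if n < 3 * window:
        logger.warning(
            "trace of %d frames is shorter than 3 filter windows (%d); "
            "high-pass output may be biased", n, 3 * window,
        )
    if window <= 1:
        return trace.copy()
    window = min(window, n)
    low = uniform_filter1d(trace, size=window, axis=0, mode="reflect")
    return trace - low + trace.mean(axis=0, keepdims=trace.ndim > 1)


def baseline_f0(trace: np.ndarray) -> float:
    """Median of the samples whose rank percentile lies in [10, 70].

    Rank bounds are ceil(0.10 n) .. floor(0.70 n) on the sorted trace, so the
    brightest 30% of samples (transients) never enter the baseline.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    n = trace.size
    if n < 10:
        raise ValueError("need at least 10 frames to estimate F0")
    srt = np.sort(trace)
    lo = math.ceil(0.10 * n)
    hi = math.floor(0.70 * n)
    if hi <= lo:  # degenerate tiny trace
        lo, hi = 0, n
    return float(np.median(srt[lo:hi]))


def baseline_f0_matrix(traces: np.ndarray) -> np.ndarray:
    """Vectorized :func:`baseline_f0` over the columns of a frame x neuron matrix."""
    n = traces.shape[0]
    lo = math.ceil(0.10 * n)
    hi = math.floor(0.70 * n)
    srt = np.sort(traces, axis=0)
    return np.median(srt[lo:hi], axis=0)


def compute_dff(trace: np.ndarray, f0: float | np.ndarray) -> np.ndarray:
    """dF/F0 = (F - F0) / F0; requires a strictly positive baseline."""
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("F0 must be positive; corrupt baseline")
    return (np.asarray(trace, dtype=float) - f0) / f0


def neuropil_correct(trace: np.ndarray, neuropil_trace: np.ndarray, r: float) -> np.ndarray:
    """Subtract ``r`` times the neuropil dF/F from the cell dF/F."""
    if not 0 <= r < 1:
        raise ValueError("contamination ratio r must be in [0, 1)")
    trace = np.asarray(trace, dtype=float)
    neuropil_trace = np.asarray(neuropil_trace, dtype=float)
    if trace.shape != neuropil_trace.shape:
        raise ValueError("trace and neuropil trace shapes differ")
    return trace - r * neuropil_trace


@dataclass
class ResponseTensor:
    """Per-neuron, per-trial scalar responses with their condition labels.

    responses[i, j] = post_peaks[i, j] - pre_peaks[i, j] for neuron i on
    trial j. ``trials`` carries one row per retained trial, including the
    condition columns (stim_class, ild_db, abl_db, freq_hz, level_db).
    """

    responses: np.ndarray
    pre_peaks: np.ndarray
    post_peaks: np.ndarray
    trials: pd.DataFrame
    positions: np.ndarray | None = None
    dropped_trials: list = field(default_factory=list)
    excluded_neurons: list = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[1]

    def trial_mask(self, **conditions) -> np.ndarray:
        """Boolean mask over trials matching the given column values."""
        mask = np.ones(len(self.trials), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.trials[col] == val).to_numpy()
        return mask

    def condition_means(self, columns: list[str]) -> pd.DataFrame:
        """Trial-averaged responses per condition (neurons as columns r0..rN)."""
        df = self.trials[columns].copy()
        resp = pd.DataFrame(
            self.responses.T, columns=[f"r{i}" for i in range(self.n_neurons)],
            index=df.index,
        )
        return pd.concat([df, resp], axis=1).groupby(columns, dropna=False).mean()

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (neuron, trial, condition, response) table."""
        n, t = self.responses.shape
        out = self.trials.iloc[np.tile(np.arange(t), n)].reset_index(drop=True)
        out.insert(0, "neuron", np.repeat(np.arange(n), t))
        out["response"] = self.responses.ravel()
        return out


def extract_responses(
    dff: np.ndarray,
    trials: pd.DataFrame,
    window_frames: int = 14,
    stat: str = "peak",
    positions: np.ndarray | None = None,
) -> ResponseTensor:
    """Window the dF/F matrix around each stimulus onset.

    pre window  = [onset - window, onset - 1]
    post window = [onset, onset + window - 1]   (onset frame included)

    ``stat`` chooses the window statistic: "peak" (max, default) or "sum".
    Trials lacking a complete pre or post window are dropped and logged.
    """
    if stat not in ("peak", "sum"):
        raise ValueError("stat must be 'peak' or 'sum'")
    dff = np.asarray(dff, dtype=float)
    if dff.ndim == 1:
        dff = dff[:, None]
    n_frames, n_neurons = dff.shape
    onsets = trials["onset_frame"].to_numpy(dtype=int)
    ok = (onsets >= window_frames) & (onsets + window_frames <= n_frames)
    dropped = trials.index[~ok].tolist()
    if dropped:
        logger.warning("dropping %d trials without complete windows: %s",
                       len(dropped), dropped[:10])
    kept = trials.loc[ok].reset_index(drop=True)
    onsets = onsets[ok]
    # gather windows: (n_trials, window) frame indices
    pre_idx = onsets[:, None] + np.arange(-window_frames, 0)[None, :]
    post_idx = onsets[:, None] + np.arange(0, window_frames)[None, :]
    reducer = np.max if stat == "peak" else np.sum
    # dff[pre_idx] -> (n_trials, window, n_neurons)
    pre = reducer(dff[pre_idx], axis=1).T   # (n_neurons, n_trials)
    post = reducer(dff[post_idx], axis=1).T
    return ResponseTensor(
        responses=post - pre,
        pre_peaks=pre,
        post_peaks=post,
        trials=kept,
        positions=positions,
        dropped_trials=dropped,
    )


def process_recording(
    recording: FluorescenceRecording,
    trials: pd.DataFrame,
    cutoff_hz: float = 0.02,
    r_neuropil: float = 0.6,
    window_frames: int = 14,
    stat: str = "peak",
) -> ResponseTensor:
    """Full chain: high-pass -> dF/F (cell and neuropil) -> neuropil
    correction -> per-trial response extraction.

    Neurons whose estimated F0 is non-positive or whose trace contains
    non-finite samples are excluded (their rows are NaN in the output and
    listed in ``ResponseTensor.dropped_trials`` is reserved for trials; the
    exclusion is logged and returned via the ``excluded_neurons`` attribute
    attached to the tensor).
    """
    traces = recording.traces
    neuropil = recording.neuropil
    bad = ~np.all(np.isfinite(traces), axis=0)
    excluded = np.flatnonzero(bad).tolist()
    if excluded:
        logger.warning("excluding %d neurons with non-finite traces: %s",
                       len(excluded), excluded[:10])
        traces = traces.copy()
        traces[:, bad] = 1.0  # placeholder; rows NaN-ed below

    hp = highpass(traces, cutoff_hz, recording.frame_rate_hz)
    hp_np = highpass(neuropil, cutoff_hz, recording.frame_rate_hz)
    f0 = baseline_f0_matrix(hp)
    f0_np = baseline_f0_matrix(hp_np)
    bad_f0 = f0 <= 0
    if np.any(bad_f0):
        newly = np.flatnonzero(bad_f0 & ~bad).tolist()
        if newly:
            logger.warning("excluding %d neurons with non-positive F0: %s",
                           len(newly), newly[:10])
        excluded = sorted(set(excluded) | set(np.flatnonzero(bad_f0).tolist()))
        f0 = np.where(bad_f0, 1.0, f0)
    f0_np = np.where(f0_np <= 0, 1.0, f0_np)
    dff = compute_dff(hp, f0)
    dff_np = compute_dff(hp_np, f0_np)
    corrected = neuropil_correct(dff, dff_np, r_neuropil)
    tensor = extract_responses(corrected, trials, window_frames, stat,
                               positions=recording.positions)
    if excluded:
        tensor.responses[excluded, :] = np.nan
        tensor.pre_peaks[excluded, :] = np.nan
        tensor.post_peaks[excluded, :] = np.nan
    tensor.excluded_neurons = excluded
    return tensor
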