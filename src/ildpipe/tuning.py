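"""Per-neuron tuning statistics: responsiveness, ILD and frequency
sensitivity, tuning-curve summaries, and field-level tonotopy.

Statistical conventions follow the analysis this package reimplements:

* responsiveness: one-tailed paired t-test (post-window peak > pre-window
  peak) per stimulus condition, alpha 0.01; a neuron is responsive to a
  stimulus family if any of its conditions is significant;
* ILD sensitivity: one-way ANOVA over the 7 ILDs, separately per ABL,
  alpha 0.05;
* frequency sensitivity: two-way ANOVA (frequency x level) on tone
  responses, alpha 0.05 on the main effect of frequency;
* peak ILD = argmax of the trial-averaged ILD curve; weighted ILD =
  response-weighted centroid sum(ILD_i * r_i) / sum(r_i) with negative mean
  responses floored at 0 (configurable);
* BF = argmax over frequencies of the level-averaged FRA, kept only if the
  response at BF clears the prestimulus mean by 3 prestimulus SDs;
* tonotopic axis: the rotation (1 deg steps over 360 deg) of the
  rostro-caudal axis minimizing the correlation between position and
  log2(BF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signal_extraction import ResponseTensor
from .synthetic import NOISE_BINAURAL, TONE

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------

def paired_onetailed_p(pre: np.ndarray, post: np.ndarray, axis: int = -1) -> np.ndarray:
    """One-tailed paired t-test p-values for post > pre, vectorized.

    Zero-variance difference vectors get p = 0 if the (constant) difference
    is positive and p = 1 otherwise, so noise-free simulations behave
    sensibly instead of producing NaNs.
    """
    d = np.asarray(post, float) - np.asarray(pre, float)
    n = d.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 repetitions per condition")
    mean = d.mean(axis=axis)
    sd = d.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = stats.t.sf(t, df=n - 1)
    degenerate = sd == 0
    if np.any(degenerate):
        p = np.where(degenerate, np.where(mean > 0, 0.0, 1.0), p)
    return p


def test_responsive(
    tensor: ResponseTensor,
    condition_columns: list[str],
    stim_class_prefix: str | None = None,
    alpha: float = 0.01,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-condition responsiveness p-values and the any-condition flag.

    Groups trials by ``condition_columns`` (restricted to stimulus classes
    starting with ``stim_class_prefix`` if given), runs the one-tailed
    paired t-test per condition for every neuron, and flags a neuron
    responsive if any condition's p < alpha.

    Returns (flags (n_neurons,), p-values DataFrame with one column per
    condition keyed by the condition tuple).
    """
    trials = tensor.trials
    sel = np.ones(len(trials), dtype=bool)
    if stim_class_prefix is not None:
        sel &= trials["stim_class"].str.startswith(stim_class_prefix).to_numpy()
    sub = trials.loc[sel]
    pvals = {}
    for key, idx in sub.groupby(condition_columns, dropna=False).groups.items():
        cols = trials.index.get_indexer(idx)
        pre = tensor.pre_peaks[:, cols]
        post = tensor.post_peaks[:, cols]
        pvals[key] = paired_onetailed_p(pre, post, axis=1)
    pdf = pd.DataFrame(pvals)
    flags = (pdf.to_numpy() < alpha).any(axis=1)
    flags &= ~np.isnan(pdf.to_numpy()).all(axis=1)
    return flags, pdf


# ---------------------------------------------------------------------------
# ILD sensitivity and curve summaries
# ---------------------------------------------------------------------------

def test_ild_sensitivity(groups: list[np.ndarray], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """One-way fixed-effects ANOVA across ILD groups, vectorized over neurons.

    ``groups`` is a list (one entry per ILD) of (n_neurons, n_reps) arrays.
    Returns (flags, p). Degenerate all-constant data yields p = NaN and a
    False flag.
    """
    if any(g.shape[-1] < 2 for g in groups):
        raise ValueError("need at least 2 repetitions per ILD")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*groups, axis=-1)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if np.any(bad):
        logger.info("one-way ANOVA undefined for %d neurons (constant data)", bad.sum())
    flags = np.where(bad, False, p < alpha)
    return flags, p


@dataclass
class ILDCurveSummary:
    """Nonparametric summary of one trial-averaged ILD response curve."""

    peak_ild_db: float
    slopes: np.ndarray              # n_ILDs - 1 values, response per step
    steepest_midpoint_db: float
    weighted_ild_db: float          # NaN when undefined
    weighted_defined: bool


def ild_curve_summary(
    mean_responses: np.ndarray,
    ilds: np.ndarray,
    floor_negative: bool = True,
) -> ILDCurveSummary:
    """Peak ILD, contiguous-pair slopes, steepest-slope midpoint, centroid.

    The centroid is sum(ILD_i * r_i) / sum(r_i) over the (optionally
    zero-floored) mean responses; ties at the peak and steepest slope break
    toward the most contralateral (most negative) ILD.
    """
    r = np.asarray(mean_responses, dtype=float)
    ilds = np.asarray(ilds, dtype=float)
    if r.shape != ilds.shape:
        raise ValueError("need one mean response per ILD")
    peak = float(ilds[int(np.argmax(r))])
    slopes = np.diff(r)
    mids = (ilds[:-1] + ilds[1:]) / 2
    steepest = float(mids[int(np.argmax(np.abs(slopes)))])
    rw = np.maximum(r, 0.0) if floor_negative else r
    denom = rw.sum()
    if denom <= 0:
        logger.info("centroid undefined: nonpositive response mass")
        return ILDCurveSummary(peak, slopes, steepest, np.nan, False)
    weighted = float(np.dot(ilds, rw) / denom)
    return ILDCurveSummary(peak, slopes, steepest, weighted, True)


def group_average_curves(
    curves: np.ndarray, peak_ilds: np.ndarray, ilds: np.ndarray
) -> dict[float, np.ndarray]:
    """Average max-normalized ILD curves within groups sharing a peak ILD.

    Each neuron's 7-point curve is divided by its own maximum before
    averaging; neurons with a nonpositive maximum are skipped. Empty groups
    are omitted from the result.
    """
    curves = np.asarray(curves, dtype=float)
    out: dict[float, np.ndarray] = {}
    for ild in np.asarray(ilds, dtype=float):
        mask = np.asarray(peak_ilds) == ild
        sub = curves[mask]
        if sub.size == 0:
            continue
        mx = sub.max(axis=1)
        ok = mx > 0
        if not ok.any():
            continue
        out[float(ild)] = (sub[ok] / mx[ok, None]).mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# frequency response areas
# ---------------------------------------------------------------------------

def smooth_fra(fra: np.ndarray) -> np.ndarray:
    """3-point running average along the frequency axis (axis 0), with the
    truncated kernel renormalized at the edges."""
    fra = np.asarray(fra, dtype=float)
    squeeze = fra.ndim == 1
    x = fra[:, None] if squeeze else fra
    n = x.shape[0]
    padded = np.vstack([np.zeros((1, x.shape[1])), x, np.zeros((1, x.shape[1]))])
    num = padded[:-2] + padded[1:-1] + padded[2:]
    den = np.full((n, 1), 3.0)
    den[0, 0] = den[-1, 0] = 2.0 if n > 1 else 1.0
    out = num / den
    return out[:, 0] if squeeze else out


def build_fra(
    responses: np.ndarray,
    freq_labels: np.ndarray,
    level_labels: np.ndarray,
    freqs: np.ndarray,
    levels: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-mean response per (frequency, level) cell, plus a smoothed copy.

    The smoothed matrix is for display only; BF and the ANOVA use the
    unsmoothed cells. Raises if any cell of the grid has no trials.
    """
    responses = np.asarray(responses, dtype=float)
    fra = np.full((len(freqs), len(levels)), np.nan)
    for i, f in enumerate(freqs):
        for j, lv in enumerate(levels):
            m = (freq_labels == f) & (level_labels == lv)
            if not m.any():
                raise ValueError(f"no trials for frequency {f}, level {lv}")
            fra[i, j] = responses[m].mean()
    return fra, smooth_fra(fra)


def twoway_anova_balanced(cells: np.ndarray) -> dict[str, np.ndarray]:
    """Closed-form balanced two-way fixed-effects ANOVA with interaction.

    ``cells`` has shape (..., a, b, r): a frequency levels, b sound levels,
    r replicates. Returns main-effect and interaction F and p arrays over
    the leading axes. With a balanced design type-I/II/III sums of squares
    coincide; this vectorized form is cross-checked against statsmodels'
    anova_lm in the test suite.
    """
    cells = np.asarray(cells, dtype=float)
    a, b, r = cells.shape[-3:]
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")
    grand = cells.mean(axis=(-1, -2, -3), keepdims=True)
    mean_ab = cells.mean(axis=-1, keepdims=True)
    mean_a = cells.mean(axis=(-1, -2), keepdims=True)
    mean_b = cells.mean(axis=(-1, -3), keepdims=True)
    ss_a = (r * b * (mean_a - grand) ** 2).sum(axis=(-1, -2, -3))
    ss_b = (r * a * (mean_b - grand) ** 2).sum(axis=(-1, -2, -3))
    ss_ab = (r * (mean_ab - mean_a - mean_b + grand) ** 2).sum(axis=(-1, -2, -3))
    ss_e = ((cells - mean_ab) ** 2).sum(axis=(-1, -2, -3))
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = (ss_a / df_a) / (ss_e / df_e)
        f_b = (ss_b / df_b) / (ss_e / df_e)
        f_ab = (ss_ab / df_ab) / (ss_e / df_e)
    return {
        "F_freq": f_a, "p_freq": stats.f.sf(f_a, df_a, df_e),
        "F_level": f_b, "p_level": stats.f.sf(f_b, df_b, df_e),
        "F_interaction": f_ab, "p_interaction": stats.f.sf(f_ab, df_ab, df_e),
    }


def test_frequency_sensitivity(
    responses: np.ndarray,
    freq_labels: np.ndarray,
    level_labels: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Two-way ANOVA of tone responses on frequency and level.

    Balanced grids use the closed-form path; unbalanced grids fall back to
    a statsmodels OLS with type-II sums of squares. Returns flags and
    p-values for both main effects.
    """
    freqs = np.unique(freq_labels)
    levels = np.unique(level_labels)
    counts = np.array([
        [np.sum((freq_labels == f) & (level_labels == lv)) for lv in levels]
        for f in freqs
    ])
    if counts.min() == 0:
        raise ValueError("missing cells in the frequency x level grid")
    if np.all(counts == counts[0, 0]):
        r = int(counts[0, 0])
        cells = np.empty((len(freqs), len(levels), r))
        for i, f in enumerate(freqs):
            for j, lv in enumerate(levels):
                cells[i, j] = responses[(freq_labels == f) & (level_labels == lv)]
        res = twoway_anova_balanced(cells)
        p_freq, p_level = float(res["p_freq"]), float(res["p_level"])
    else:  # unbalanced: type-II via statsmodels
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = pd.DataFrame({
            "resp": responses,
            "freq": pd.Categorical(freq_labels),
            "level": pd.Categorical(level_labels),
        })
        fit = smf.ols("resp ~ C(freq) + C(level) + C(freq):C(level)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        p_freq = float(tab.loc["C(freq)", "PR(>F)"])
        p_level = float(tab.loc["C(level)", "PR(>F)"])
    return {
        "freq_sensitive": bool(np.isfinite(p_freq) and p_freq < alpha),
        "level_sensitive": bool(np.isfinite(p_level) and p_level < alpha),
        "p_freq": p_freq,
        "p_level": p_level,
    }


def best_frequency(
    fra: np.ndarray,
    freqs: np.ndarray,
    pre_peaks: np.ndarray,
) -> tuple[float, bool]:
    """BF = argmax of the level-averaged FRA; 3-SD validity rule.

    The BF is kept ("clear") only if the mean response at BF is at least 3
    prestimulus standard deviations above the prestimulus mean, both
    computed from the pre-window peak values across the neuron's tone
    trials. Ties break toward the lowest frequency (logged).
    """
    level_avg = np.asarray(fra, dtype=float).mean(axis=1)
    imax = int(np.argmax(level_avg))
    if np.sum(level_avg == level_avg[imax]) > 1:
        logger.info("BF tie; keeping lowest frequency")
    bf = float(np.asarray(freqs)[imax])
    pre = np.asarray(pre_peaks, dtype=float)
    thresh = pre.mean() + 3.0 * pre.std(ddof=1)
    valid = bool(level_avg[imax] >= thresh)
    return bf, valid


# ---------------------------------------------------------------------------
# field-level tonotopy
# ---------------------------------------------------------------------------

@dataclass
class GradientFit:
    """Orientation of the tonotopic axis found by axis rotation."""

    angle_deg: float
    correlation_at_angle: float
    profile: np.ndarray  # Pearson r at each of 360 one-degree rotations
    defined: bool = True


def tonotopic_gradient(positions: np.ndarray, bfs_hz: np.ndarray) -> GradientFit:
    """Rotate the rostro-caudal axis in 1-degree steps through 360 degrees
    and correlate the projected position with log2(BF); the rotation with
    the strongest negative correlation is the tonotopic axis.
    """
    positions = np.asarray(positions, dtype=float)[:, :2]
    bfs_hz = np.asarray(bfs_hz, dtype=float)
    if len(bfs_hz) < 3:
        raise ValueError("need at least 3 neurons with a valid BF")
    b = np.log2(bfs_hz)
    b = b - b.mean()
    if np.allclose(b, 0):
        logger.warning("all BFs equal; gradient undefined")
        return GradientFit(np.nan, np.nan, np.full(360, np.nan), defined=False)
    xy = positions - positions.mean(axis=0)
    theta = np.deg2rad(np.arange(360))
    proj = xy @ np.vstack([np.cos(theta), np.sin(theta)])   # (n, 360)
    proj = proj - proj.mean(axis=0)
    denom = np.sqrt((proj ** 2).sum(axis=0) * (b ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (proj.T @ b) / denom
    idx = int(np.nanargmin(r))
    return GradientFit(float(idx), float(r[idx]), r)


def bf_variation(bfs_hz: np.ndarray) -> float:
    """Coefficient of BF variation: SD of log2(BF) across the field, in octaves."""
    bfs_hz = np.asarray(bfs_hz, dtype=float)
    bfs_hz = bfs_hz[np.isfinite(bfs_hz)]
    if len(bfs_hz) < 2:
        raise ValueError("need at least 2 valid BFs")
    return float(np.std(np.log2(bfs_hz), ddof=1))


# ---------------------------------------------------------------------------
# per-neuron profile assembly
# ---------------------------------------------------------------------------

def compute_neuron_profiles(tensor: ResponseTensor, config) -> pd.DataFrame:
    """Run the full per-neuron characterization over a response tensor.

    Produces one row per neuron with, per ABL: noise responsiveness, ILD
    ANOVA p and flag, peak/weighted ILD and steepest-slope midpoint; plus
    tone responsiveness, the two-way ANOVA outcome, and the (validated) BF.
    """
    trials = tensor.trials
    abls = sorted(trials.loc[trials["stim_class"] == NOISE_BINAURAL, "abl_db"].dropna().unique())
    ilds = np.sort(trials.loc[trials["stim_class"] == NOISE_BINAURAL, "ild_db"].dropna().unique())
    n = tensor.n_neurons
    prof = pd.DataFrame(index=pd.RangeIndex(n, name="neuron"))

    # noise responsiveness per ABL: t-test per ILD, any-significant rule
    any_resp = np.zeros(n, dtype=bool)
    for abl in abls:
        sub_mask = (trials["stim_class"] == NOISE_BINAURAL) & (trials["abl_db"] == abl)
        sub = trials.loc[sub_mask]
        ps = []
        for ild in ilds:
            cols = sub.index[sub["ild_db"] == ild].to_numpy()
            ps.append(paired_onetailed_p(tensor.pre_peaks[:, cols], tensor.post_peaks[:, cols], axis=1))
        pmat = np.column_stack(ps)
        flag = (pmat < config.alpha_responsive).any(axis=1)
        prof[f"noise_responsive_abl{int(abl)}"] = flag
        any_resp |= flag

        groups = [tensor.responses[:, sub.index[sub["ild_db"] == ild].to_numpy()] for ild in ilds]
        sflag, p = test_ild_sensitivity(groups, alpha=config.alpha_anova)
        # only responsive neurons are characterized for ILD sensitivity
        sflag = sflag & flag
        prof[f"ild_p_abl{int(abl)}"] = p
        prof[f"ild_sensitive_abl{int(abl)}"] = sflag

        means = np.column_stack([g.mean(axis=1) for g in groups])
        peaks = np.full(n, np.nan)
        weighted = np.full(n, np.nan)
        steep = np.full(n, np.nan)
        for i in range(n):
            if not sflag[i]:
                continue
            s = ild_curve_summary(means[i], ilds, config.floor_negative_responses)
            peaks[i] = s.peak_ild_db
            weighted[i] = s.weighted_ild_db
            steep[i] = s.steepest_midpoint_db
        prof[f"peak_ild_abl{int(abl)}"] = peaks
        prof[f"weighted_ild_abl{int(abl)}"] = weighted
        prof[f"steepest_mid_abl{int(abl)}"] = steep
    prof["noise_responsive_any"] = any_resp

    # tones
    tone_mask = trials["stim_class"] == TONE
    if tone_mask.any():
        tsub = trials.loc[tone_mask]
        freqs = np.sort(tsub["freq_hz"].unique())
        levels = np.sort(tsub["level_db"].unique())
        ps = []
        for f in freqs:
            cols = tsub.index[tsub["freq_hz"] == f].to_numpy()
            ps.append(paired_onetailed_p(tensor.pre_peaks[:, cols], tensor.post_peaks[:, cols], axis=1))
        pmat = np.column_stack(ps)
        tone_resp = (pmat < config.alpha_responsive).any(axis=1)
        prof["tone_responsive"] = tone_resp

        tcols = tsub.index.to_numpy()
        flabels = tsub["freq_hz"].to_numpy()
        llabels = tsub["level_db"].to_numpy()
        bf = np.full(n, np.nan)
        bf_valid = np.zeros(n, dtype=bool)
        p_freq = np.full(n, np.nan)
        freq_sens = np.zeros(n, dtype=bool)
        for i in range(n):
            if not tone_resp[i] or not np.all(np.isfinite(tensor.responses[i, tcols])):
                continue
            res = test_frequency_sensitivity(
                tensor.responses[i, tcols], flabels, llabels, alpha=config.alpha_anova)
            p_freq[i] = res["p_freq"]
            freq_sens[i] = res["freq_sensitive"]
            if res["freq_sensitive"]:
                fra, _ = build_fra(tensor.responses[i, tcols], flabels, llabels, freqs, levels)
                bf[i], bf_valid[i] = best_frequency(fra, freqs, tensor.pre_peaks[i, tcols])
        prof["p_freq"] = p_freq
        prof["freq_sensitive"] = freq_sens
        prof["bf_hz"] = bf
        prof["bf_valid"] = bf_valid
    else:
        prof["tone_responsive"] = False
        prof["freq_sensitive"] = False
        prof["bf_hz"] = np.nan
        prof["bf_valid"] = False
    return prof
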