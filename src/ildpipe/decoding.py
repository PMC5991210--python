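"""Population-level ILD analyses.

Two analyses operate on the noise-responsive population:

* PCA of the neurons x 21-stimulus (7 ILDs x 3 ABLs) matrix of
  max-normalized trial-averaged responses, to extract the dominant ILD/ABL
  response motifs;
* an opponent-channel decoder: each "monotonic" neuron (significant OLS
  slope of single-trial response on signed ILD, responses pooled across
  ABLs) joins the contralateral- (negative slope) or ipsilateral-preferring
  (positive slope) channel; the population opponent value on a trial is the
  mean normalized response of the contra channel minus that of the ipsi
  channel, and the decoded ILD is the one whose leave-one-out reference
  opponent value lies nearest. Accuracy is the mean unsigned error (MUE, in
  dB), also reported normalized by the maximal possible error (60 dB for
  the -30..+30 task), averaged over many random subpopulations per
  population size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .signal_extraction import ResponseTensor
from .synthetic import NOISE_BINAURAL

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# population response matrix and PCA
# ---------------------------------------------------------------------------

@dataclass
class PopulationMatrix:
    """Max-normalized trial-averaged responses, neurons x (ILD x ABL)."""

    matrix: np.ndarray            # (n_kept, n_ilds * n_abls), row max = 1
    neuron_ids: np.ndarray
    ilds: np.ndarray
    abls: np.ndarray
    excluded: list = field(default_factory=list)


def build_population_matrix(
    tensor: ResponseTensor, neuron_mask: np.ndarray | None = None
) -> PopulationMatrix:
    """Trial-averaged binaural-noise responses, normalized per neuron.

    Columns are ordered ABL-major then ILD (7 ILDs within each ABL). Each
    row is divided by its maximum; rows with a nonpositive maximum cannot
    be normalized and are excluded (logged).
    """
    trials = tensor.trials
    noise = trials["stim_class"] == NOISE_BINAURAL
    ilds = np.sort(trials.loc[noise, "ild_db"].dropna().unique())
    abls = np.sort(trials.loc[noise, "abl_db"].dropna().unique())
    cols = []
    for abl in abls:
        for ild in ilds:
            idx = trials.index[noise & (trials["abl_db"] == abl) & (trials["ild_db"] == ild)].to_numpy()
            cols.append(tensor.responses[:, idx].mean(axis=1))
    mat = np.column_stack(cols)
    if neuron_mask is None:
        neuron_mask = np.ones(mat.shape[0], dtype=bool)
    ids = np.flatnonzero(neuron_mask)
    mat = mat[neuron_mask]
    mx = mat.max(axis=1)
    keep = mx > 0
    excluded = ids[~keep].tolist()
    if excluded:
        logger.info("excluding %d neurons with nonpositive max response", len(excluded))
    return PopulationMatrix(mat[keep] / mx[keep, None], ids[keep], ilds, abls, excluded)


@dataclass
class PCAResult:
    components: np.ndarray                 # (n_components, n_stimuli)
    coefficients: np.ndarray               # (n_components, n_ilds, n_abls)
    variance_explained: np.ndarray         # fractions, sum to 1
    degenerate: bool = False


def run_pca(pop: PopulationMatrix) -> PCAResult:
    """PCA of the population matrix; components ordered by variance explained.

    Eigenvector coefficients are reshaped to (ILD, ABL) for reporting. A
    constant matrix carries no variance and is returned flagged.
    """
    if pop.matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 neurons")
    if np.allclose(pop.matrix.var(axis=0), 0):
        logger.warning("population matrix has zero variance; PCA degenerate")
        return PCAResult(
            components=np.zeros((1, pop.matrix.shape[1])),
            coefficients=np.zeros((1, len(pop.ilds), len(pop.abls))),
            variance_explained=np.array([0.0]),
            degenerate=True,
        )
    pca = PCA()
    pca.fit(pop.matrix)
    comps = pca.components_
    n_ilds, n_abls = len(pop.ilds), len(pop.abls)
    coeff = np.stack([c.reshape(n_abls, n_ilds).T for c in comps])
    return PCAResult(comps, coeff, pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# opponent-channel decoder
# ---------------------------------------------------------------------------

@dataclass
class ChannelAssignment:
    """Per-neuron ILD-monotonicity regression and channel sign."""

    slope: np.ndarray
    p: np.ndarray
    sign: np.ndarray            # 'contra' (slope < 0) or 'ipsi' (slope > 0)
    monotonic: np.ndarray       # regression p < alpha


def assign_channel(
    tensor: ResponseTensor,
    neuron_mask: np.ndarray | None = None,
    alpha: float = 0.05,
) -> ChannelAssignment:
    """OLS of single-trial responses on signed ILD, pooled across ABLs.

    Negative slope = contralateral-preferring, positive = ipsilateral.
    Neurons with zero response variance are excluded (non-monotonic).
    """
    trials = tensor.trials
    noise = (trials["stim_class"] == NOISE_BINAURAL).to_numpy()
    idx = np.flatnonzero(noise)
    x = trials["ild_db"].to_numpy(dtype=float)[idx]
    n = tensor.n_neurons
    slope = np.full(n, np.nan)
    p = np.full(n, np.nan)
    sign = np.array(["none"] * n, dtype=object)
    mono = np.zeros(n, dtype=bool)
    mask = np.ones(n, dtype=bool) if neuron_mask is None else np.asarray(neuron_mask, bool)
    for i in range(n):
        if not mask[i]:
            continue
        y = tensor.responses[i, idx]
        if not np.all(np.isfinite(y)) or np.std(y) == 0:
            continue
        fit = stats.linregress(x, y)
        slope[i] = fit.slope
        p[i] = fit.pvalue
        sign[i] = "contra" if fit.slope < 0 else "ipsi"
        mono[i] = fit.pvalue < alpha and fit.slope != 0
    return ChannelAssignment(slope, p, sign, mono)


@dataclass
class DecoderResult:
    predicted_ild: np.ndarray
    true_ild: np.ndarray
    mue_db: float
    mue_normalized: float
    confusion_pct: np.ndarray    # rows = true ILD, each row sums to 100


def opponent_decode(
    responses: np.ndarray,
    ild_per_trial: np.ndarray,
    signs: np.ndarray,
    ilds: np.ndarray | None = None,
    max_error_db: float = 60.0,
    _leak_own_trial: bool = False,
) -> DecoderResult:
    """Leave-one-out opponent-channel classification of single-trial ILD.

    ``responses`` is (n_neurons, n_trials) over binaural-noise trials
    (pooled across ABLs), ``signs`` gives each neuron's channel. Each
    neuron is normalized by the maximum of its trial-averaged per-ILD
    response curve; neurons whose maximum is nonpositive are dropped. The
    decoded ILD of a trial is the ILD whose reference opponent value —
    computed from all *other* trials — is nearest to the trial's opponent
    value, ties broken toward the smaller |ILD|.
    """
    responses = np.asarray(responses, dtype=float)
    ild_per_trial = np.asarray(ild_per_trial, dtype=float)
    signs = np.asarray(signs)
    if ilds is None:
        ilds = np.unique(ild_per_trial)
    ilds = np.sort(np.asarray(ilds, dtype=float))
    n_trials = responses.shape[1]

    # per-neuron normalization by the max of the trial-averaged ILD curve
    curve = np.column_stack([
        responses[:, ild_per_trial == ild].mean(axis=1) for ild in ilds])
    mx = curve.max(axis=1)
    keep = mx > 0
    if not keep.all():
        logger.info("dropping %d neurons with nonpositive tuning max", (~keep).sum())
    responses = responses[keep] / mx[keep, None]
    signs = signs[keep]
    contra = signs == "contra"
    ipsi = signs == "ipsi"
    if not contra.any() or not ipsi.any():
        raise ValueError("need at least one neuron per opponent channel")

    opp = responses[contra].mean(axis=0) - responses[ipsi].mean(axis=0)

    # leave-one-out reference opponent value per ILD
    onehot = ild_per_trial[:, None] == ilds[None, :]          # (trials, ilds)
    sums = opp @ onehot
    counts = onehot.sum(axis=0).astype(float)
    if _leak_own_trial:  # broken reference, kept only to verify the LOO discipline
        loo_sums = np.broadcast_to(sums[None, :], (n_trials, len(ilds)))
        loo_counts = np.broadcast_to(counts[None, :], (n_trials, len(ilds)))
    else:
        loo_sums = sums[None, :] - np.where(onehot, opp[:, None], 0.0)
        loo_counts = counts[None, :] - onehot
    with np.errstate(divide="ignore", invalid="ignore"):
        refs = loo_sums / loo_counts                          # (trials, ilds)
    diffs = np.abs(opp[:, None] - refs)
    min_d = diffs.min(axis=1, keepdims=True)
    tie_key = np.where(diffs == min_d, np.abs(ilds)[None, :], np.inf)
    pred = ilds[np.argmin(tie_key, axis=1)]

    errors = np.abs(ild_per_trial - pred)
    mue = float(errors.mean())
    conf = np.zeros((len(ilds), len(ilds)))
    for r, ild in enumerate(ilds):
        m = ild_per_trial == ild
        for c, p_ild in enumerate(ilds):
            conf[r, c] = 100.0 * np.mean(pred[m] == p_ild)
    return DecoderResult(pred, ild_per_trial, mue, mue / max_error_db, conf)


def decode_curve(
    responses: np.ndarray,
    ild_per_trial: np.ndarray,
    signs: np.ndarray,
    monotonic: np.ndarray,
    population_sizes,
    n_resamples: int = 1000,
    seed: int = 0,
    max_error_db: float = 60.0,
) -> pd.DataFrame:
    """MUE versus population size, averaged over random subpopulations.

    Per resample, ``size`` monotonic neurons are drawn without replacement
    (across fields/mice; nonsimultaneity is acceptable for this decoder);
    draws leaving a channel empty are rejected and redrawn (logged).
    """
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(np.asarray(monotonic, bool))
    if len(pool) < 2:
        raise ValueError("need at least 2 monotonic neurons")
    rows = []
    for size in population_sizes:
        size_eff = min(int(size), len(pool))
        mues, mues_norm = [], []
        for _ in range(n_resamples):
            for _attempt in range(100):
                sample = rng.choice(pool, size=size_eff, replace=False)
                s = np.asarray(signs)[sample]
                if (s == "contra").any() and (s == "ipsi").any():
                    break
                logger.debug("resampling: a channel came up empty")
            res = opponent_decode(
                responses[sample], ild_per_trial, s, max_error_db=max_error_db)
            mues.append(res.mue_db)
            mues_norm.append(res.mue_normalized)
        rows.append({
            "population_size": size_eff,
            "mue_db_mean": float(np.mean(mues)),
            "mue_db_sd": float(np.std(mues, ddof=1)) if len(mues) > 1 else 0.0,
            "mue_norm_mean": float(np.mean(mues_norm)),
            "n_resamples": n_resamples,
        })
    return pd.DataFrame(rows)


def noise_trial_responses(tensor: ResponseTensor) -> tuple[np.ndarray, np.ndarray]:
    """(responses to binaural-noise trials pooled across ABLs, their ILDs)."""
    noise = (tensor.trials["stim_class"] == NOISE_BINAURAL).to_numpy()
    idx = np.flatnonzero(noise)
    return tensor.responses[:, idx], tensor.trials["ild_db"].to_numpy(dtype=float)[idx]


def chance_mue_db(ilds=np.array([-30, -20, -10, 0, 10, 20, 30], dtype=float)) -> float:
    """Expected MUE of a uniform random guesser over the tested ILD set."""
    d = np.abs(ilds[:, None] - ilds[None, :])
    return float(d.mean())
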