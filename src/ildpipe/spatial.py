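"""Pairwise correlations and spatial-organization statistics.

Noise correlation between two simultaneously imaged neurons is the Pearson
correlation of their trial responses after subtracting each neuron's mean
response to the presented stimulus (removing tuning); signal correlation
is the correlation of the two condition-mean tuning vectors minus the
noise correlation, so that signal + noise recovers the raw trial-averaged
correlation by construction. Shuffle bootstraps provide the
independent-response null for both quantities.

Spatial clustering of a tuning parameter (weighted ILD, BF in octaves, or
binaural-category codes) is tested per experiment with a bootstrap: the
mean absolute preference difference over "local" pairs (<= 150 um apart in
the 2D cortical plane) is compared with the fifth percentile of 1000 means
over equally many randomly chosen "distant" (> 150 um) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

# category codes for the binaural-class clustering test (the three most
# common classes only)
BINAURAL_CLUSTER_CODES = {"EO/I": -1.0, "EO/F": 0.0, "OO/F": 1.0}


# ---------------------------------------------------------------------------
# pairwise correlations
# ---------------------------------------------------------------------------

def _condition_ids(labels) -> np.ndarray:
    """Map arbitrary condition labels (possibly tuples) to integer ids."""
    arr = pd.Series(list(map(tuple, labels)) if isinstance(labels[0], (list, np.ndarray)) else list(labels))
    return arr.astype("category").cat.codes.to_numpy()


def _residuals(responses: np.ndarray, cond: np.ndarray) -> np.ndarray:
    """Subtract each neuron's per-condition mean response from each trial."""
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    out = responses.copy()
    for c in np.unique(cond):
        m = cond == c
        out[:, m] -= responses[:, m].mean(axis=1, keepdims=True)
    return out


def _condition_means(responses: np.ndarray, cond: np.ndarray) -> np.ndarray:
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    conds = np.unique(cond)
    return np.column_stack([responses[:, cond == c].mean(axis=1) for c in conds])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def noise_correlation(responses_a, responses_b, condition_labels) -> float:
    """Correlation of stimulus-mean-subtracted trial responses.

    NaN if either neuron has zero residual variance (pair skipped upstream).
    """
    cond = _condition_ids(condition_labels)
    res = _residuals(np.vstack([responses_a, responses_b]), cond)
    return _pearson(res[0], res[1])


def signal_correlation(responses_a, responses_b, condition_labels) -> float:
    """Correlation of the two tuning (condition-mean) vectors minus the
    pair's noise correlation."""
    cond = _condition_ids(condition_labels)
    means = _condition_means(np.vstack([responses_a, responses_b]), cond)
    raw = _pearson(means[0], means[1])
    nc = noise_correlation(responses_a, responses_b, condition_labels)
    if np.isnan(raw) or np.isnan(nc):
        return np.nan
    return raw - nc


def pairwise_correlations(
    responses: np.ndarray,
    condition_labels,
    positions: np.ndarray,
    neuron_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """All within-field pairwise signal/noise correlations and distances.

    ``positions`` supplies (rostro-caudal, dorso-ventral) coordinates; the
    per-axis absolute distances are reported alongside the 2D Euclidean
    distance. Pairs with undefined correlations are dropped (logged).
    """
    responses = np.asarray(responses, dtype=float)
    n = responses.shape[0]
    if neuron_ids is None:
        neuron_ids = np.arange(n)
    cond = _condition_ids(condition_labels)
    res = _residuals(responses, cond)
    means = _condition_means(responses, cond)
    rows = []
    skipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            nc = _pearson(res[i], res[j])
            raw = _pearson(means[i], means[j])
            if np.isnan(nc) or np.isnan(raw):
                skipped += 1
                continue
            rows.append({
                "neuron_a": neuron_ids[i], "neuron_b": neuron_ids[j],
                "noise_r": nc, "signal_r": raw - nc,
                "dist_rc_um": abs(positions[i, 0] - positions[j, 0]),
                "dist_dv_um": abs(positions[i, 1] - positions[j, 1]),
                "dist_2d_um": float(np.hypot(*(positions[i, :2] - positions[j, :2]))),
            })
    if skipped:
        logger.info("skipped %d pairs with undefined correlations", skipped)
    return pd.DataFrame(rows)


def bootstrap_correlation_null(
    responses: np.ndarray,
    condition_labels,
    mode: str = "noise",
    n_iter: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> dict:
    """Shuffle null for pairwise correlations, plus the population-level test.

    Per iteration each neuron's trial responses are redrawn with
    replacement — within the same stimulus condition in "noise" mode,
    from all trials in "signal" mode — and the pairwise correlations are
    recomputed. The observed correlations are compared with the null means
    via a paired t-test across pairs (alpha 0.01).
    """
    if mode not in ("noise", "signal"):
        raise ValueError("mode must be 'noise' or 'signal'")
    responses = np.asarray(responses, dtype=float)
    n, t = responses.shape
    cond = _condition_ids(condition_labels)
    rng = np.random.default_rng(seed)

    iu = np.triu_indices(n, k=1)

    def corr_set(resp):
        if mode == "noise":
            r = _residuals(resp, cond)
            c = np.corrcoef(r)
        else:
            m = _condition_means(resp, cond)
            nc = np.corrcoef(_residuals(resp, cond))
            c = np.corrcoef(m) - nc
        return c[iu]

    observed = corr_set(responses)
    null = np.empty((n_iter, len(observed)))
    for it in range(n_iter):
        if mode == "noise":
            shuf = np.empty_like(responses)
            for c in np.unique(cond):
                m = np.flatnonzero(cond == c)
                pick = rng.integers(0, len(m), size=(n, len(m)))
                shuf[:, m] = np.take_along_axis(responses[:, m], pick, axis=1)
        else:
            pick = rng.integers(0, t, size=(n, t))
            shuf = np.take_along_axis(responses, pick, axis=1)
        null[it] = corr_set(shuf)
    null_mean = np.nanmean(null, axis=0)
    ok = np.isfinite(observed) & np.isfinite(null_mean)
    if ok.sum() < 2:
        logger.warning("fewer than 2 valid pairs; no population test")
        return {"observed": observed, "null_mean": null_mean, "p": np.nan,
                "significant": False}
    tt = stats.ttest_rel(observed[ok], null_mean[ok])
    return {
        "observed": observed,
        "null_mean": null_mean,
        "p": float(tt.pvalue),
        "significant": bool(tt.pvalue < alpha),
    }


def correlation_vs_distance(pairs: pd.DataFrame) -> pd.DataFrame:
    """OLS of pairwise correlation on cortical distance, per axis and kind.

    Returns one row per (axis in {rc, dv}) x (kind in {signal, noise}) with
    slope, intercept, Pearson r, and p. Degenerate (constant-distance)
    inputs yield no row for that axis.
    """
    rows = []
    for axis, col in (("rc", "dist_rc_um"), ("dv", "dist_dv_um")):
        d = pairs[col].to_numpy(dtype=float)
        if len(d) < 3 or np.std(d) == 0:
            logger.warning("degenerate distances on axis %s; no fit", axis)
            continue
        for kind in ("signal", "noise"):
            y = pairs[f"{kind}_r"].to_numpy(dtype=float)
            fit = stats.linregress(d, y)
            rows.append({
                "axis": axis, "kind": kind, "slope_per_um": fit.slope,
                "intercept": fit.intercept, "r": fit.rvalue, "p": fit.pvalue,
                "n_pairs": len(d),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrapped spatial clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterTestResult:
    """Outcome of the local-vs-distant preference-distance bootstrap."""

    parameter: str
    n_local_pairs: int
    n_distant_pairs: int
    observed_local_mean: float
    boot_fifth_percentile: float
    observed_percentile: float     # % of bootstrap means below the observed
    significant: bool
    conclusive: bool = True
    boot_means: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def cluster_test(
    values: np.ndarray,
    positions: np.ndarray,
    threshold_um: float = 150.0,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    parameter: str = "value",
) -> ClusterTestResult:
    """Do nearby neurons (<= threshold apart, 2D) have more similar values?

    The preference distance of a pair is |value_a - value_b|. Significant
    clustering: the mean over local pairs lies strictly below the fifth
    percentile of ``n_boot`` bootstrap means over equally many distant
    pairs (drawn without replacement within a draw when enough distant
    pairs exist, with replacement otherwise). NaN values are excluded.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)[:, :2]
    ok = np.isfinite(values)
    values, positions = values[ok], positions[ok]
    if len(values) < 3:
        return _inconclusive(parameter, 0, 0)
    d = pdist(positions)
    pref = pdist(values[:, None], metric="cityblock")
    local = d <= threshold_um
    distant = d > threshold_um
    n_local, n_distant = int(local.sum()), int(distant.sum())
    if n_local < 2 or n_distant < 2:
        logger.warning("cluster test inconclusive: %d local / %d distant pairs",
                       n_local, n_distant)
        return _inconclusive(parameter, n_local, n_distant)
    observed = float(pref[local].mean())
    distant_pref = pref[distant]
    rng = np.random.default_rng(seed)
    if n_distant >= n_local:
        keys = rng.random((n_boot, n_distant))
        sel = np.argpartition(keys, n_local - 1, axis=1)[:, :n_local]
    else:
        sel = rng.integers(0, n_distant, size=(n_boot, n_local))
    boot_means = distant_pref[sel].mean(axis=1)
    fifth = float(np.percentile(boot_means, 100 * alpha))
    significant = observed < fifth    # strict: ties are not significant
    return ClusterTestResult(
        parameter=parameter,
        n_local_pairs=n_local, n_distant_pairs=n_distant,
        observed_local_mean=observed,
        boot_fifth_percentile=fifth,
        observed_percentile=float(100 * np.mean(boot_means < observed)),
        significant=bool(significant),
        boot_means=boot_means,
    )


def _inconclusive(parameter: str, n_local: int, n_distant: int) -> ClusterTestResult:
    return ClusterTestResult(
        parameter=parameter, n_local_pairs=n_local, n_distant_pairs=n_distant,
        observed_local_mean=np.nan, boot_fifth_percentile=np.nan,
        observed_percentile=np.nan, significant=False, conclusive=False,
    )


def cluster_tests_for_experiment(
    profiles: pd.DataFrame,
    categories: pd.DataFrame,
    positions: np.ndarray,
    config,
    abl_db: float = 60.0,
    seed: int = 0,
) -> dict[str, ClusterTestResult]:
    """The three standard clustering tests for one experiment.

    * weighted ILD preference (at ``abl_db``), restricted to neurons with a
      valid BF >= 10 kHz;
    * BF, in octaves (log2), over all valid-BF neurons;
    * binaural category (EO/I, EO/F, OO/F coded -1/0/+1 at ``abl_db``),
      same BF restriction.
    """
    out = {}
    bf = profiles["bf_hz"].to_numpy(dtype=float)
    bf_ok = profiles["bf_valid"].to_numpy(dtype=bool) & np.isfinite(bf)
    hi_bf = bf_ok & (bf >= config.min_bf_hz_for_cluster)

    col = f"weighted_ild_abl{int(abl_db)}"
    wild = profiles[col].to_numpy(dtype=float) if col in profiles else np.full(len(profiles), np.nan)
    vals = np.where(hi_bf, wild, np.nan)
    out["weighted_ild"] = cluster_test(
        vals, positions, config.cluster_threshold_um, config.n_boot,
        seed=seed, parameter="weighted_ild")

    vals = np.where(bf_ok, np.log2(np.where(bf_ok, bf, 1.0)), np.nan)
    out["bf"] = cluster_test(
        vals, positions, config.cluster_threshold_um, config.n_boot,
        seed=seed + 1, parameter="bf")

    codes = np.full(len(profiles), np.nan)
    if len(categories):
        sub = categories[categories["abl_db"] == abl_db]
        for _, row in sub.iterrows():
            code = BINAURAL_CLUSTER_CODES.get(row["category"])
            if code is not None:
                codes[int(row["neuron"])] = code
    vals = np.where(hi_bf, codes, np.nan)
    out["binaural_category"] = cluster_test(
        vals, positions, config.cluster_threshold_um, config.n_boot,
        seed=seed + 2, parameter="binaural_category")
    return out
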