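"""Binaural interaction taxonomy.

Each noise-responsive neuron is classified, separately at each ABL, from
its responses to monaural noise in either ear and to the diotic (0 dB ILD)
stimulus:

* monaural class: EO (contra ear only), OE (ipsi only), EE (both),
  OO/F (neither ear alone, but responsive to the diotic stimulus);
* binaural interaction index BII = diotic / (contra + ipsi), computed on
  trial-mean responses with negatives floored at 0;
* interaction suffix: /F facilitation (BII > 1.2), /I inhibition
  (BII < 0.8), /N none (0.8 <= BII <= 1.2); EE neurons with BII < 0.8 whose
  diotic response still exceeds 80% of the dominant ear show "occlusion"
  (EE/O), and the remaining EE cells with BII < 0.8 are reported as EE/I so
  category totals stay auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_extraction import ResponseTensor
from .synthetic import NOISE_BINAURAL, NOISE_MON_CONTRA, NOISE_MON_IPSI
from .tuning import paired_onetailed_p

logger = logging.getLogger(__name__)

FULL_CATEGORIES = (
    "EO/F", "EO/I", "EO/N", "OE/F", "OE/I", "OE/N",
    "EE/F", "EE/N", "EE/O", "EE/I", "OO/F",
)


@dataclass
class BinauralResult:
    """Classification of one neuron at one ABL."""

    monaural_class: str            # EO, OE, EE, OO/F, unresponsive
    bii: float                     # NaN when undefined
    full_category: str             # one of FULL_CATEGORIES or 'unresponsive'
    p_contra: float
    p_ipsi: float
    p_diotic: float


def monaural_class(p_contra: float, p_ipsi: float, p_diotic: float,
                   alpha: float = 0.01) -> str:
    """EO / OE / EE / OO-F / unresponsive from three responsiveness tests."""
    c = p_contra < alpha
    i = p_ipsi < alpha
    d = p_diotic < alpha
    if c and i:
        return "EE"
    if c:
        return "EO"
    if i:
        return "OE"
    if d:
        return "OO/F"
    return "unresponsive"


def binaural_interaction_index(r_diotic: float, r_contra: float, r_ipsi: float) -> float:
    """BII = diotic / (contra + ipsi), negatives floored at 0 first.

    Returns NaN when the denominator is nonpositive (such neurons belong in
    OO/F or unresponsive, where the ratio is meaningless).
    """
    rc = max(0.0, r_contra)
    ri = max(0.0, r_ipsi)
    rd = max(0.0, r_diotic)
    denom = rc + ri
    if denom <= 0:
        return math.nan
    return rd / denom


def full_category(cls: str, bii: float, r_diotic: float, r_contra: float,
                  r_ipsi: float, bii_low: float = 0.8, bii_high: float = 1.2) -> str:
    """Attach the interaction suffix to a monaural class.

    Boundary BII values (exactly bii_low or bii_high) fall in the
    no-interaction band. EE splits its inhibition band into EE/O (diotic
    > 80% of the dominant ear: occlusion) and EE/I otherwise.
    """
    if cls in ("OO/F", "unresponsive"):
        return cls
    if cls not in ("EO", "OE", "EE"):
        raise ValueError(f"unknown monaural class {cls!r}")
    if not np.isfinite(bii):
        logger.info("BII undefined for %s neuron; reporting /N", cls)
        return f"{cls}/N"
    if bii > bii_high:
        return f"{cls}/F"
    if bii >= bii_low:
        return f"{cls}/N"
    # BII < bii_low
    if cls != "EE":
        return f"{cls}/I"
    dominant = max(max(0.0, r_contra), max(0.0, r_ipsi))
    if max(0.0, r_diotic) > 0.8 * dominant:
        return "EE/O"
    return "EE/I"


def classify_neuron(
    pre_c, post_c, pre_i, post_i, pre_d, post_d,
    alpha: float = 0.01, bii_low: float = 0.8, bii_high: float = 1.2,
) -> BinauralResult:
    """Classify one neuron at one ABL from its windowed trial peaks.

    Inputs are the pre/post-window peak vectors for the contralateral
    monaural, ipsilateral monaural, and diotic stimulus repetitions.
    """
    p_c = float(paired_onetailed_p(pre_c, post_c))
    p_i = float(paired_onetailed_p(pre_i, post_i))
    p_d = float(paired_onetailed_p(pre_d, post_d))
    cls = monaural_class(p_c, p_i, p_d, alpha)
    r_c = float(np.mean(np.asarray(post_c) - np.asarray(pre_c)))
    r_i = float(np.mean(np.asarray(post_i) - np.asarray(pre_i)))
    r_d = float(np.mean(np.asarray(post_d) - np.asarray(pre_d)))
    bii = binaural_interaction_index(r_d, r_c, r_i) if cls not in ("OO/F", "unresponsive") else math.nan
    cat = full_category(cls, bii, r_d, r_c, r_i, bii_low, bii_high)
    return BinauralResult(cls, bii, cat, p_c, p_i, p_d)


def categorize_population(tensor: ResponseTensor, config) -> pd.DataFrame:
    """One BinauralResult per neuron per ABL, as a tidy DataFrame."""
    trials = tensor.trials
    abls = sorted(trials["abl_db"].dropna().unique())
    rows = []
    for abl in abls:
        idx_c = trials.index[(trials["stim_class"] == NOISE_MON_CONTRA) & (trials["abl_db"] == abl)].to_numpy()
        idx_i = trials.index[(trials["stim_class"] == NOISE_MON_IPSI) & (trials["abl_db"] == abl)].to_numpy()
        idx_d = trials.index[(trials["stim_class"] == NOISE_BINAURAL)
                             & (trials["abl_db"] == abl) & (trials["ild_db"] == 0)].to_numpy()
        if min(len(idx_c), len(idx_i), len(idx_d)) < 2:
            logger.warning("ABL %s lacks monaural/diotic trials; skipping", abl)
            continue
        for i in range(tensor.n_neurons):
            if not np.all(np.isfinite(tensor.responses[i])):
                continue
            res = classify_neuron(
                tensor.pre_peaks[i, idx_c], tensor.post_peaks[i, idx_c],
                tensor.pre_peaks[i, idx_i], tensor.post_peaks[i, idx_i],
                tensor.pre_peaks[i, idx_d], tensor.post_peaks[i, idx_d],
                alpha=config.alpha_responsive,
                bii_low=config.bii_low, bii_high=config.bii_high,
            )
            rows.append({
                "neuron": i, "abl_db": abl,
                "monaural_class": res.monaural_class, "bii": res.bii,
                "category": res.full_category,
                "p_contra": res.p_contra, "p_ipsi": res.p_ipsi, "p_diotic": res.p_diotic,
            })
    return pd.DataFrame(rows)


def category_summary(categories: pd.DataFrame) -> pd.DataFrame:
    """Percentage of classified (non-unresponsive) neurons per category and ABL."""
    sub = categories[categories["category"] != "unresponsive"]
    counts = sub.groupby(["abl_db", "category"]).size().rename("n").reset_index()
    totals = counts.groupby("abl_db")["n"].transform("sum")
    counts["percent"] = 100.0 * counts["n"] / totals
    return counts[["abl_db", "category", "percent"]]
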