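"""Optional figure rendering (requires matplotlib).

Four report figures: ILD response areas, FRA heatmaps, spatial tuning
maps, and the decoder error curve. All functions take an existing Axes or
create one, and return the Axes so callers can compose panels.
"""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_ild_response_area(mean_responses: np.ndarray, ilds, abls, ax=None):
    """Heatmap of trial-averaged responses, ABL rows x ILD columns."""
    ax = _ax(ax)
    im = ax.imshow(np.asarray(mean_responses), aspect="auto", origin="lower",
                   extent=[min(ilds), max(ilds), min(abls), max(abls)],
                   cmap="viridis")
    ax.set_xlabel("ILD (dB)")
    ax.set_ylabel("ABL (dB SPL)")
    ax.figure.colorbar(im, ax=ax, label=r"$\Delta$F/F$_0$ response")
    return ax


def plot_fra(fra: np.ndarray, freqs_hz, levels_db, smoothed=True, ax=None):
    """Frequency response area heatmap (frequency x level)."""
    from .tuning import smooth_fra
    ax = _ax(ax)
    m = smooth_fra(fra) if smoothed else np.asarray(fra)
    im = ax.imshow(m.T, aspect="auto", origin="lower", cmap="magma")
    ax.set_xticks(range(0, len(freqs_hz), 4))
    ax.set_xticklabels([f"{f/1000:.1f}" for f in list(freqs_hz)[::4]])
    ax.set_yticks(range(len(levels_db)))
    ax.set_yticklabels([f"{l:.0f}" for l in levels_db])
    ax.set_xlabel("frequency (kHz)")
    ax.set_ylabel("level (dB SPL)")
    ax.figure.colorbar(im, ax=ax, label="response")
    return ax


def plot_tuning_map(positions: np.ndarray, values: np.ndarray, label: str,
                    ax=None):
    """Scatter map of a per-neuron tuning value over cortical space."""
    ax = _ax(ax)
    ok = np.isfinite(values)
    sc = ax.scatter(positions[ok, 0], positions[ok, 1], c=values[ok],
                    cmap="coolwarm", s=30, edgecolor="k", linewidth=0.3)
    ax.scatter(positions[~ok, 0], positions[~ok, 1], c="lightgray", s=15)
    ax.set_xlabel("rostro-caudal (um)")
    ax.set_ylabel("dorso-ventral (um)")
    ax.set_aspect("equal")
    ax.figure.colorbar(sc, ax=ax, label=label)
    return ax


def plot_decoder_curve(curve, normalized=False, ax=None):
    """Mean unsigned error versus population size, with resampling SD."""
    ax = _ax(ax)
    x = curve["population_size"]
    y = curve["mue_norm_mean"] if normalized else curve["mue_db_mean"]
    ax.plot(x, y, "o-", color="k")
    if not normalized and "mue_db_sd" in curve:
        ax.fill_between(x, y - curve["mue_db_sd"], y + curve["mue_db_sd"],
                        alpha=0.2, color="k")
    ax.set_xlabel("population size (neurons)")
    ax.set_ylabel("normalized MUE" if normalized else "MUE (dB)")
    return ax


def render_report_figures(artifacts: dict, outdir) -> list:
    """Write the standard report figures for a pipeline run; returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    tensor = artifacts.get("tensor")
    if tensor is not None and tensor.positions is not None:
        prof = artifacts.get("profiles")
        if prof is not None:
            col = next((c for c in prof.columns if c.startswith("weighted_ild_")), None)
            if col is not None:
                fig, ax = plt.subplots(figsize=(6, 3))
                plot_tuning_map(tensor.positions[:, :2],
                                prof[col].to_numpy(dtype=float),
                                "weighted ILD (dB)", ax=ax)
                p = outdir / "map_weighted_ild.png"
                fig.savefig(p, dpi=150, bbox_inches="tight")
                plt.close(fig)
                written.append(p)

    curve = artifacts.get("decoder_curve")
    if curve is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        plot_decoder_curve(curve, ax=ax)
        p = outdir / "decoder_curve.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
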