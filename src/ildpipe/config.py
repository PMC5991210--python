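"""Run configuration: every analysis threshold in one place.

Defaults reproduce the analysis parameters this pipeline standardizes on: responsiveness alpha
0.01, ANOVA alpha 0.05, BII interaction band [0.8, 1.2], 14-frame response
windows, neuropil contamination ratio 0.6, 150 um cluster threshold, and
1000 bootstrap/resampling iterations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of the analysis pipeline.

    Attributes
    ----------
    alpha_responsive : float
        Alpha for one-tailed paired t-tests flagging stimulus-responsive
        neurons (per ILD / tone frequency / monaural condition).
    alpha_anova : float
        Alpha for the one-way ILD ANOVA and two-way frequency x level ANOVA.
    bii_low, bii_high : float
        Binaural interaction index bounds: BII < bii_low is inhibition,
        BII > bii_high is facilitation, the closed band in between is "no
        interaction".
    window_frames : int
        Length of the pre- and post-stimulus response windows in frames
        (14 frames ~ 500 ms at ~30 Hz).
    r_neuropil : float
        Neuropil contamination ratio r subtracted from each cell trace.
    highpass_cutoff_hz : float
        Cut-off of the slow-drift high-pass filter applied to raw traces.
    response_stat : str
        "peak" (default): response = max dF/F0 in post window minus max in
        pre window. "sum": window sums instead of maxima.
    floor_negative_responses : bool
        Floor negative condition-mean responses at 0 before computing the
        weighted-ILD centroid and the BII.
    cluster_threshold_um : float
        Pair distance (2D, um) separating "local" from "distant" pairs in
        the spatial clustering bootstrap.
    n_boot : int
        Bootstrap iterations (correlation shuffles, cluster test).
    decoder_resamples : int
        Neuron resamples per population size for the opponent decoder.
    max_decoder_error_db : float
        Maximal possible single-trial decoding error used to normalize the
        mean unsigned error (60 dB for the -30..+30 dB ILD task).
    seed : int
        Root seed for every stochastic stage.
    """

    alpha_responsive: float = 0.01
    alpha_anova: float = 0.05
    bii_low: float = 0.8
    bii_high: float = 1.2
    window_frames: int = 14
    r_neuropil: float = 0.6
    highpass_cutoff_hz: float = 0.02
    response_stat: str = "peak"
    floor_negative_responses: bool = True
    cluster_threshold_um: float = 150.0
    min_bf_hz_for_cluster: float = 10_000.0
    n_boot: int = 1000
    decoder_resamples: int = 1000
    decoder_population_sizes: tuple[int, ...] = (10, 25, 50, 100, 200, 300)
    max_decoder_error_db: float = 60.0
    seed: int = 0
    stages: tuple[str, ...] = ("extract", "tune", "categorize", "decode", "spatial")

    def __post_init__(self) -> None:
        if self.response_stat not in ("peak", "sum"):
            raise ValueError(f"response_stat must be 'peak' or 'sum', got {self.response_stat!r}")
        if not 0 <= self.r_neuropil < 1:
            raise ValueError("r_neuropil must be in [0, 1)")
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")
        if not 0 < self.bii_low <= self.bii_high:
            raise ValueError("require 0 < bii_low <= bii_high")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decoder_population_sizes"] = list(self.decoder_population_sizes)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "decoder_population_sizes" in d:
            d["decoder_population_sizes"] = tuple(d["decoder_population_sizes"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash over every analysis-relevant parameter."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
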