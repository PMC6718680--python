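"""Pipeline configuration: every tunable of the detector and the feature
statistics, with the defaults used throughout the package.

The defaults implement the published five-step alpha-suppression detector
(db2 wavelet band [8, 16] Hz, swing envelope over a 1-s window, burst
amplification with B = 0.72, t_b = 1 s, eta = 1.96, R = 1.4, threshold
T = 0.25, dilation 0.9 s / erosion 1.1 s, two-of-four electrode consensus)
and the moving-window statistics built on top of it.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # --- working rate -------------------------------------------------
    #: detector sampling rate; the db2 level-2 detail spans [8, 16] Hz here
    fs_work: float = 64.0

    # --- swing envelope ------------------------------------------------
    #: window (s) for averaging min-to-max swing distances into Amp(t)
    w: float = 1.0
    #: divisor of the swing average: "count" (mean over pairs) or "window"
    amp_divisor: str = "count"

    # --- burst amplification kernel -------------------------------------
    B: float = 0.72          #: kernel gain (unitless); peak is 1 + B
    t_b: float = 1.0         #: kernel peak time (s)
    eta: float = 1.96        #: kernel sharpness (unitless)
    kernel_sign: str = "decay"  #: "decay" (bounded kernel) or "growth"
    R: float = 1.4           #: burst selection ratio; kernel iff R*X < Y

    # --- thresholding ----------------------------------------------------
    T: float = 0.25          #: threshold on the normalized amplified envelope
    env_window: float = 0.25  #: moving-maximum window (s) turning |S_phi| into an envelope
    norm_window: float = 120.0  #: centered running-maximum normalization window (s)
    norm_floor: float = 1e-6  #: normalizer floor (uV), guards flat spans

    # --- morphology / consensus ------------------------------------------
    dilate_s: float = 0.9    #: per-endpoint dilation (s), repairs breaks
    erode_s: float = 1.1     #: per-endpoint erosion (s), discards short events
    morphology: str = "endpoint"  #: "endpoint" or "structuring" convention
    min_channels: int = 2    #: electrodes required for a consensus event
    min_consensus_dur: float = 0.1  #: minimum consensus event duration (s)

    # --- iso-electric suppression ------------------------------------------
    ies_amp_uV: float = 8.0  #: |(Fp1+Fp2)/2| amplitude bound (uV)
    ies_min_dur_s: float = 1.0  #: minimum flat duration (s)
    label_horizon_min: float = 35.0  #: window for the IES / noIES label (min)
    label_total_ies_s: float = 10.0  #: total IES (s) separating the groups

    # --- moving-window statistics -----------------------------------------
    prop_window: float = 240.0  #: sliding proportion window (s)
    prop_step: float = 1.0      #: evaluation step (s)
    first_occ_threshold: float = 5.0  #: % of window for first-occurrence times
    fit_span_min: float = 10.0  #: induction fit span (min)
    wf_s: float = 50.0          #: occurrence-frequency window (s)
    f_step_s: float = 10.0      #: occurrence-frequency step (s)
    freq_event_anchor: str = "start"  #: count events by "start" or "midpoint"

    def __post_init__(self) -> None:
        if self.amp_divisor not in ("count", "window"):
            raise ValueError("amp_divisor must be 'count' or 'window'")
        if self.kernel_sign not in ("decay", "growth"):
            raise ValueError("kernel_sign must be 'decay' or 'growth'")
        if self.morphology not in ("endpoint", "structuring"):
            raise ValueError("morphology must be 'endpoint' or 'structuring'")
        if not 0 < self.T < 1:
            raise ValueError("T must lie in (0, 1)")

    # ------------------------------------------------------------------ #
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
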