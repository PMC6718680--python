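"""End-to-end orchestration: recording -> segmentation -> patient features.

This is the layer the command-line interface and the cohort-level
analyses build on. The per-patient classification features are the
induction-phase summaries of the alpha-suppression statistics:

* ``a`` — through-origin slope of the alpha-suppression proportion
  ``P_alpha`` over the first 10 min (%/min);
* ``slope_F`` — linear slope of the occurrence frequency ``F_alpha``
  (events/min per min);
* ``slope_Aa`` / ``slope_AIaS`` — linear slopes of the per-event average
  alpha-band amplitude inside / outside alpha-suppressions (nV/min).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .alpha_detect import band_filter_wavelet
from .config import PipelineConfig
from .features import (
    duration_series,
    event_amplitude_series,
    first_occurrence_time,
    initial_slope,
    linear_slope_fit,
    occurrence_frequency,
    sliding_proportions,
)
from .ies_detect import label_patient, segment_recording
from .io_eeg import EEGRecording, resample
from .segmentation import Segmentation

__all__ = [
    "alpha_band_magnitude",
    "patient_features",
    "cohort_features",
    "group_summary",
]


def alpha_band_magnitude(rec: EEGRecording, cfg: PipelineConfig | None = None):
    """Per-channel rectified alpha-band signals.

    Returns ``(dict channel -> |S_alpha|, fs_work)``. Cross-channel
    averaging of the rectified signals reduces the channel-independent
    noise contribution to the per-event amplitude statistics.
    """
    cfg = cfg or PipelineConfig()
    work = resample(rec, cfg.fs_work) if rec.fs != cfg.fs_work else rec
    mags = {
        ch: np.abs(band_filter_wavelet(work.channel(ch), work.fs).values)
        for ch in work.channel_labels
    }
    return mags, work.fs


def consensus_amplitude_series(
    mags: dict[str, np.ndarray],
    fs: float,
    consensus: "IntervalSet",
    n_select: int = 2,
):
    """Per-event amplitude of consensus events, electrode-aware.

    For each consensus event the per-electrode event means of
    ``|S_alpha|`` are computed and the ``n_select`` smallest are
    averaged. A consensus event is guaranteed present on at least two
    electrodes, so the two smallest means always come from electrodes
    showing the suppression; electrodes on which the event is absent
    would contribute their full alpha rhythm and swamp the suppressed
    amplitude. Ranking by value (rather than by detection overlap) keeps
    the estimator free of selection effects that vary with event
    duration.
    """
    from .features import EventSeries, event_amplitude_series

    if len(consensus) == 0:
        return EventSeries(times=np.empty(0), values=np.empty(0))
    per = np.vstack(
        [event_amplitude_series(mag, fs, consensus).values for mag in mags.values()]
    )
    k = min(n_select, per.shape[0])
    values = np.sort(per, axis=0)[:k].mean(axis=0)
    return EventSeries(times=consensus.starts.copy(), values=values)


def patient_features(
    rec: EEGRecording,
    cfg: PipelineConfig | None = None,
    seg: Segmentation | None = None,
) -> dict:
    """All per-patient scalar features plus the underlying series.

    Returns a dict with the classification features (``a``, ``slope_F``,
    ``slope_Aa``, ``slope_AIaS``), the label, first-occurrence times, and
    the intermediate series for group-level analyses.
    """
    cfg = cfg or PipelineConfig()
    if seg is None:
        seg = segment_recording(rec, cfg)
    props = sliding_proportions(seg, window=cfg.prop_window, step=cfg.prop_step)
    a = initial_slope(props.times, props.p_alpha, cfg.fit_span_min)
    freq = occurrence_frequency(
        seg, w_f=cfg.wf_s, step=cfg.f_step_s, anchor=cfg.freq_event_anchor
    )
    slope_f, _ = linear_slope_fit(freq, cfg.fit_span_min)

    mags, fs_work = alpha_band_magnitude(rec, cfg)
    mean_mag = np.mean(list(mags.values()), axis=0)
    durs = duration_series(seg)
    amp_as = consensus_amplitude_series(mags, fs_work, seg.consensus_aS)
    inter = _drop_empty(seg.consensus_aS.union(seg.ies).complement(seg.span))
    amp_inter = event_amplitude_series(mean_mag, fs_work, inter)

    def safe_slope(series) -> float:
        try:
            s, _ = linear_slope_fit(series, cfg.fit_span_min)
        except ValueError:
            s = 0.0
        return s

    slope_aa_nv = 1000.0 * safe_slope(amp_as)
    slope_aias_nv = 1000.0 * safe_slope(amp_inter)

    t_as = first_occurrence_time(props.times, props.p_alpha, cfg.first_occ_threshold)
    t_ies = first_occurrence_time(props.times, props.p_ies, cfg.first_occ_threshold)

    return {
        "a": a,
        "slope_F": slope_f,
        "slope_Aa": slope_aa_nv,
        "slope_AIaS": slope_aias_nv,
        "label": label_patient(seg, cfg.label_horizon_min, cfg.label_total_ies_s),
        "t_aS_s": t_as,
        "t_IES_s": t_ies,
        "segmentation": seg,
        "proportions": props,
        "frequency": freq,
        "durations": durs,
        "amp_aS": amp_as,
        "amp_IaS": amp_inter,
    }


def group_summary(features_list: list[dict], cfg: PipelineConfig | None = None) -> dict:
    """Cohort-level statistics of a list of :func:`patient_features` outputs.

    Computes the group-averaged occurrence-frequency saturation fit, the
    duration series (time average and induction slope), the per-event
    amplitude induction slope, the steady-state and initial behaviour of
    the alpha-suppression proportion, and the median first-occurrence
    times of the two event classes.
    """
    from .features import exp_saturation_fit, group_average_series, linear_slope_fit

    cfg = cfg or PipelineConfig()
    span_end = max(f["segmentation"].span[1] for f in features_list)

    freq_group = group_average_series(
        [f["frequency"] for f in features_list], grid_step=cfg.f_step_s, t_max=span_end
    )
    f_max, tau, r2 = exp_saturation_fit(freq_group)

    dur_group = group_average_series(
        [f["durations"] for f in features_list], grid_step=1.0, t_max=span_end
    )
    dur_slope, _ = linear_slope_fit(dur_group, cfg.fit_span_min)

    amp_group = group_average_series(
        [f["amp_aS"] for f in features_list], grid_step=1.0, t_max=span_end
    )
    amp_slope, _ = linear_slope_fit(amp_group, cfg.fit_span_min)

    # group-mean proportion trace on the common 1-s grid
    n_grid = min(f["proportions"].times.size for f in features_list)
    p_stack = np.vstack([f["proportions"].p_alpha[:n_grid] for f in features_list])
    p_times = features_list[0]["proportions"].times[:n_grid]
    late = (p_times >= 25 * 60.0) & (p_times <= 35 * 60.0)

    t_as = [f["t_aS_s"] for f in features_list if f["t_aS_s"] is not None]
    t_ies = [f["t_IES_s"] for f in features_list if f["t_IES_s"] is not None]

    return {
        "f_max": f_max,
        "tau_min": tau,
        "f_fit_r2": r2,
        "dur_time_avg_s": float(dur_group.values.mean()),
        "dur_slope_s_per_min": dur_slope,
        "amp_slope_nv_per_min": 1000.0 * amp_slope,
        "p_alpha_steady_pct": float(p_stack.mean(axis=0)[late].mean()) if late.any() else float("nan"),
        "a_mean_pct_per_min": float(np.mean([f["a"] for f in features_list])),
        "t_as_median_min": float(np.median(t_as) / 60.0) if t_as else None,
        "t_ies_median_min": float(np.median(t_ies) / 60.0) if t_ies else None,
        "n": len(features_list),
    }


def _drop_empty(iv):
    """Drop zero-length fragments that would break per-event averaging."""
    from .intervals import IntervalSet

    return IntervalSet([(s, e) for s, e in iv if e - s > 1e-9], validate=False)


def cohort_features(
    patients: list[tuple[str, EEGRecording]],
    demographics: pd.DataFrame | None = None,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Feature table (one row per patient), optionally joined with
    demographics on ``patient_id``."""
    rows = []
    for pid, rec in patients:
        f = patient_features(rec, cfg)
        rows.append(
            {
                "patient_id": pid,
                "a": f["a"],
                "slope_F": f["slope_F"],
                "slope_Aa": f["slope_Aa"],
                "slope_AIaS": f["slope_AIaS"],
                "label": f["label"],
            }
        )
    df = pd.DataFrame(rows)
    if demographics is not None:
        df = df.merge(
            demographics.drop(columns=["group", "seed"], errors="ignore"),
            on="patient_id",
            how="left",
        )
    return df
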