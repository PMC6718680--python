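"""Iso-electric suppression (IES) detection and patient group labeling.

An IES is a near-flat stretch of the broadband frontal EEG: the Fp1/Fp2
average stays within +/-8 uV for at least one second. Patients are split
into an IES group (>= 10 s of cumulated IES within the first 35 min) and
a noIES group.
"""
from __future__ import annotations

import logging

import numpy as np

from .config import PipelineConfig
from .intervals import IntervalSet
from .io_eeg import EEGRecording
from .segmentation import Segmentation

__all__ = ["detect_ies", "label_patient", "Segmentation"]

logger = logging.getLogger(__name__)


def detect_ies(
    rec: EEGRecording, amp_limit: float = 8.0, min_dur: float = 1.0
) -> IntervalSet:
    """Maximal runs where ``|(Fp1 + Fp2) / 2| <= amp_limit`` for >= ``min_dur``.

    Runs at the recording's native rate on the broadband signal, before
    any alpha-band filtering; sub-threshold runs interrupted by even a
    single-sample excursion are not bridged.
    """
    avg = (rec.channel("Fp1") + rec.channel("Fp2")) / 2.0
    runs = IntervalSet.from_mask(np.abs(avg) <= amp_limit, rec.fs)
    return IntervalSet(
        [(s, e) for s, e in runs if e - s >= min_dur - 1e-12], validate=False
    )


def label_patient(
    seg: Segmentation,
    horizon_min: float = 35.0,
    ies_total_min_s: float = 10.0,
) -> str:
    """Return ``"IES"`` or ``"noIES"`` from the cumulated IES duration.

    The total IES time inside ``[t0, t0 + horizon]`` is compared with the
    10-s group boundary; exactly 10 s counts as IES. A shorter recording
    is labeled on its available span with a warning.
    """
    t0 = seg.span[0]
    horizon_s = horizon_min * 60.0
    if seg.span[1] - t0 < horizon_s:
        logger.warning(
            "recording span %.1f s shorter than the %.0f-min labeling horizon; "
            "labeling on the available span",
            seg.span[1] - t0,
            horizon_min,
        )
    total = seg.ies.overlap(t0, t0 + horizon_s)
    return "IES" if total >= ies_total_min_s else "noIES"


def segment_recording(
    rec: EEGRecording, config: PipelineConfig | None = None
) -> Segmentation:
    """Full three-state segmentation of one recording.

    Alpha-suppressions are detected per channel and merged by consensus;
    IES are detected on the Fp1/Fp2 average; consensus alpha-suppressions
    are trimmed against IES so that aS / IES / alpha+delta partition the
    span.
    """
    from .alpha_detect import detect_alpha_suppressions

    cfg = config or PipelineConfig()
    per_channel, consensus = detect_alpha_suppressions(rec, cfg)
    ies = detect_ies(rec, amp_limit=cfg.ies_amp_uV, min_dur=cfg.ies_min_dur_s)
    return Segmentation(
        per_channel_aS=per_channel,
        consensus_aS=consensus.difference(ies),
        ies=ies,
        span=(0.0, rec.duration),
    )
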