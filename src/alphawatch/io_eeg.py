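"""Reading and writing the formats the pipeline touches.

EDF/EDF+ recordings are read with MNE and converted to microvolts; a
minimal EDF writer is provided so synthetic cohorts can round-trip through
the same clinical container. Interval segmentations and feature tables are
stored as plain CSV.
"""
from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .intervals import IntervalSet
from .segmentation import Segmentation

__all__ = [
    "EEGRecording",
    "REQUIRED_CHANNELS",
    "read_edf",
    "write_edf",
    "resample",
    "write_intervals",
    "read_intervals",
    "write_features",
    "read_features",
]

logger = logging.getLogger(__name__)

#: frontal montage of the Sedline-style four-electrode strip
REQUIRED_CHANNELS = ("Fp1", "Fp2", "F7", "F8")


@dataclass
class EEGRecording:
    """Multichannel sampled EEG in microvolts.

    ``t0`` is the analysis start offset in seconds (start of induction);
    interval times elsewhere in the package are seconds from the first
    sample, with ``t0`` carried as metadata.
    """

    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray  # shape (n_channels, n_samples), uV
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("one label per data row required")
        if self.data.shape[1] == 0:
            raise ValueError("zero-length signal")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        for i, lab in enumerate(self.channel_labels):
            if lab.lower() == name.lower():
                return self.data[i]
        raise KeyError(f"channel {name!r} not present in {self.channel_labels}")

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def _resolve_channels(
    labels: list[str], channel_aliases: dict[str, str] | None
) -> dict[str, str]:
    """Map each required channel to the matching raw label.

    Resolution is case-insensitive: an explicit alias map takes priority,
    then substring matching on fp1/fp2/f7/f8.
    """
    aliases = {k.lower(): v for k, v in (channel_aliases or {}).items()}
    resolved: dict[str, str] = {}
    for target in REQUIRED_CHANNELS:
        found = None
        for lab in labels:
            if aliases.get(lab.lower()) == target:
                found = lab
                break
        if found is None:
            for lab in labels:
                if target.lower() in lab.lower():
                    found = lab
                    break
        if found is None:
            raise ValueError(
                f"missing channel {target}: none of {labels} matches"
            )
        resolved[target] = found
    return resolved


def read_edf(
    path: str | Path, channel_aliases: dict[str, str] | None = None
) -> EEGRecording:
    """Read an EDF/EDF+ file and return the four frontal channels in uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    resolved = _resolve_channels(list(raw.ch_names), channel_aliases)
    data = np.vstack(
        [raw.get_data(picks=[resolved[t]])[0] for t in REQUIRED_CHANNELS]
    )
    # MNE returns Volts for EEG channels; work in microvolts throughout.
    return EEGRecording(
        channel_labels=REQUIRED_CHANNELS,
        fs=float(raw.info["sfreq"]),
        data=data * 1e6,
        meta={"source": str(path)},
    )


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a plain EDF file (16-bit, 1-s data records).

    The sampling rate must be a positive integer. Signals are quantized to
    the 16-bit digital range spanned by each channel's physical extrema.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n = rec.data.shape
    n_rec = int(np.ceil(n / fs))
    pad = n_rec * fs - n
    data = np.pad(rec.data, ((0, 0), (0, pad)), mode="edge") if pad else rec.data

    phys_min = np.floor(np.minimum(data.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(data.max(axis=1), 1.0))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None]) + dig_min,
        dig_min,
        dig_max,
    ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate X X X X", 80),
            f(now.strftime("%d.%m.%y"), 8),
            f(now.strftime("%H.%M.%S"), 8),
            f(str(256 * (1 + n_ch)), 8),
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),
            f(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(f(f"EEG {lab}", 16) for lab in rec.channel_labels),
            b"".join(f("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(f("uV", 8) for _ in range(n_ch)),
            b"".join(f(f"{phys_min[i]:.0f}", 8) for i in range(n_ch)),
            b"".join(f(f"{phys_max[i]:.0f}", 8) for i in range(n_ch)),
            b"".join(f(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(f(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(f("", 80) for _ in range(n_ch)),
            b"".join(f(str(fs), 8) for _ in range(n_ch)),
            b"".join(f("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        # records: for each second, all samples of signal 1, then signal 2, ...
        rec_view = digital.reshape(n_ch, n_rec, fs)
        fh.write(np.ascontiguousarray(rec_view.transpose(1, 0, 2)).tobytes())


def resample(rec: EEGRecording, fs_target: float) -> EEGRecording:
    """Anti-aliased downsampling to ``fs_target`` (upsampling is rejected)."""
    if fs_target > rec.fs + 1e-9:
        raise ValueError("upsampling is not supported")
    if fs_target < 32:
        raise ValueError("target rate must be at least 32 Hz")
    if abs(fs_target - rec.fs) < 1e-9:
        return EEGRecording(rec.channel_labels, rec.fs, rec.data.copy(), rec.t0, dict(rec.meta))
    frac = Fraction(fs_target / rec.fs).limit_denominator(10000)
    out = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1, padtype="line")
    return EEGRecording(rec.channel_labels, fs_target, out, rec.t0, dict(rec.meta))


# ---------------------------------------------------------------------- #
# interval CSV round-trip
# ---------------------------------------------------------------------- #
_INTERVAL_COLUMNS = ["patient_id", "channel", "event_type", "start_s", "end_s"]


def write_intervals(seg: Segmentation, path: str | Path, patient_id: str = "p0") -> None:
    """Write a segmentation as CSV (patient_id, channel, event_type, start_s, end_s)."""
    rows = []
    for ch, iv in seg.per_channel_aS.items():
        rows += [(patient_id, ch, "aS", s, e) for s, e in iv]
    rows += [(patient_id, "consensus", "aS", s, e) for s, e in seg.consensus_aS]
    rows += [(patient_id, "consensus", "IES", s, e) for s, e in seg.ies]
    df = pd.DataFrame(rows, columns=_INTERVAL_COLUMNS)
    df["span_start"] = seg.span[0]
    df["span_end"] = seg.span[1]
    df.to_csv(path, index=False)


def read_intervals(path: str | Path) -> Segmentation:
    """Read a segmentation CSV written by :func:`write_intervals`.

    Malformed rows raise ``ValueError`` naming the offending line number.
    """
    df = pd.read_csv(path)
    missing = set(_INTERVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    per_channel: dict[str, list] = {}
    consensus, ies = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            s, e = float(row["start_s"]), float(row["end_s"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {line}: non-numeric interval bounds") from exc
        if not e > s:
            raise ValueError(f"line {line}: end must exceed start")
        if row["event_type"] == "IES":
            ies.append((s, e))
        elif row["event_type"] == "aS":
            if row["channel"] == "consensus":
                consensus.append((s, e))
            else:
                per_channel.setdefault(str(row["channel"]), []).append((s, e))
        else:
            raise ValueError(f"line {line}: unknown event_type {row['event_type']!r}")
    if len(df) and "span_end" in df.columns:
        span = (float(df["span_start"].iloc[0]), float(df["span_end"].iloc[0]))
    else:
        ends = [e for _, e in consensus + ies] + [
            e for iv in per_channel.values() for _, e in iv
        ]
        span = (0.0, max(ends, default=0.0))
    try:
        return Segmentation(
            per_channel_aS={ch: IntervalSet(iv) for ch, iv in per_channel.items()},
            consensus_aS=IntervalSet(consensus),
            ies=IntervalSet(ies),
            span=span,
        )
    except ValueError as exc:
        raise ValueError(f"invalid intervals in {path}: {exc}") from exc


# ---------------------------------------------------------------------- #
# features CSV
# ---------------------------------------------------------------------- #
def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("features table requires a patient_id column")
    return df
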