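"""Three-state segmentation of a recording: alpha-suppressions (per
electrode and consensus), iso-electric suppressions, and — implicitly —
the remaining alpha+delta (hypnosis) time."""
from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import IntervalSet

__all__ = ["Segmentation"]


@dataclass
class Segmentation:
    """Detector output for one patient.

    ``consensus_aS`` and ``ies`` are disjoint: consensus alpha-suppressions
    are trimmed against IES so that alpha-suppression / IES / alpha+delta
    partition the recording span.
    """

    per_channel_aS: dict[str, IntervalSet] = field(default_factory=dict)
    consensus_aS: IntervalSet = field(default_factory=IntervalSet)
    ies: IntervalSet = field(default_factory=IntervalSet)
    span: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        a, b = self.span
        if b < a:
            raise ValueError("span end must be >= span start")

    @property
    def duration(self) -> float:
        return self.span[1] - self.span[0]

    def hypnosis(self) -> IntervalSet:
        """alpha+delta time: the span minus alpha-suppressions and IES."""
        return self.consensus_aS.union(self.ies).complement(self.span)

    def validate(self) -> None:
        if len(self.consensus_aS.intersection(self.ies)):
            raise ValueError("consensus alpha-suppressions overlap IES")
        for name, iv in list(self.per_channel_aS.items()) + [
            ("consensus", self.consensus_aS),
            ("ies", self.ies),
        ]:
            if len(iv) and (
                iv.starts[0] < self.span[0] - 1e-9 or iv.ends[-1] > self.span[1] + 1e-9
            ):
                raise ValueError(f"intervals of {name!r} fall outside the span")
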