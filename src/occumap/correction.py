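"""Background subtraction and replicate averaging.

The background for epitope-tag ChIP is a no-tag control strain processed
identically (spike-in normalized to RPM).  The control is subtracted from
EACH replicate, and the corrected replicates are then averaged.  With
clamping off the two orders commute (subtraction and averaging are linear);
with clamping on they do not, so the subtract-then-average order is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import CoverageTrack

__all__ = ["CorrectedTrack", "subtract_background", "average_replicates"]


@dataclass
class CorrectedTrack(CoverageTrack):
    control_id: str = ""
    clamped: bool = True


def _check_compatible(tracks: Sequence[CoverageTrack]) -> None:
    first = tracks[0]
    for t in tracks[1:]:
        if t.units != first.units:
            raise ValueError(
                f"unit mismatch: {first.sample_id!r} is {first.units}, "
                f"{t.sample_id!r} is {t.units}"
            )
        if not first.same_declaration(t):
            raise ValueError(
                f"chromosome declarations differ between {first.sample_id!r} "
                f"and {t.sample_id!r}"
            )


def subtract_background(
    signal: CoverageTrack, control: CoverageTrack, clamp: bool = True
) -> CorrectedTrack:
    """Per-base ``signal - control``; negatives clamped to 0 when ``clamp``.

    Both tracks must be RPM (spike-in normalized) on identical chromosome
    declarations.  Clamping is the default for visualization tracks;
    unclamped subtraction is used for per-gene scatter quantities where
    values near zero may legitimately go slightly negative.
    """
    if signal.units != "RPM" or control.units != "RPM":
        raise ValueError(
            "background subtraction requires two RPM tracks "
            f"(got {signal.units!r} and {control.units!r})"
        )
    _check_compatible([signal, control])
    data = {}
    for chrom, arr in signal.data.items():
        diff = arr - control.data[chrom]
        if clamp:
            np.maximum(diff, 0.0, out=diff)
        data[chrom] = diff.astype(np.float32)
    return CorrectedTrack(
        sample_id=signal.sample_id,
        data=data,
        units="RPM",
        scale_factor=signal.scale_factor,
        control_id=control.sample_id,
        clamped=clamp,
    )


def average_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Arithmetic per-base mean of replicate tracks (>= 2 required)."""
    if len(tracks) < 2:
        raise ValueError("replicate averaging requires at least 2 tracks")
    _check_compatible(list(tracks))
    data = {}
    for chrom in tracks[0].data:
        stack = np.stack([t.data[chrom] for t in tracks])
        data[chrom] = stack.mean(axis=0, dtype=np.float64).astype(np.float32)
    sample_id = "+".join(t.sample_id for t in tracks)
    if all(isinstance(t, CorrectedTrack) for t in tracks):
        return CorrectedTrack(
            sample_id=sample_id,
            data=data,
            units=tracks[0].units,
            control_id=getattr(tracks[0], "control_id", ""),
            clamped=all(t.clamped for t in tracks),  # type: ignore[attr-defined]
        )
    return CoverageTrack(sample_id=sample_id, data=data, units=tracks[0].units)
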