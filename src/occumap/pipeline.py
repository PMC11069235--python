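"""Convenience orchestration of the standard track-building recipe:
pileup -> spike-in RPM -> no-tag subtraction per replicate -> average."""

from __future__ import annotations

from typing import Mapping, Sequence

from .correction import average_replicates, subtract_background
from .coverage import (
    CoverageTrack,
    ReadSet,
    build_coverage,
    normalize,
    spikein_scale_factor,
)

__all__ = ["rpm_track", "corrected_average_track"]


def rpm_track(
    rs: ReadSet,
    chrom_sizes: Mapping[str, int],
    extend_to: int | None = None,
) -> CoverageTrack:
    """Raw pileup scaled by the sample's spike-in factor."""
    raw = build_coverage(rs, chrom_sizes, extend_to=extend_to)
    return normalize(raw, spikein_scale_factor(rs))


def corrected_average_track(
    replicates: Sequence[ReadSet],
    control: ReadSet,
    chrom_sizes: Mapping[str, int],
    clamp: bool = True,
    extend_to: int | None = None,
) -> CoverageTrack:
    """Subtract the (spike-in normalized) control from each replicate's RPM
    track, then average the corrected replicates."""
    ctrl = rpm_track(control, chrom_sizes, extend_to)
    corrected = [
        subtract_background(rpm_track(rs, chrom_sizes, extend_to), ctrl, clamp=clamp)
        for rs in replicates
    ]
    if len(corrected) == 1:
        return corrected[0]
    return average_replicates(corrected)
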