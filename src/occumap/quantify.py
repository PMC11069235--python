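"""Windowed per-gene occupancy (RPKM) with null-strain correction.

Per-gene occupancy near an anchor (e.g. -100..+300 bp of the TSS) is
quantified as RPKM: reads overlapping the strand-aware window, divided by
window length in kb and by experiment-genome mapped reads in millions.
RPKM is depth-relative by definition, so spike-in scaling is not applied
here.  Background is removed by subtracting, per gene and unclamped, the
same quantity measured in a null strain lacking the ChIP target (e.g. a
deletion of the gene encoding it), so genuinely empty windows can land
slightly below zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneRecord, GeneSet, anchor_position
from .coverage import ReadSet

__all__ = [
    "WindowSpec",
    "OccupancyTable",
    "gene_window",
    "window_rpkm",
    "null_corrected_occupancy",
    "scatter_table",
]


@dataclass(frozen=True)
class WindowSpec:
    """Anchor-relative window: ``upstream`` bp before to ``downstream`` bp
    after the anchor (both in transcription direction)."""

    anchor: str = "TSS"
    upstream: int = 100
    downstream: int = 300

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(
                f"window length must be positive, got {self.length} "
                f"(upstream={self.upstream}, downstream={self.downstream})"
            )

    @property
    def length(self) -> int:
        return self.upstream + self.downstream


def gene_window(gene: GeneRecord, w: WindowSpec) -> tuple[str, int, int]:
    """Genomic half-open interval of the strand-aware window."""
    chrom, pos, strand = anchor_position(gene, w.anchor)
    if strand == "+":
        return chrom, pos - w.upstream, pos + w.downstream
    return chrom, pos - w.downstream, pos + w.upstream


def window_rpkm(
    rs: ReadSet, genes: GeneSet, w: WindowSpec
) -> dict[str, float]:
    """Per-gene RPKM of reads overlapping the anchor window.

    A read counts if it overlaps the window by at least one base.  The
    per-million denominator is the sample's experiment-genome mapped reads.
    """
    if rs.experiment_reads <= 0:
        raise ValueError(f"sample {rs.sample_id!r} has no experiment reads")
    per_kb = w.length / 1000.0
    per_million = rs.experiment_reads / 1e6
    out: dict[str, float] = {}
    by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in rs.reads.groupby("chrom", sort=False)
    }
    for g in genes:
        chrom, ws, we = gene_window(g, w)
        if chrom not in by_chrom:
            out[g.gene_id] = 0.0
            continue
        starts, ends = by_chrom[chrom]
        count = int(((starts < we) & (ends > ws)).sum())
        out[g.gene_id] = count / per_kb / per_million
    return out


@dataclass
class OccupancyTable:
    """Raw and null-corrected per-gene windowed occupancy.

    ``raw`` is genes x conditions; ``corrected`` holds, for every condition
    other than the null, raw minus the null condition's raw values
    (unclamped).
    """

    raw: pd.DataFrame
    corrected: pd.DataFrame
    null_condition: str

    def to_tsv(self, path: str | Path) -> None:
        df = self.raw.add_prefix("raw_").join(self.corrected.add_prefix("corrected_"))
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.6g")


def null_corrected_occupancy(
    tables: Mapping[str, Mapping[str, float]], null_condition: str
) -> OccupancyTable:
    """Subtract the null condition's per-gene values from every other
    condition, unclamped."""
    if null_condition not in tables:
        raise ValueError(f"null condition {null_condition!r} not among {list(tables)}")
    gene_sets = {cond: frozenset(t) for cond, t in tables.items()}
    ref = gene_sets[null_condition]
    for cond, gs in gene_sets.items():
        if gs != ref:
            extra = sorted(gs ^ ref)
            raise ValueError(
                f"gene sets differ between {cond!r} and {null_condition!r} "
                f"(e.g. {extra[:5]})"
            )
    raw = pd.DataFrame({cond: pd.Series(t) for cond, t in tables.items()}).sort_index()
    null = raw[null_condition]
    corrected = pd.DataFrame(
        {c: raw[c] - null for c in raw.columns if c != null_condition}
    )
    return OccupancyTable(raw=raw, corrected=corrected, null_condition=null_condition)


def scatter_table(
    occ: OccupancyTable, x_condition: str, y_condition: str
) -> pd.DataFrame:
    """Per-gene (x, y) corrected occupancies for a scatter against y = x.

    All genes are reported; no filtering is applied.
    """
    for cond in (x_condition, y_condition):
        if cond not in occ.corrected.columns:
            raise ValueError(
                f"condition {cond!r} has no corrected values "
                f"(available: {list(occ.corrected.columns)})"
            )
    return pd.DataFrame(
        {
            "gene_id": occ.corrected.index,
            "x": occ.corrected[x_condition].to_numpy(),
            "y": occ.corrected[y_condition].to_numpy(),
        }
    )
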