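"""Anchored signal matrices (heatmaps) and metagene profiles.

A :class:`SignalMatrix` holds one row per gene and one column per bin of an
anchor-relative window.  Rows are strand-flipped so that left-to-right is
always upstream-to-downstream of the anchor; window bases that fall outside
the chromosome are masked (NaN) rather than zero-filled, so short
chromosomes do not fabricate depletion, and masked bases are excluded from
bin means and metagene averages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotation import GeneSet, anchor_position
from .coverage import CoverageTrack

__all__ = [
    "SignalMatrix",
    "anchor_matrix",
    "sort_rows_by_length",
    "metagene",
    "tiered_heatmaps",
    "write_matrix_tsv",
    "write_metagene_tsv",
    "plot_heatmap",
    "plot_metagene",
]


@dataclass
class SignalMatrix:
    anchor: str
    flank_up: int
    flank_down: int
    bin_size: int
    gene_ids: list[str]
    values: np.ndarray  # genes x bins, float64, NaN = masked
    row_order: str = "input"  # "input" | "length_desc"
    groups: dict[str, str] | None = None

    @property
    def n_bins(self) -> int:
        return (self.flank_up + self.flank_down) // self.bin_size

    @property
    def bin_offsets(self) -> np.ndarray:
        """Bin-center offsets relative to the anchor (bp)."""
        return (
            -self.flank_up
            + self.bin_size * np.arange(self.n_bins, dtype=float)
            + self.bin_size / 2.0
        )

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def anchor_matrix(
    track: CoverageTrack,
    genes: GeneSet,
    anchor: str = "TSS",
    flank_up: int = 1500,
    flank_down: int = 1500,
    bin_size: int = 10,
    groups: Mapping[str, str] | None = None,
) -> SignalMatrix:
    """Build a strand-aware anchored matrix of bin-mean signal.

    Each cell is the mean per-base signal within its bin; for minus-strand
    genes the window is read in the reverse genomic direction so offset 0 is
    the first transcribed base and positive offsets point downstream.
    """
    if track.units != "RPM":
        raise ValueError(
            f"anchored matrices are built from RPM tracks, got {track.units!r}"
        )
    if flank_up % bin_size or flank_down % bin_size:
        raise ValueError(
            f"flanks ({flank_up}, {flank_down}) must be divisible by "
            f"bin_size ({bin_size})"
        )
    n_bins = (flank_up + flank_down) // bin_size
    width = flank_up + flank_down
    offsets = np.arange(-flank_up, flank_down)
    values = np.empty((len(genes), n_bins), dtype=np.float64)
    for i, g in enumerate(genes):
        chrom, pos, strand = anchor_position(g, anchor)
        if chrom not in track.data:
            raise ValueError(
                f"gene {g.gene_id!r} is on chromosome {chrom!r}, absent from track"
            )
        arr = track.data[chrom]
        if strand == "+":
            idx = pos + offsets
        else:
            idx = pos - 1 - offsets
        valid = (idx >= 0) & (idx < len(arr))
        window = np.full(width, np.nan)
        window[valid] = arr[idx[valid]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            values[i] = np.nanmean(window.reshape(n_bins, bin_size), axis=1)
    return SignalMatrix(
        anchor=anchor.upper(),
        flank_up=flank_up,
        flank_down=flank_down,
        bin_size=bin_size,
        gene_ids=list(genes.gene_ids),
        values=values,
        groups=dict(groups) if groups else None,
    )


def sort_rows_by_length(m: SignalMatrix, genes: GeneSet) -> SignalMatrix:
    """Reorder rows by descending gene length (ties broken by gene_id)."""
    for gid in m.gene_ids:
        if gid not in genes:
            raise ValueError(f"matrix row {gid!r} not present in GeneSet")
    order = sorted(
        range(len(m.gene_ids)),
        key=lambda i: (-genes[m.gene_ids[i]].length, m.gene_ids[i]),
    )
    return SignalMatrix(
        anchor=m.anchor,
        flank_up=m.flank_up,
        flank_down=m.flank_down,
        bin_size=m.bin_size,
        gene_ids=[m.gene_ids[i] for i in order],
        values=m.values[order],
        row_order="length_desc",
        groups=m.groups,
    )


def metagene(
    m: SignalMatrix, groups: Mapping[str, str] | None = None
) -> dict[str, np.ndarray]:
    """Per-group, per-bin mean profile across rows (masked cells excluded).

    Without ``groups`` a single profile over all rows is returned under the
    label ``"all"``.  Genes present in the matrix but absent from ``groups``
    are simply not averaged into any profile.
    """
    if groups is None:
        groups = {gid: "all" for gid in m.gene_ids}
    row_index = {gid: i for i, gid in enumerate(m.gene_ids)}
    labels = sorted(set(groups.values()))
    profiles: dict[str, np.ndarray] = {}
    for label in labels:
        rows = [row_index[gid] for gid, lab in groups.items() if lab == label and gid in row_index]
        missing = [gid for gid, lab in groups.items() if lab == label and gid not in row_index]
        if missing:
            raise ValueError(
                f"group {label!r} includes genes without matrix rows: {missing[:5]}"
            )
        if not rows:
            raise ValueError(f"group {label!r} is empty")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            profiles[label] = np.nanmean(m.values[rows], axis=0)
    return profiles


def tiered_heatmaps(
    track: CoverageTrack,
    genes: GeneSet,
    tiers: Mapping[str, str],
    anchor: str = "TSS",
    flank_up: int = 1500,
    flank_down: int = 1500,
    bin_size: int = 10,
) -> dict[str, SignalMatrix]:
    """One anchored matrix per expression tier (high / medium / low)."""
    by_tier: dict[str, list[str]] = {}
    for g in genes:
        tier = tiers.get(g.gene_id)
        if tier is None:
            raise ValueError(f"gene {g.gene_id!r} has no expression tier")
        by_tier.setdefault(tier, []).append(g.gene_id)
    for tier in ("high", "medium", "low"):
        if tier not in by_tier or not by_tier[tier]:
            raise ValueError(f"expression tier {tier!r} is empty")
    out: dict[str, SignalMatrix] = {}
    for tier, gids in by_tier.items():
        subset = GeneSet([genes[gid] for gid in gids], provenance=f"tier={tier}")
        out[tier] = anchor_matrix(
            track, subset, anchor=anchor, flank_up=flank_up,
            flank_down=flank_down, bin_size=bin_size,
        )
    return out


def write_matrix_tsv(m: SignalMatrix, path: str | Path) -> None:
    """Matrix TSV (gene_id + one column per bin-center offset) with a JSON
    sidecar recording anchor, flanks, bin size, row order and groups."""
    path = Path(path)
    with open(path, "w") as fh:
        header = "gene_id\t" + "\t".join(f"{c:g}" for c in m.bin_offsets)
        fh.write(header + "\n")
        for gid, row in zip(m.gene_ids, m.values):
            cells = "\t".join("NA" if np.isnan(v) else f"{v:.6g}" for v in row)
            fh.write(f"{gid}\t{cells}\n")
    sidecar = {
        "anchor": m.anchor,
        "flank_up": m.flank_up,
        "flank_down": m.flank_down,
        "bin_size": m.bin_size,
        "row_order": m.row_order,
        "groups": m.groups,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def write_metagene_tsv(
    profiles: Mapping[str, np.ndarray], m: SignalMatrix, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("group\tbin_offset\tmean_rpm\n")
        for label, prof in profiles.items():
            for off, v in zip(m.bin_offsets, prof):
                val = "NA" if np.isnan(v) else f"{v:.6g}"
                fh.write(f"{label}\t{off:g}\t{val}\n")


def plot_heatmap(
    m: SignalMatrix, path: str | Path, cap_percentile: float = 95.0
) -> None:
    """Render the matrix as a PNG heatmap, capping color at a percentile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = m.values
    finite = vals[np.isfinite(vals)]
    vmax = float(np.percentile(finite, cap_percentile)) if finite.size else 1.0
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(
        np.nan_to_num(vals, nan=0.0),
        aspect="auto",
        cmap="Blues",
        vmin=0.0,
        vmax=vmax if vmax > 0 else 1.0,
        extent=(-m.flank_up, m.flank_down, len(m.gene_ids), 0),
        interpolation="nearest",
    )
    ax.set_xlabel(f"distance from {m.anchor} (bp)")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metagene(
    profiles: Mapping[str, np.ndarray], m: SignalMatrix, path: str | Path
) -> None:
    """Render metagene profiles as a PNG line plot (y axis: mean RPM)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, prof in profiles.items():
        ax.plot(m.bin_offsets, prof, label=label)
    ax.set_xlabel(f"distance from {m.anchor} (bp)")
    ax.set_ylabel("mean RPM")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
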