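"""Read ingestion and spike-in normalized per-base coverage tracks.

The central currency of the pipeline is the :class:`CoverageTrack`: one
float32 array per chromosome holding per-base signal, either ``raw`` (read
pileup) or ``RPM`` after spike-in scaling.  Spike-in scaling follows the
exogenous-chromatin convention: every sample is multiplied by
``1e6 / spikein_reads`` so that each sample's spike-in depth corresponds to
one million reads, making occupancy comparable across samples and
conditions regardless of IP yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ReadSet",
    "CoverageTrack",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "load_reads",
    "spikein_scale_factor",
    "build_coverage",
    "normalize",
    "write_bedgraph",
    "read_bedgraph",
    "write_bigwig",
]

READ_COLUMNS = ["chrom", "start", "end", "strand"]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    if not sizes:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


@dataclass
class ReadSet:
    """Aligned single-end read intervals for one sample.

    ``reads`` holds the experiment-genome reads; spike-in reads are kept as
    a count (plus an optional interval table for serialization) because only
    their number enters the normalization.
    """

    sample_id: str
    reads: pd.DataFrame
    spikein_reads: int
    experiment_reads: int
    condition: str = ""
    replicate: int = 1
    spikein_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.spikein_reads < 0:
            raise ValueError("spikein_reads must be >= 0")
        if len(self.reads) and not (self.reads["start"] < self.reads["end"]).all():
            bad = int((self.reads["start"] >= self.reads["end"]).sum())
            raise ValueError(f"{bad} read intervals with start >= end")


def _reads_from_sam(
    path: Path, spikein_prefix: str, experiment_chroms: set[str] | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    exp_rows: list[tuple[str, int, int, str]] = []
    spike_rows: list[tuple[str, int, int, str]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            chrom = aln.reference_name
            row = (
                chrom,
                int(aln.reference_start),
                int(aln.reference_end),
                "-" if aln.is_reverse else "+",
            )
            if chrom.startswith(spikein_prefix):
                spike_rows.append(row)
            else:
                if experiment_chroms is not None and chrom not in experiment_chroms:
                    raise ValueError(
                        f"read on chromosome {chrom!r} belongs to neither the "
                        "experiment genome nor the spike-in genome"
                    )
                exp_rows.append(row)
    return (
        pd.DataFrame(exp_rows, columns=READ_COLUMNS),
        pd.DataFrame(spike_rows, columns=READ_COLUMNS),
    )


def _reads_from_bed(
    path: Path, spikein_prefix: str, experiment_chroms: set[str] | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": int, "end": int, "strand": str},
    )
    is_spike = df["chrom"].str.startswith(spikein_prefix)
    exp = df.loc[~is_spike, READ_COLUMNS].reset_index(drop=True)
    spike = df.loc[is_spike, READ_COLUMNS].reset_index(drop=True)
    if experiment_chroms is not None:
        unknown = sorted(set(exp["chrom"]) - experiment_chroms)
        if unknown:
            raise ValueError(
                f"reads on chromosomes {unknown} belong to neither the "
                "experiment genome nor the spike-in genome"
            )
    return exp, spike


def load_reads(
    path: str | Path,
    format: str | None = None,
    spikein_prefix: str = "spombe_",
    chrom_sizes: Mapping[str, int] | None = None,
    sample_id: str | None = None,
    condition: str = "",
    replicate: int = 1,
) -> ReadSet:
    """Load aligned single-end reads from SAM/BAM or 6-column BED.

    Reads are partitioned into experiment vs spike-in by chromosome-name
    prefix; unmapped records are skipped.  When ``chrom_sizes`` is given
    (experiment genome declaration), a read on a chromosome in neither
    genome is an error.
    """
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix.lower() in (".bed", ".bed6") else "sam"
    exp_chroms = None
    if chrom_sizes is not None:
        exp_chroms = {c for c in chrom_sizes if not c.startswith(spikein_prefix)}
    if format.lower() in ("sam", "bam"):
        exp, spike = _reads_from_sam(path, spikein_prefix, exp_chroms)
    elif format.lower() in ("bed", "bed6"):
        exp, spike = _reads_from_bed(path, spikein_prefix, exp_chroms)
    else:
        raise ValueError(f"unsupported read format {format!r}")
    if len(exp) == 0:
        raise ValueError(f"{path}: no experiment-genome reads")
    return ReadSet(
        sample_id=sample_id or path.stem,
        reads=exp,
        spikein_reads=len(spike),
        experiment_reads=len(exp),
        condition=condition,
        replicate=replicate,
        spikein_table=spike if len(spike) else None,
    )


def spikein_scale_factor(rs: ReadSet) -> float:
    """Scale factor adjusting the sample's spike-in reads to one million."""
    if rs.spikein_reads <= 0:
        raise ValueError(
            f"sample {rs.sample_id!r} has no spike-in reads; spike-in "
            "normalization is impossible — use raw/depth-based scaling instead"
        )
    return 1_000_000 / rs.spikein_reads


@dataclass
class CoverageTrack:
    """Per-base signal, one float32 array per experiment chromosome."""

    sample_id: str
    data: dict[str, np.ndarray]
    units: str = "raw"  # "raw" | "RPM"
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.units not in ("raw", "RPM"):
            raise ValueError(f"units must be 'raw' or 'RPM', got {self.units!r}")

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def total_mass(self) -> float:
        """Sum of per-base signal over the whole genome."""
        return float(sum(a.sum(dtype=np.float64) for a in self.data.values()))

    def copy(self) -> "CoverageTrack":
        return replace(self, data={c: a.copy() for c, a in self.data.items()})

    def same_declaration(self, other: "CoverageTrack") -> bool:
        return self.chrom_sizes() == other.chrom_sizes()


def build_coverage(
    rs: ReadSet,
    chrom_sizes: Mapping[str, int],
    extend_to: int | None = None,
) -> CoverageTrack:
    """Pile reads into a raw per-base coverage track.

    Each read adds +1 to every base of its interval; with ``extend_to`` the
    interval is extended to that length from the read's 5' end in the
    strand-aware downstream direction.  Intervals are truncated at
    chromosome bounds.
    """
    reads = rs.reads
    starts = reads["start"].to_numpy(dtype=np.int64, copy=True)
    ends = reads["end"].to_numpy(dtype=np.int64, copy=True)
    if extend_to is not None:
        lengths = ends - starts
        if (lengths > extend_to).any():
            raise ValueError(
                f"extend_to={extend_to} is shorter than the longest read "
                f"({int(lengths.max())} bp)"
            )
        minus = (reads["strand"] == "-").to_numpy()
        ends = np.where(minus, ends, starts + extend_to)
        starts = np.where(minus, ends - extend_to, starts)
    data: dict[str, np.ndarray] = {}
    chrom_arr = reads["chrom"].to_numpy()
    read_chroms = set(chrom_arr.tolist())
    missing = read_chroms - set(chrom_sizes)
    if missing:
        raise ValueError(f"chrom_sizes does not declare chromosomes {sorted(missing)}")
    for chrom, length in chrom_sizes.items():
        sel = chrom_arr == chrom
        diff = np.zeros(length + 1, dtype=np.float64)
        if sel.any():
            s = np.clip(starts[sel], 0, length)
            e = np.clip(ends[sel], 0, length)
            keep = s < e
            np.add.at(diff, s[keep], 1.0)
            np.add.at(diff, e[keep], -1.0)
        data[chrom] = np.cumsum(diff[:-1]).astype(np.float32)
    return CoverageTrack(sample_id=rs.sample_id, data=data, units="raw")


def normalize(cov: CoverageTrack, factor: float) -> CoverageTrack:
    """Apply a spike-in scale factor, producing an RPM track.

    Double normalization is rejected: the input must be a raw track.
    """
    if cov.units != "raw":
        raise ValueError(
            f"track {cov.sample_id!r} already has units {cov.units!r}; "
            "normalization must be applied exactly once"
        )
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    data = {c: (a * np.float32(factor)).astype(np.float32) for c, a in cov.data.items()}
    return CoverageTrack(
        sample_id=cov.sample_id, data=data, units="RPM", scale_factor=factor
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write the track as 4-column bedGraph (0-based half-open), run-length
    encoded; zero runs are written so the file round-trips exactly."""
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            vals = arr[starts]
            for s, e, v in zip(starts, ends, vals):
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    units: str = "RPM",
    sample_id: str | None = None,
) -> CoverageTrack:
    """Reconstruct a CoverageTrack from bedGraph plus a genome declaration."""
    data = {c: np.zeros(n, dtype=np.float32) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in data:
                raise ValueError(f"{path}:{lineno}: undeclared chromosome {chrom!r}")
            data[chrom][s:e] = v
    return CoverageTrack(
        sample_id=sample_id or Path(path).stem, data=data, units=units
    )


def write_bigwig(track: CoverageTrack, path: str | Path) -> None:
    """Write the track as bigWig (requires pyBigWig)."""
    import pyBigWig  # deferred: optional output format

    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader(list(track.chrom_sizes().items()))
        for chrom, arr in track.data.items():
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            vals = arr[starts].astype(float)
            keep = vals != 0
            if keep.any():
                bw.addEntries(
                    [chrom] * int(keep.sum()),
                    starts[keep].tolist(),
                    ends=ends[keep].tolist(),
                    values=vals[keep].tolist(),
                )
    finally:
        bw.close()
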