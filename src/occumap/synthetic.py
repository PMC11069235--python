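"""Synthetic ChIP-seq data: genomes, gene sets, and read simulation.

The simulator emulates the occupancy structures seen in budding-yeast
ChIP-seq of the H2Bub/H3K4me3 axis: uniform gene-body signal (Rad6-like),
sharp TSS-proximal peaks (Set1/H3K4me3-like), TTS-proximal peaks
(CPF-like), mixtures of the two (Swd2-like), and background-only landscapes
(no-tag controls, deletion strains).  Reads are 51-bp single-end by
default; a disjoint spike-in genome receives a configurable fraction of
reads, emulating exogenous-chromatin spike-in.

The generative model is read-start based: each landscape is an intensity
function over candidate 5' read positions; a read is then extended
``read_len`` bases downstream on a uniformly random strand (ChIP signal is
strand-symmetric).  Landscape weights are relative — reads are allocated
multinomially across genes and background in proportion to them — so the
``amplitude`` parameter sets the expected signal reads per gene relative to
``background_rate`` (reads per kb genome-wide).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneRecord, GeneSet, classify_by_expression
from .coverage import READ_COLUMNS, ReadSet, write_chrom_sizes

__all__ = [
    "OccupancyModel",
    "SimTruth",
    "SimSuite",
    "make_genome",
    "make_genes",
    "make_expression",
    "simulate_reads",
    "condition_suite",
    "ip_yield_spikein_fraction",
    "write_sam",
    "write_read_bed",
]

DEFAULT_SPIKEIN_PREFIX = "spombe_"

#: Length ranges (bp, half-open) used to populate the five gene-length
#: classes; round-robin assignment keeps every class populated.
DEFAULT_LENGTH_RANGES: tuple[tuple[int, int], ...] = (
    (150, 750),
    (750, 1500),
    (1500, 2250),
    (2250, 3000),
    (3000, 3750),
)

SHAPES = ("uniform_gene_body", "tss_peak", "tts_peak", "mixture", "background_only")


@dataclass(frozen=True)
class OccupancyModel:
    """Parametric per-gene occupancy landscape.

    amplitude
        Expected signal reads per gene (relative weight against background).
    peak_offset, peak_width
        Mean and s.d. (bp) of the Gaussian read-start kernel for peak
        shapes, in anchor-relative, strand-flipped coordinates (positive =
        downstream).
    background_rate
        Nonspecific reads per kb, uniform over the experiment genome.
    tier_multipliers
        Amplitude multipliers for (high, medium, low) expression tiers;
        applied only when an expression-tier map is supplied.
    components
        For ``mixture``: (weight, model) pairs; weights must sum to 1 and
        the parent amplitude is split across components by weight.
    """

    shape: str
    amplitude: float = 0.0
    peak_offset: float = 100.0
    peak_width: float = 150.0
    background_rate: float = 0.0
    tier_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    components: tuple[tuple[float, "OccupancyModel"], ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape == "background_only" and self.amplitude != 0:
            raise ValueError("background_only landscapes must have amplitude 0")
        if self.shape == "mixture":
            if not self.components:
                raise ValueError("mixture requires components")
            total = sum(w for w, _ in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {total}")


@dataclass
class SimTruth:
    """Planted ground truth for one simulated sample; fully determined by
    (config, seed)."""

    sample_id: str
    condition: str
    replicate: int
    seed: int
    n_reads: int
    spikein_fraction: float
    expected_counts: dict[str, float]
    peak_offsets: dict[str, float]
    tier_multiplier_by_gene: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "condition": self.condition,
            "replicate": self.replicate,
            "seed": self.seed,
            "n_reads": self.n_reads,
            "spikein_fraction": self.spikein_fraction,
            "expected_counts": self.expected_counts,
            "peak_offsets": self.peak_offsets,
            "tier_multiplier_by_gene": self.tier_multiplier_by_gene,
        }


def make_genome(
    n_chroms: int,
    chrom_length: int,
    spikein_chroms: int = 1,
    spikein_chrom_length: int | None = None,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
) -> dict[str, int]:
    """Declare a small multi-chromosome genome plus a disjoint spike-in
    genome, as a chrom.sizes mapping."""
    if n_chroms < 1 or chrom_length < 1:
        raise ValueError("need at least one experiment chromosome of positive length")
    if spikein_chroms < 0:
        raise ValueError("spikein_chroms must be >= 0")
    if spikein_chrom_length is None:
        spikein_chrom_length = chrom_length // 2
    sizes = {f"chrS{i + 1}": int(chrom_length) for i in range(n_chroms)}
    for i in range(spikein_chroms):
        sizes[f"{spikein_prefix}chr{i + 1}"] = int(spikein_chrom_length)
    return sizes


def experiment_sizes(
    chrom_sizes: Mapping[str, int], spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX
) -> dict[str, int]:
    return {c: n for c, n in chrom_sizes.items() if not c.startswith(spikein_prefix)}


def spikein_sizes(
    chrom_sizes: Mapping[str, int], spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX
) -> dict[str, int]:
    return {c: n for c, n in chrom_sizes.items() if c.startswith(spikein_prefix)}


def make_genes(
    chrom_sizes: Mapping[str, int],
    n: int,
    min_gap: int = 150,
    strand_prob: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
    length_ranges: Sequence[tuple[int, int]] = DEFAULT_LENGTH_RANGES,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
) -> GeneSet:
    """Place n non-overlapping, strand-mixed genes on the experiment genome.

    Lengths are assigned round-robin across ``length_ranges`` (then drawn
    uniformly within each range) so all five length classes are populated
    whenever n >= len(length_ranges).
    """
    exp = experiment_sizes(chrom_sizes, spikein_prefix)
    if not exp:
        raise ValueError("no experiment chromosomes in the genome declaration")
    if n < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    ranges = [length_ranges[i % len(length_ranges)] for i in range(n)]
    lengths = np.array([rng.integers(lo, hi) for lo, hi in ranges])
    order = rng.permutation(n)
    lengths = lengths[order]
    chroms = list(exp)
    cursors = {c: min_gap for c in chroms}
    placements: list[tuple[str, int, int]] = []
    ci = 0
    for L in lengths:
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            gap = int(rng.integers(0, min_gap + 1))
            start = cursors[chrom] + gap
            end = start + int(L)
            if end + min_gap <= exp[chrom]:
                placements.append((chrom, start, end))
                cursors[chrom] = end + min_gap
                placed = True
                break
        if not placed:
            raise ValueError(
                f"genome too small to place {n} genes with min_gap={min_gap}"
            )
    placements.sort(key=lambda p: (p[0], p[1]))
    width = len(str(n))
    genes = []
    for i, (chrom, start, end) in enumerate(placements):
        strand = "+" if rng.random() < strand_prob else "-"
        genes.append(
            GeneRecord(
                gene_id=f"g{i + 1:0{width}d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
            )
        )
    return GeneSet(genes, provenance=f"synthetic(n={n})")


def make_expression(
    genes: GeneSet, seed: int | np.random.SeedSequence = 0
) -> dict[str, float]:
    """Log-normal per-gene RPKM values (median ~20, ~10-fold spread),
    mimicking the skewed mRNA abundance distribution of yeast."""
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=3.0, sigma=1.2, size=len(genes))
    return {g.gene_id: float(v) for g, v in zip(genes, vals)}


_TIER_INDEX = {"high": 0, "medium": 1, "low": 2}


def _leaf_components(
    model: OccupancyModel,
) -> list[tuple[float, OccupancyModel]]:
    if model.shape == "mixture":
        leaves: list[tuple[float, OccupancyModel]] = []
        for w, comp in model.components:
            if comp.shape == "mixture":
                raise ValueError("nested mixtures are not supported")
            leaves.append((w, comp))
        return leaves
    return [(1.0, model)]


def _gene_shape_weights(
    comp: OccupancyModel, genes: GeneSet
) -> np.ndarray:
    """Relative per-gene weight of one landscape component (mean ~1)."""
    if comp.shape == "uniform_gene_body":
        lengths = np.array([g.length for g in genes], dtype=float)
        return lengths / lengths.mean()
    if comp.shape in ("tss_peak", "tts_peak"):
        return np.ones(len(genes))
    return np.zeros(len(genes))  # background_only


def _tier_multipliers(
    model: OccupancyModel, genes: GeneSet, tiers: Mapping[str, str] | None
) -> np.ndarray:
    if tiers is None:
        return np.ones(len(genes))
    mult = np.empty(len(genes))
    for i, g in enumerate(genes):
        tier = tiers.get(g.gene_id)
        if tier is None:
            raise ValueError(f"gene {g.gene_id!r} has no expression tier")
        mult[i] = model.tier_multipliers[_TIER_INDEX[tier]]
    return mult


def _peak_positions(
    comp: OccupancyModel,
    gene: GeneRecord,
    k: int,
    chrom_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    anchor = gene.tss if comp.shape == "tss_peak" else gene.tts
    rel = np.rint(rng.normal(comp.peak_offset, comp.peak_width, size=k)).astype(
        np.int64
    )
    if gene.strand == "+":
        pos = anchor + rel
    else:
        pos = anchor - 1 - rel
    return np.clip(pos, 0, chrom_len - 1)


def simulate_reads(
    genes: GeneSet,
    model: OccupancyModel,
    chrom_sizes: Mapping[str, int],
    n_reads: int,
    read_len: int = 51,
    spikein_fraction: float = 0.1,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
    seed: int | np.random.SeedSequence = 0,
    sample_id: str = "sim",
    condition: str = "",
    replicate: int = 1,
    tiers: Mapping[str, str] | None = None,
) -> tuple[ReadSet, SimTruth]:
    """Draw single-end reads from an occupancy landscape plus spike-in.

    The spike-in read count is Binomial(n_reads, spikein_fraction), uniform
    over spike-in chromosomes; the remaining reads are allocated
    multinomially across gene landscape components and uniform background.
    """
    if not 0 <= spikein_fraction < 1:
        raise ValueError("spikein_fraction must be in [0, 1)")
    exp = experiment_sizes(chrom_sizes, spikein_prefix)
    spike = spikein_sizes(chrom_sizes, spikein_prefix)
    if spikein_fraction > 0 and not spike:
        raise ValueError("spike-in requested but no spike-in chromosomes declared")
    genes.validate_chromosomes(exp)
    rng = np.random.default_rng(seed)

    leaves = _leaf_components(model)
    tier_mult = _tier_multipliers(model, genes, tiers)
    # weight matrix: components x genes
    comp_weights = np.stack(
        [w * model.amplitude * _gene_shape_weights(c, genes) * tier_mult
         for w, c in leaves]
    ) if model.amplitude > 0 else np.zeros((len(leaves), len(genes)))
    genome_kb = sum(exp.values()) / 1000.0
    bg_mass = model.background_rate * genome_kb
    total_mass = float(comp_weights.sum() + bg_mass)
    if total_mass <= 0:
        raise ValueError("landscape has zero total mass (no signal, no background)")

    n_spike = int(rng.binomial(n_reads, spikein_fraction)) if spikein_fraction else 0
    n_exp = n_reads - n_spike

    flat = np.concatenate([comp_weights.ravel(), [bg_mass]])
    counts = rng.multinomial(n_exp, flat / flat.sum())
    gene_counts = counts[:-1].reshape(comp_weights.shape)
    n_bg = int(counts[-1])

    gene_list = list(genes)
    chrom_rows: list[np.ndarray] = []
    pos_rows: list[np.ndarray] = []
    chrom_code = {c: i for i, c in enumerate(list(exp) + list(spike))}
    code_chrom = np.array(list(exp) + list(spike), dtype=object)

    for (w, comp), row in zip(leaves, gene_counts):
        for g, k in zip(gene_list, row):
            k = int(k)
            if k == 0:
                continue
            L = exp[g.chrom]
            if comp.shape == "uniform_gene_body":
                pos = rng.integers(g.start, g.end, size=k)
            else:
                pos = _peak_positions(comp, g, k, L, rng)
            chrom_rows.append(np.full(k, chrom_code[g.chrom], dtype=np.int64))
            pos_rows.append(pos.astype(np.int64))
    if n_bg:
        exp_names = list(exp)
        exp_lens = np.array([exp[c] for c in exp_names], dtype=float)
        which = rng.choice(len(exp_names), size=n_bg, p=exp_lens / exp_lens.sum())
        pos = rng.integers(0, exp_lens[which].astype(np.int64))
        chrom_rows.append(np.array([chrom_code[exp_names[i]] for i in which]))
        pos_rows.append(pos.astype(np.int64))

    if chrom_rows:
        codes = np.concatenate(chrom_rows)
        positions = np.concatenate(pos_rows)
    else:
        codes = np.empty(0, dtype=np.int64)
        positions = np.empty(0, dtype=np.int64)

    reads = _reads_from_positions(
        codes, positions, code_chrom,
        {**exp, **spike}, read_len, rng,
    )

    if n_spike:
        sp_names = list(spike)
        sp_lens = np.array([spike[c] for c in sp_names], dtype=float)
        which = rng.choice(len(sp_names), size=n_spike, p=sp_lens / sp_lens.sum())
        sp_pos = rng.integers(0, sp_lens[which].astype(np.int64))
        sp_codes = np.array([chrom_code[sp_names[i]] for i in which])
        spike_reads = _reads_from_positions(
            sp_codes, sp_pos.astype(np.int64), code_chrom,
            {**exp, **spike}, read_len, rng,
        )
    else:
        spike_reads = None

    expected = n_exp * comp_weights.sum(axis=0) / total_mass
    seed_int = (
        int(np.random.SeedSequence(seed).generate_state(1)[0])
        if isinstance(seed, int)
        else int(seed.generate_state(1)[0])
    )
    truth = SimTruth(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        seed=seed_int,
        n_reads=n_reads,
        spikein_fraction=spikein_fraction,
        expected_counts={
            g.gene_id: float(e) for g, e in zip(gene_list, expected)
        },
        peak_offsets={
            c.shape: float(c.peak_offset)
            for _, c in leaves
            if c.shape in ("tss_peak", "tts_peak")
        },
        tier_multiplier_by_gene={
            g.gene_id: float(m) for g, m in zip(gene_list, tier_mult)
        },
    )
    rs = ReadSet(
        sample_id=sample_id,
        reads=reads,
        spikein_reads=n_spike,
        experiment_reads=len(reads),
        condition=condition,
        replicate=replicate,
        spikein_table=spike_reads,
    )
    return rs, truth


def _reads_from_positions(
    codes: np.ndarray,
    positions: np.ndarray,
    code_chrom: np.ndarray,
    sizes: Mapping[str, int],
    read_len: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Turn 5' read-start positions into strand-assigned read intervals."""
    n = len(positions)
    minus = rng.random(n) < 0.5
    starts = np.where(minus, positions - read_len + 1, positions)
    ends = np.where(minus, positions + 1, positions + read_len)
    lens_by_code = np.array([sizes[c] for c in code_chrom], dtype=np.int64)
    lens = lens_by_code[codes]
    starts = np.clip(starts, 0, None)
    ends = np.minimum(ends, lens)
    df = pd.DataFrame(
        {
            "chrom": code_chrom[codes],
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "strand": np.where(minus, "-", "+"),
        }
    )
    df = df.sort_values(
        ["chrom", "start", "end", "strand"], kind="stable"
    ).reset_index(drop=True)
    return df[READ_COLUMNS]


def ip_yield_spikein_fraction(
    signal_mass: float, background_mass: float, chromatin_fraction: float
) -> float:
    """Expected spike-in read fraction under an IP-yield model.

    The spike-in chromatin (fraction ``chromatin_fraction`` of the pooled
    extract) is recovered only by nonspecific pulldown, at the same rate as
    the experiment background; specific signal dilutes the spike-in share
    of a fixed-depth library.  For a background-only IP the read fraction
    equals the chromatin fraction.
    """
    if not 0 < chromatin_fraction < 1:
        raise ValueError("chromatin_fraction must be in (0, 1)")
    if background_mass <= 0:
        raise ValueError("background_mass must be positive")
    spike_mass = background_mass * chromatin_fraction / (1 - chromatin_fraction)
    return spike_mass / (spike_mass + signal_mass + background_mass)


@dataclass
class SimSuite:
    """A bundle of simulated samples emulating a multi-condition ChIP-seq
    study design."""

    chrom_sizes: dict[str, int]
    genes: GeneSet
    rpkm: dict[str, float]
    tiers: dict[str, str]
    samples: dict[str, list[ReadSet]]
    truths: dict[str, list[SimTruth]]
    seed: int
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX

    @property
    def experiment_sizes(self) -> dict[str, int]:
        return experiment_sizes(self.chrom_sizes, self.spikein_prefix)

    def write(self, out_dir: str | Path, read_format: str = "sam") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.chrom_sizes, out / "chrom.sizes")
        from .annotation import write_genes_bed

        write_genes_bed(self.genes, out / "genes.bed")
        with open(out / "expression_rpkm.tsv", "w") as fh:
            fh.write("gene_id\trpkm\n")
            for gid, v in self.rpkm.items():
                fh.write(f"{gid}\t{v:.6g}\n")
        truth_blob = {
            cond: [t.to_dict() for t in ts] for cond, ts in self.truths.items()
        }
        with open(out / "truth.json", "w") as fh:
            json.dump({"seed": self.seed, "samples": truth_blob}, fh, indent=2)
        for cond, readsets in self.samples.items():
            for rs in readsets:
                stem = f"{cond}_rep{rs.replicate}"
                if read_format == "sam":
                    write_sam(rs, self.chrom_sizes, out / f"{stem}.sam")
                else:
                    write_read_bed(rs, out / f"{stem}.bed")


def condition_suite(
    seed: int = 0,
    n_reads: int = 200_000,
    n_genes: int = 120,
    n_chroms: int = 2,
    chrom_length: int = 200_000,
    read_len: int = 51,
    replicates: int = 2,
    amplitude: float = 1500.0,
    background_rate: float = 25.0,
    chromatin_fraction: float = 0.1,
    tss_peak_offset: float = 100.0,
    tss_peak_width: float = 150.0,
    wt_mixture_weights: tuple[float, float] = (0.6, 0.4),
    tier_multipliers: tuple[float, float, float] = (4.0, 1.5, 0.5),
) -> SimSuite:
    """Simulate the full multi-condition study design.

    Conditions (all sharing one gene set, genome, and background rate):

    - ``rad6_wt``: uniform gene-body occupancy (H2B ubiquitinase-like).
    - ``h3k4me3_wt``: sharp TSS-proximal peak.
    - ``set1_tiered``: TSS peak with amplitude scaled by expression tier.
    - ``swd2_wt``: mixture of TSS and TTS peaks (dual COMPASS/CPF binding).
    - ``swd2_dset1``: TTS peak only, full amplitude — the 5' peak is lost
      and the 3' occupancy rises when the methyltransferase is absent.
    - ``swd2_drad6``: background only — chromatin binding is lost without
      the ubiquitinase.
    - ``notag``: background only, single replicate (the subtractive
      control).

    Each sample's spike-in read fraction follows the IP-yield model in
    :func:`ip_yield_spikein_fraction` with a 10% chromatin spike, so
    low-yield IPs (background-only conditions) carry proportionally more
    spike-in reads, which is precisely what spike-in normalization corrects.
    """
    root = np.random.SeedSequence(seed)
    ss_genes, ss_expr, ss_samples = root.spawn(3)
    chrom_sizes = make_genome(n_chroms, chrom_length)
    genes = make_genes(chrom_sizes, n_genes, seed=ss_genes)
    rpkm = make_expression(genes, seed=ss_expr)
    tiers = classify_by_expression(genes, rpkm)

    bg = background_rate
    tss = OccupancyModel(
        "tss_peak", amplitude=amplitude, peak_offset=tss_peak_offset,
        peak_width=tss_peak_width, background_rate=bg,
    )
    tts = OccupancyModel(
        "tts_peak", amplitude=amplitude, peak_offset=0.0,
        peak_width=tss_peak_width, background_rate=bg,
    )
    w5, w3 = wt_mixture_weights
    models: dict[str, tuple[OccupancyModel, Mapping[str, str] | None]] = {
        "rad6_wt": (
            OccupancyModel(
                "uniform_gene_body", amplitude=amplitude, background_rate=bg
            ),
            None,
        ),
        "h3k4me3_wt": (tss, None),
        "set1_tiered": (
            OccupancyModel(
                "tss_peak", amplitude=amplitude, peak_offset=tss_peak_offset,
                peak_width=tss_peak_width, background_rate=bg,
                tier_multipliers=tier_multipliers,
            ),
            tiers,
        ),
        "swd2_wt": (
            OccupancyModel(
                "mixture", amplitude=amplitude, background_rate=bg,
                components=(
                    (w5, OccupancyModel("tss_peak", amplitude=1.0,
                                        peak_offset=tss_peak_offset,
                                        peak_width=tss_peak_width)),
                    (w3, OccupancyModel("tts_peak", amplitude=1.0,
                                        peak_offset=0.0,
                                        peak_width=tss_peak_width)),
                ),
            ),
            None,
        ),
        "swd2_dset1": (tts, None),
        "swd2_drad6": (
            OccupancyModel("background_only", background_rate=bg),
            None,
        ),
        "notag": (
            OccupancyModel("background_only", background_rate=bg),
            None,
        ),
    }

    genome_kb = sum(experiment_sizes(chrom_sizes).values()) / 1000.0
    bg_mass = bg * genome_kb

    samples: dict[str, list[ReadSet]] = {}
    truths: dict[str, list[SimTruth]] = {}
    child_seeds = iter(ss_samples.spawn(len(models) * replicates))
    for cond, (model, cond_tiers) in models.items():
        n_reps = 1 if cond == "notag" else replicates
        leaves = _leaf_components(model)
        tier_mult = _tier_multipliers(model, genes, cond_tiers)
        signal_mass = float(
            sum(
                w * model.amplitude
                * (_gene_shape_weights(c, genes) * tier_mult).sum()
                for w, c in leaves
            )
        )
        frac = ip_yield_spikein_fraction(signal_mass, bg_mass, chromatin_fraction)
        samples[cond] = []
        truths[cond] = []
        for rep in range(1, n_reps + 1):
            rs, truth = simulate_reads(
                genes,
                model,
                chrom_sizes,
                n_reads=n_reads,
                read_len=read_len,
                spikein_fraction=frac,
                seed=next(child_seeds),
                sample_id=f"{cond}_rep{rep}",
                condition=cond,
                replicate=rep,
                tiers=cond_tiers,
            )
            samples[cond].append(rs)
            truths[cond].append(truth)
    return SimSuite(
        chrom_sizes=chrom_sizes,
        genes=genes,
        rpkm=rpkm,
        tiers=tiers,
        samples=samples,
        truths=truths,
        seed=seed,
    )


def write_sam(
    rs: ReadSet, chrom_sizes: Mapping[str, int], path: str | Path
) -> None:
    """Write experiment + spike-in reads as a headered single-end SAM.

    Sequences are omitted ('*'); only placement matters downstream.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_sizes.items()],
    }
    tables = [rs.reads]
    if rs.spikein_table is not None:
        tables.append(rs.spikein_table)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        i = 0
        for table in tables:
            for chrom, start, end, strand in table.itertuples(index=False):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"r{i}"
                a.flag = 16 if strand == "-" else 0
                a.reference_id = out.header.get_tid(chrom)
                a.reference_start = int(start)
                a.mapping_quality = 42
                a.cigarstring = f"{int(end) - int(start)}M"
                i += 1
                out.write(a)


def write_read_bed(rs: ReadSet, path: str | Path) -> None:
    """Write experiment + spike-in reads as 6-column BED."""
    tables = [rs.reads]
    if rs.spikein_table is not None:
        tables.append(rs.spikein_table)
    with open(path, "w") as fh:
        i = 0
        for table in tables:
            for chrom, start, end, strand in table.itertuples(index=False):
                fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{strand}\n")
                i += 1
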