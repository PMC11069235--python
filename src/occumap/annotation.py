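"""Gene annotation handling: loading, anchors, and gene classification.

Coordinates are 0-based, half-open ``[start, end)`` throughout the package.
BED input is native to this convention; GFF3 input is converted (start - 1).
The TSS of a minus-strand gene is its ``end`` coordinate (the exclusive
bound), so that anchor-relative offset ``x`` maps to genomic base
``anchor + x`` on plus strands and ``anchor - 1 - x`` on minus strands:
offset 0 is always the first transcribed base and positive offsets always
point downstream (into the gene body).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GeneRecord",
    "GeneSet",
    "LENGTH_BOUNDARIES",
    "LENGTH_LABELS",
    "load_genes",
    "classify_by_length",
    "classify_by_expression",
    "anchor_position",
    "write_gene_table",
]

#: Default gene-length class boundaries in bp.  The five classes XS..XL
#: partition [1, 3750) half-open; genes >= 3750 bp fall into OVER.
LENGTH_BOUNDARIES: tuple[int, ...] = (750, 1500, 2250, 3000, 3750)
LENGTH_LABELS: tuple[str, ...] = ("XS", "S", "M", "L", "XL")

EXPRESSION_TIERS: tuple[str, str, str] = ("high", "medium", "low")


@dataclass(frozen=True)
class GeneRecord:
    """A single gene interval with strand-aware anchors."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start must be < end ({self.start} >= {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end`` on -."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Transcription termination site: the end opposite the TSS."""
        return self.end if self.strand == "+" else self.start


class GeneSet:
    """An ordered, id-unique collection of :class:`GeneRecord`."""

    def __init__(self, genes: Iterable[GeneRecord], provenance: str = "") -> None:
        self.genes: list[GeneRecord] = list(genes)
        self.provenance = provenance
        self._by_id: dict[str, GeneRecord] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def chromosomes(self) -> set[str]:
        return {g.chrom for g in self.genes}

    def validate_chromosomes(self, chrom_sizes: Mapping[str, int]) -> None:
        """Every gene must live on a declared chromosome and fit inside it."""
        for g in self.genes:
            if g.chrom not in chrom_sizes:
                raise ValueError(
                    f"gene {g.gene_id!r} on undeclared chromosome {g.chrom!r}"
                )
            if g.end > chrom_sizes[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id!r} extends past the end of {g.chrom!r} "
                    f"({g.end} > {chrom_sizes[g.chrom]})"
                )


def _parse_bed6(path: Path) -> Iterator[GeneRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 requires 6 fields, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: missing or invalid strand {strand!r}"
                )
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            yield GeneRecord(gene_id=name, chrom=chrom, start=s, end=e, strand=strand)


def _gff3_attr(attrs: str, lineno: int, path: Path) -> str:
    """Extract a gene identifier from a GFF3 column-9 attribute string."""
    parsed = {}
    for item in attrs.strip().split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        k, v = item.split("=", 1)
        parsed[k] = v
    for key in ("ID", "gene_id", "Name", "locus_tag"):
        if key in parsed:
            return parsed[key]
    raise ValueError(f"{path}:{lineno}: no ID/gene_id/Name attribute in {attrs!r}")


def _parse_gff3(path: Path) -> Iterator[GeneRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: GFF3 requires 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: missing or invalid strand {strand!r}"
                )
            try:
                # GFF3 is 1-based inclusive; convert to 0-based half-open.
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            gid = _gff3_attr(attrs, lineno, path)
            yield GeneRecord(gene_id=gid, chrom=chrom, start=s, end=e, strand=strand)


def load_genes(path: str | Path, format: str | None = None) -> GeneSet:
    """Load gene annotations from BED6 or GFF3 (``gene`` features only).

    Parameters
    ----------
    path
        Annotation file path.
    format
        ``"bed"`` or ``"gff3"``; inferred from the file suffix when None.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".bed", ".bed6"):
            format = "bed"
        elif suffix in (".gff", ".gff3"):
            format = "gff3"
        else:
            raise ValueError(
                f"cannot infer annotation format from {path.name!r}; pass format="
            )
    format = format.lower()
    if format in ("bed", "bed6"):
        records = _parse_bed6(path)
    elif format in ("gff", "gff3"):
        records = _parse_gff3(path)
    else:
        raise ValueError(f"unsupported annotation format {format!r}")
    return GeneSet(records, provenance=f"{path} ({format})")


def classify_by_length(
    genes: GeneSet,
    boundaries: Sequence[int] = LENGTH_BOUNDARIES,
) -> dict[str, str]:
    """Label each gene with a half-open length class.

    With the default boundaries the classes are XS [1, 750), S [750, 1500),
    M [1500, 2250), L [2250, 3000), XL [3000, 3750); genes at or beyond the
    last boundary are labelled ``OVER`` (kept in whole-genome heatmaps but
    excluded from five-class metagenes).
    """
    if len(genes) == 0:
        raise ValueError("cannot classify an empty GeneSet")
    bounds = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("length boundaries must be strictly increasing")
    if len(bounds) != len(LENGTH_LABELS):
        raise ValueError(
            f"expected {len(LENGTH_LABELS)} boundaries, got {len(bounds)}"
        )
    labels: dict[str, str] = {}
    for g in genes:
        for label, upper in zip(LENGTH_LABELS, bounds):
            if g.length < upper:
                labels[g.gene_id] = label
                break
        else:
            labels[g.gene_id] = "OVER"
    return labels


def classify_by_expression(
    genes: GeneSet, rpkm: Mapping[str, float]
) -> dict[str, str]:
    """Split genes into high/medium/low expression tiers by RPKM rank.

    Genes are sorted by RPKM descending (ties broken by gene_id so the split
    is deterministic); the first floor(n/3) are ``high``, the next floor(n/3)
    ``medium``, and the remainder ``low``.  For n = 6020 this yields tier
    sizes 2006 / 2006 / 2008.
    """
    if len(genes) == 0:
        raise ValueError("cannot classify an empty GeneSet")
    missing = [g.gene_id for g in genes if g.gene_id not in rpkm]
    if missing:
        raise ValueError(
            f"missing RPKM values for {len(missing)} genes: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    ranked = sorted(genes.gene_ids, key=lambda gid: (-float(rpkm[gid]), gid))
    n = len(ranked)
    third = n // 3
    tiers: dict[str, str] = {}
    for i, gid in enumerate(ranked):
        if i < third:
            tiers[gid] = "high"
        elif i < 2 * third:
            tiers[gid] = "medium"
        else:
            tiers[gid] = "low"
    return tiers


def anchor_position(gene: GeneRecord, anchor: str) -> tuple[str, int, str]:
    """Return (chrom, position, strand) of the gene's TSS or TTS anchor."""
    anchor = anchor.upper()
    if anchor == "TSS":
        return gene.chrom, gene.tss, gene.strand
    if anchor == "TTS":
        return gene.chrom, gene.tts, gene.strand
    raise ValueError(f"anchor must be 'TSS' or 'TTS', got {anchor!r}")


def write_gene_table(
    genes: GeneSet,
    path: str | Path,
    length_classes: Mapping[str, str] | None = None,
    expression_tiers: Mapping[str, str] | None = None,
) -> None:
    """Write a TSV of per-gene coordinates and class labels."""
    length_classes = length_classes or {}
    expression_tiers = expression_tiers or {}
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstart\tend\tstrand\tlength\tlength_class\texpression_tier\n"
        )
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.length}\t{length_classes.get(g.gene_id, 'NA')}\t"
                f"{expression_tiers.get(g.gene_id, 'NA')}\n"
            )


def write_genes_bed(genes: GeneSet, path: str | Path) -> None:
    """Write the gene set as BED6."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
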