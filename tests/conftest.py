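import numpy as np
import pandas as pd
import pytest

from occumap.annotation import GeneRecord, GeneSet
from occumap.coverage import ReadSet


@pytest.fixture
def toy_sizes():
    return {"chrA": 10_000, "chrB": 6_000}


@pytest.fixture
def toy_genes():
    return GeneSet(
        [
            GeneRecord("gene1", "chrA", 1000, 2000, "+"),
            GeneRecord("gene2", "chrA", 3000, 5400, "-"),
            GeneRecord("gene3", "chrA", 6000, 6500, "+"),
            GeneRecord("gene4", "chrB", 500, 3700, "-"),
            GeneRecord("gene5", "chrB", 4000, 5800, "+"),
        ]
    )


def make_readset(rows, spikein=0, sample_id="toy", **kw):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return ReadSet(
        sample_id=sample_id,
        reads=df,
        spikein_reads=spikein,
        experiment_reads=len(df),
        **kw,
    )


def random_readset(rng, chrom_sizes, n_reads, read_len=51, spikein=0, sample_id="rand"):
    chroms = list(chrom_sizes)
    lens = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n_reads, p=lens / lens.sum())
    starts = rng.integers(0, (lens[which] - read_len).astype(int))
    rows = [
        (chroms[w], int(s), int(s) + read_len, "+" if rng.random() < 0.5 else "-")
        for w, s in zip(which, starts)
    ]
    return make_readset(rows, spikein=spikein, sample_id=sample_id)


# ---------------------------------------------------------------- oracles


def pileup_oracle(readset, chrom_sizes):
    """O(reads x length) per-base counting."""
    out = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    for chrom, start, end, _strand in readset.reads.itertuples(index=False):
        for p in range(max(0, start), min(chrom_sizes[chrom], end)):
            out[chrom][p] += 1
    return out


def anchor_matrix_oracle(track, genes, anchor, flank_up, flank_down, bin_size):
    """Per-base strand-aware window means, computed positionwise."""
    n_bins = (flank_up + flank_down) // bin_size
    mat = np.full((len(genes), n_bins), np.nan)
    for gi, g in enumerate(genes):
        arr = track.data[g.chrom]
        apos = g.tss if anchor == "TSS" else g.tts
        for b in range(n_bins):
            vals = []
            for j in range(bin_size):
                x = -flank_up + b * bin_size + j
                p = apos + x if g.strand == "+" else apos - 1 - x
                if 0 <= p < len(arr):
                    vals.append(float(arr[p]))
            if vals:
                mat[gi, b] = sum(vals) / len(vals)
    return mat


def window_rpkm_oracle(readset, genes, w):
    """Per-read interval-overlap counting."""
    out = {}
    for g in genes:
        apos = g.tss if w.anchor == "TSS" else g.tts
        if g.strand == "+":
            ws, we = apos - w.upstream, apos + w.downstream
        else:
            ws, we = apos - w.downstream, apos + w.upstream
        count = 0
        for chrom, start, end, _ in readset.reads.itertuples(index=False):
            if chrom == g.chrom and start < we and end > ws:
                count += 1
        out[g.gene_id] = (
            count / (w.length / 1000.0) / (readset.experiment_reads / 1e6)
        )
    return out
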