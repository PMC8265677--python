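"""Metagene / TSS composite profiles, the 6mA-amount statistic, gene set
definitions, and the amount-change vs expression-change correlation.

The "6mA amount" of a region is the sum of methylated fractions over its
sites — a site count weighted by methylation level — so it is bounded by
the site count and grows with both density and level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneModel

EXPRESSION_COLUMNS = ["gene_id", "counts_veg", "counts_s24", "log2fc", "padj", "fpkm_flag"]


@dataclass
class CompositeProfile:
    """A normalized positional density; ``positions`` are bin left edges
    (scaled gene-body units or bp relative to the TSS)."""

    positions: np.ndarray
    density: np.ndarray
    kind: str
    n_genes: int = 0
    n_sites: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "density": self.density})


def _gene_window(gene: GeneModel, rel_start: int, rel_end: int) -> tuple[int, int]:
    """Genomic half-open interval for a strand-aware window relative to TSS.

    Relative coordinate r covers the base r steps downstream of the TSS in
    the gene's reading direction; [0, w) is the first w transcribed bases.
    """
    if gene.strand == "+":
        return gene.tss + rel_start, gene.tss + rel_end
    return gene.tss - rel_end + 1, gene.tss - rel_start + 1


def amount_in_window(classified: pd.DataFrame, gene: GeneModel,
                     window: tuple[int, int] = (0, 1000)) -> float:
    """Sum of methylated fractions over both strands in a TSS-relative window.

    Windows running off a chromosome end are truncated, not dropped.
    """
    lo, hi = _gene_window(gene, *window)
    sub = classified[classified["chrom"] == gene.chrom]
    pos = sub["pos"].to_numpy()
    mask = (pos >= lo) & (pos < hi)
    return float(sub["frac"].to_numpy()[mask].sum())


def amounts_for_genes(classified: pd.DataFrame, genes: list[GeneModel],
                      window: tuple[int, int] = (0, 1000)) -> pd.Series:
    """Vectorized ``amount_in_window`` over many genes (gene_id -> amount)."""
    by_chrom = {}
    for chrom, grp in classified.groupby("chrom", sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        pos = grp["pos"].to_numpy()[order]
        cum = np.concatenate([[0.0], np.cumsum(grp["frac"].to_numpy()[order])])
        by_chrom[chrom] = (pos, cum)
    out = {}
    for gene in genes:
        if gene.chrom not in by_chrom:
            out[gene.gene_id] = 0.0
            continue
        pos, cum = by_chrom[gene.chrom]
        lo, hi = _gene_window(gene, *window)
        i, j = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "left")
        out[gene.gene_id] = float(cum[j] - cum[i])
    return pd.Series(out, name="amount")


def metagene_profile(classified: pd.DataFrame, genes: list[GeneModel],
                     min_len: int = 1000, bin: float = 0.05) -> CompositeProfile:
    """Amount-weighted 6mA density over scaled gene bodies with unit flanks.

    Genes longer than ``min_len`` are scaled to unit length and extended by
    one unit on each side; each site maps to (pos - start)/length on the +
    strand and the mirror on the - strand, binned at ``bin`` over [-1, 2).
    Density is the per-bin amount over the total amount, so it sums to 1.
    """
    kept = [g for g in genes if g.length > min_len]
    if not kept:
        raise ValueError(f"no genes longer than {min_len} bp")
    edges = np.round(np.arange(-1.0, 2.0 + 1e-9, bin), 10)
    acc = np.zeros(len(edges) - 1)
    n_sites = 0
    by_chrom = {}
    for chrom, grp in classified.groupby("chrom", sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        by_chrom[chrom] = (grp["pos"].to_numpy()[order], grp["frac"].to_numpy()[order])
    for gene in kept:
        if gene.chrom not in by_chrom:
            continue
        pos, frac = by_chrom[gene.chrom]
        lo, hi = gene.start - gene.length, gene.end + gene.length
        i, j = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "left")
        p, f = pos[i:j], frac[i:j]
        if gene.strand == "+":
            scaled = (p - gene.start) / gene.length
        else:
            scaled = (gene.end - 1 - p) / gene.length
        idx = np.clip(((scaled + 1.0) / bin).astype(int), 0, len(acc) - 1)
        np.add.at(acc, idx, f)
        n_sites += len(p)
    total = acc.sum()
    if total == 0:
        raise ValueError("no 6mA amount within any scaled gene window")
    return CompositeProfile(edges[:-1], acc / total, "metagene", len(kept), n_sites)


def tss_profile(classified: pd.DataFrame, genes: list[GeneModel],
                window: tuple[int, int] = (-1000, 2000)) -> CompositeProfile:
    """Per-base amount-weighted 6mA density around the TSS (strand-oriented)."""
    if len(classified) == 0:
        raise ValueError("empty call set")
    lo, hi = window
    acc = np.zeros(hi - lo)
    n_sites = 0
    by_chrom = {}
    for chrom, grp in classified.groupby("chrom", sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        by_chrom[chrom] = (grp["pos"].to_numpy()[order], grp["frac"].to_numpy()[order])
    for gene in genes:
        if gene.chrom not in by_chrom:
            continue
        pos, frac = by_chrom[gene.chrom]
        glo, ghi = _gene_window(gene, lo, hi)
        i, j = np.searchsorted(pos, glo, "left"), np.searchsorted(pos, ghi, "left")
        p, f = pos[i:j], frac[i:j]
        rel = (p - gene.tss) if gene.strand == "+" else (gene.tss - p)
        np.add.at(acc, rel - lo, f)
        n_sites += len(p)
    total = acc.sum()
    if total == 0:
        raise ValueError("no 6mA amount within any TSS window")
    return CompositeProfile(np.arange(lo, hi), acc / total, "tss", len(genes), n_sites)


def read_expression_table(path) -> pd.DataFrame:
    """Expression TSV: gene_id, counts_veg, counts_s24, log2fc, padj, fpkm_flag."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns {missing}")
    return df


def classify_gene_sets(records: pd.DataFrame, padj_max: float = 0.05,
                       lfc_cut: float = 2.0,
                       induced_gates: tuple[int, int] = (300, 1500),
                       top_frac: float = 0.10,
                       require_expressed: bool = True) -> dict[str, set]:
    """Differential / starvation-responding / highly-regulated gene sets.

    DEGs: padj < 0.05 and |log2fc| > 2 (strict). Starvation-induced:
    counts Veg < 300 and S24 > 1,500; repressed: the reverse gates.
    Highly regulated: the top 10% of |log2fc|, by default among expressed
    genes (fpkm_flag), else among all records.
    """
    for col in ("counts_veg", "counts_s24", "log2fc", "padj"):
        bad = records[records[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col} for gene {bad['gene_id'].iloc[0]!r}")
    lo, hi = induced_gates
    sig = records["padj"] < padj_max
    pool = records[records["fpkm_flag"].astype(bool)] if require_expressed else records
    n_top = max(1, int(np.floor(top_frac * len(pool)))) if len(pool) else 0
    top = pool.reindex(pool["log2fc"].abs().sort_values(ascending=False).index).head(n_top)
    return {
        "DEG_up": set(records.loc[sig & (records["log2fc"] > lfc_cut), "gene_id"]),
        "DEG_down": set(records.loc[sig & (records["log2fc"] < -lfc_cut), "gene_id"]),
        "induced": set(records.loc[(records["counts_veg"] < lo) & (records["counts_s24"] > hi), "gene_id"]),
        "repressed": set(records.loc[(records["counts_veg"] > hi) & (records["counts_s24"] < lo), "gene_id"]),
        "highly_regulated": set(top["gene_id"]),
    }


def amount_expression_correlation(records: pd.DataFrame, gene_set: set | None = None
                                  ) -> tuple[float, float, int]:
    """Pearson r between raw 6mA amount change and log2 fold change.

    ``records`` must carry ``amount_veg`` and ``amount_s24`` (per analysis
    window, typically [TSS, TSS+1 kb)); the change is S24 - Veg, unscaled.
    Returns (r, two-sided p, n).
    """
    sub = records if gene_set is None else records[records["gene_id"].isin(gene_set)]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need at least 3 genes for a correlation, got {n}")
    x = (sub["amount_s24"] - sub["amount_veg"]).to_numpy(dtype=float)
    y = sub["log2fc"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in amount change or expression change")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
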