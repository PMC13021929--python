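"""Fusion-protein target classification and gene annotation.

A knockdown differential-expression table (gene, log2 fold change of
silenced vs. control, adjusted p) is turned into *induced* and *repressed*
target sets: a gene the fusion protein induces goes **down** when the driver
is silenced, so induced targets have log2FC <= -cut, repressed targets
>= +cut, both at padj < cut. Elements and peaks are annotated to the gene
with the nearest TSS, and the transcriptome is partitioned into gene-length
tertiles for the processivity analyses.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

TARGET_CLASSES = ("induced", "repressed", "neither")
TERTILE_CLASSES = ("small", "medium", "large")


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware TSS/TES accessors."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.interval.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def genes_from_bed(df: pd.DataFrame) -> list[GeneModel]:
    """BED6 DataFrame (name column = gene_id) -> gene models."""
    return [
        GeneModel(str(r.name), GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand))
        for r in df.itertuples(index=False)
    ]


@dataclass
class SizeTertiles:
    """Gene-length tertile partition with the boundaries it used."""

    classes: pd.Series  # gene_id -> small/medium/large
    boundaries: tuple[float, float]


def classify_targets(
    de: pd.DataFrame, lfc_cut: float = 1.0, padj_cut: float = 0.01
) -> pd.DataFrame:
    """Classify genes as induced / repressed / neither from a knockdown DE table.

    Parameters
    ----------
    de : DataFrame
        Columns ``gene_id``, ``log2FoldChange`` (silenced vs. control),
        ``padj``. One record per gene; duplicates are rejected.

    Returns
    -------
    DataFrame with columns ``gene_id``, ``target_class``.
    """
    required = {"gene_id", "log2FoldChange", "padj"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    dup = de["gene_id"][de["gene_id"].duplicated()].unique()
    if dup.size:
        raise ValueError(f"duplicate gene_id records: {sorted(dup)[:10]}")
    bad = de.loc[
        de["padj"].isna()
        | (de["padj"] < 0)
        | (de["padj"] > 1)
        | de["log2FoldChange"].isna(),
        "gene_id",
    ]
    if len(bad):
        raise ValueError(
            f"invalid padj/log2FoldChange for gene_id: {sorted(bad)[:10]}"
        )
    lfc = de["log2FoldChange"].to_numpy(dtype=float)
    padj = de["padj"].to_numpy(dtype=float)
    cls = np.full(len(de), "neither", dtype=object)
    cls[(lfc <= -lfc_cut) & (padj < padj_cut)] = "induced"
    cls[(lfc >= lfc_cut) & (padj < padj_cut)] = "repressed"
    return pd.DataFrame({"gene_id": de["gene_id"].to_numpy(), "target_class": cls})


def annotate_nearest_gene(
    sites: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[str]:
    """Assign each site to the gene whose TSS is nearest to the site midpoint.

    Distance is the unsigned midpoint-to-TSS distance on the same chromosome;
    ties are broken by the lexicographically smaller gene_id.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for entries in by_chrom.values():
        entries.sort()

    assigned: list[str] = []
    for site in sites:
        entries = by_chrom.get(site.chrom)
        if not entries:
            raise ValueError(f"no genes on chromosome {site.chrom}")
        mid = site.midpoint
        tss_vals = [t for t, _ in entries]
        idx = bisect_left(tss_vals, mid)
        cands = [entries[j] for j in (idx - 1, idx) if 0 <= j < len(entries)]
        dmin = min(abs(t - mid) for t, _ in cands)
        # sweep outwards to capture every TSS at the minimal distance
        best: list[str] = []
        j = idx - 1
        while j >= 0 and mid - tss_vals[j] <= dmin:
            if abs(tss_vals[j] - mid) == dmin:
                best.append(entries[j][1])
            j -= 1
        j = idx
        while j < len(entries) and tss_vals[j] - mid <= dmin:
            if abs(tss_vals[j] - mid) == dmin:
                best.append(entries[j][1])
            j += 1
        assigned.append(min(best))
    return assigned


def partition_by_length_tertiles(genes: Sequence[GeneModel]) -> SizeTertiles:
    """Partition genes into length tertiles at the empirical 1/3 and 2/3 quantiles.

    Uses linear-interpolation (type-7) quantiles. A gene is ``small`` when
    length < b1, ``large`` when length >= b2, ``medium`` otherwise.
    """
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to form tertiles")
    lengths = np.array([g.length for g in genes], dtype=float)
    b1, b2 = np.quantile(lengths, [1 / 3, 2 / 3], method="linear")
    cls = np.full(len(genes), "medium", dtype=object)
    cls[lengths < b1] = "small"
    cls[lengths >= b2] = "large"
    series = pd.Series(cls, index=[g.gene_id for g in genes], name="tertile")
    series.index.name = "gene_id"
    return SizeTertiles(classes=series, boundaries=(float(b1), float(b2)))
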