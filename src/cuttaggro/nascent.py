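"""Nascent-transcription (GRO-seq) quantitation.

Reads are represented by their 5'-end positions (1 bp, stranded). Gene-level
quantitation is sense-strand only and uses three windows that tile
``[TSS-300, TES+300)`` in transcription order:

* TSS window  ``[TSS-300, TSS+30)``  -- promoter-proximal / initiation signal
* gene body   ``[TSS+30, TES-30)``   -- elongating polymerase
* TES window  ``[TES-30, TES+300)``  -- signal that survived to the gene end

The elongation (processivity) index of a gene is
``EI = log2((TES_CPM + psi) / (TSS_CPM + psi))`` per condition, and
``delta_EI = EI_treated - EI_control``: a drug that only changes initiation
leaves delta_EI at 0, while impaired processivity makes it negative,
increasingly so for longer genes. Scale-regions metagene matrices
(log2 treated/control per bin, gene bodies resampled to a fixed number of
columns) expose the same contrast as profile shape: flat for
initiation-only perturbations, downward-sloping for attrition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as ctg_io
from .intervals import GenomicInterval
from .stats import wilcoxon_rank_sum
from .targets import GeneModel

logger = logging.getLogger(__name__)

TSS_UPSTREAM = 300  # bp upstream of the TSS in the TSS window
TSS_INTO_GENE = 30  # bp of gene body included in the TSS window
TES_INTO_GENE = 30
TES_DOWNSTREAM = 300
MIN_GENE_LENGTH = TSS_INTO_GENE + TES_INTO_GENE  # body would be empty below this


@dataclass
class StrandedReadSet:
    """5'-end read positions for one sample.

    ``positions`` maps (chrom, strand) -> sorted int64 positions.
    """

    sample_id: str
    condition: str
    replicate: int
    positions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    library_size: int = 0

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        condition: str,
        replicate: int,
        chroms: np.ndarray,
        pos: np.ndarray,
        strands: np.ndarray,
    ) -> "StrandedReadSet":
        positions: dict[tuple[str, str], np.ndarray] = {}
        for chrom in np.unique(chroms):
            for strand in ("+", "-"):
                sel = (chroms == chrom) & (strands == strand)
                if sel.any():
                    positions[(str(chrom), strand)] = np.sort(pos[sel].astype(np.int64))
        return cls(sample_id, condition, replicate, positions, int(pos.size))

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for (chrom, strand) in sorted(self.positions):
            for p in self.positions[(chrom, strand)]:
                rows.append((chrom, int(p), int(p) + 1, self.sample_id, 0, strand))
        rows.sort(key=lambda r: (r[0], r[1], r[5]))
        return pd.DataFrame(rows, columns=ctg_io.BED6_COLUMNS)


def load_reads(
    path: str | Path, sample_id: str, condition: str = "control", replicate: int = 1
) -> StrandedReadSet:
    """Load 5'-end positions from a BED6 file (the interval start is the 5' end)."""
    bed = ctg_io.read_bed6(path)
    if (bed["strand"] == ".").any():
        raise ValueError(f"{path}: GRO-seq reads must be stranded")
    return StrandedReadSet.from_arrays(
        sample_id,
        condition,
        replicate,
        bed["chrom"].to_numpy(),
        bed["start"].to_numpy(np.int64),
        bed["strand"].to_numpy(),
    )


@dataclass(frozen=True)
class GeneWindows:
    """TSS / body / TES windows for a gene, in genome coordinates."""

    gene_id: str
    chrom: str
    strand: str
    tss_win: GenomicInterval
    body_win: GenomicInterval
    tes_win: GenomicInterval


def gene_windows(gene: GeneModel) -> GeneWindows:
    """Window layout around a gene; raises for genes too short to have a body."""
    if gene.length <= MIN_GENE_LENGTH:
        raise ValueError(
            f"gene {gene.gene_id}: length {gene.length} <= {MIN_GENE_LENGTH}, body empty"
        )
    iv = gene.interval
    if gene.strand == "+":
        tss_win = (iv.start - TSS_UPSTREAM, iv.start + TSS_INTO_GENE)
        body = (iv.start + TSS_INTO_GENE, iv.end - TES_INTO_GENE)
        tes_win = (iv.end - TES_INTO_GENE, iv.end + TES_DOWNSTREAM)
    else:
        tss_win = (iv.end - TSS_INTO_GENE, iv.end + TSS_UPSTREAM)
        body = (iv.start + TES_INTO_GENE, iv.end - TSS_INTO_GENE)
        tes_win = (iv.start - TES_DOWNSTREAM, iv.start + TES_INTO_GENE)

    def _mk(bounds: tuple[int, int]) -> GenomicInterval:
        start, end = max(0, bounds[0]), bounds[1]
        return GenomicInterval(iv.chrom, start, end, gene.strand)

    return GeneWindows(gene.gene_id, iv.chrom, gene.strand, _mk(tss_win), _mk(body), _mk(tes_win))


def windows_for_genes(genes: Sequence[GeneModel]) -> list[GeneWindows]:
    """Windows for every gene long enough to have one; short genes are skipped."""
    out = []
    for g in genes:
        try:
            out.append(gene_windows(g))
        except ValueError as exc:
            logger.warning("skipping gene: %s", exc)
    return out


def _count_in(reads: StrandedReadSet, chrom: str, strand: str, start: int, end: int) -> int:
    pos = reads.positions.get((chrom, strand))
    if pos is None:
        return 0
    return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


def count_window_reads(
    reads: StrandedReadSet, windows: Sequence[GeneWindows]
) -> pd.DataFrame:
    """Sense-strand 5'-end counts (and CPMs) per gene window for one sample."""
    rows = []
    scale = 1e6 / reads.library_size if reads.library_size else 0.0
    for w in windows:
        tss = _count_in(reads, w.chrom, w.strand, w.tss_win.start, w.tss_win.end)
        body = _count_in(reads, w.chrom, w.strand, w.body_win.start, w.body_win.end)
        tes = _count_in(reads, w.chrom, w.strand, w.tes_win.start, w.tes_win.end)
        rows.append((w.gene_id, tss, body, tes, tss * scale, body * scale, tes * scale))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "tss", "body", "tes", "tss_cpm", "body_cpm", "tes_cpm"],
    )
    return df.set_index("gene_id")


def pooled_window_counts(
    read_sets: Sequence[StrandedReadSet], windows: Sequence[GeneWindows]
) -> pd.DataFrame:
    """Replicates pooled by summed counts; CPM on the summed library size."""
    total_lib = sum(rs.library_size for rs in read_sets)
    counts = None
    for rs in read_sets:
        df = count_window_reads(rs, windows)[["tss", "body", "tes"]]
        counts = df if counts is None else counts + df
    if counts is None:
        raise ValueError("need at least one read set")
    scale = 1e6 / total_lib if total_lib else 0.0
    for col in ("tss", "body", "tes"):
        counts[f"{col}_cpm"] = counts[col] * scale
    return counts


def elongation_index(
    control: pd.DataFrame, treated: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene elongation index and its treated-minus-control change.

    Inputs are pooled window-count tables (``pooled_window_counts``) indexed
    by gene_id; genes missing from either condition are skipped with a
    warning.
    """
    common = control.index.intersection(treated.index)
    missing = control.index.symmetric_difference(treated.index)
    if len(missing):
        logger.warning("elongation_index: skipping %d genes missing a condition", len(missing))
    c = control.loc[common]
    t = treated.loc[common]
    ei_c = np.log2((c["tes_cpm"] + pseudocount) / (c["tss_cpm"] + pseudocount))
    ei_t = np.log2((t["tes_cpm"] + pseudocount) / (t["tss_cpm"] + pseudocount))
    return pd.DataFrame(
        {"ei_control": ei_c, "ei_treated": ei_t, "delta_ei": ei_t - ei_c}, index=common
    )


def coverage_track(
    read_sets: Sequence[StrandedReadSet],
    chrom_sizes: Mapping[str, int],
    bin_width: int = 50,
) -> dict[str, np.ndarray]:
    """Pooled (both-strand) binned CPM coverage; last partial bin keeps its true width."""
    total_lib = sum(rs.library_size for rs in read_sets)
    scale = 1e6 / total_lib if total_lib else 0.0
    tracks: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n_bins = (size + bin_width - 1) // bin_width
        counts = np.zeros(n_bins, dtype=float)
        for rs in read_sets:
            for strand in ("+", "-"):
                pos = rs.positions.get((chrom, strand))
                if pos is not None:
                    counts += np.bincount(pos // bin_width, minlength=n_bins)[:n_bins]
        tracks[chrom] = counts * scale
    return tracks


def log2fc_track(
    treated: Mapping[str, np.ndarray],
    control: Mapping[str, np.ndarray],
    pseudocount: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-bin log2((treated_cpm + psi) / (control_cpm + psi)) of two tracks."""
    out = {}
    for chrom in control:
        t, c = treated[chrom], control[chrom]
        if t.shape != c.shape:
            raise ValueError(f"{chrom}: treated and control tracks have different bins")
        out[chrom] = np.log2((t + pseudocount) / (c + pseudocount))
    return out


def group_scale(
    tracks: Mapping[str, Mapping[str, np.ndarray]], control: str
) -> dict[str, dict[str, np.ndarray]]:
    """Scale every track in the group to the highest peak of the control track."""
    ctrl_max = max(float(arr.max()) for arr in tracks[control].values() if arr.size)
    if ctrl_max <= 0:
        raise ValueError("control track has no positive signal")
    return {
        name: {chrom: arr / ctrl_max for chrom, arr in track.items()}
        for name, track in tracks.items()
    }


@dataclass
class MetageneResult:
    """Scale-regions (or reference-point) metagene log2-ratio matrix.

    ``matrix`` is genes x columns in transcription orientation; ``profile``
    the column mean; ``body_cols`` the slice of columns covering the gene
    body (empty in reference-point mode).
    """

    matrix: np.ndarray
    profile: np.ndarray
    gene_ids: list[str]
    n_flank_bins: int
    body_bins: int

    @property
    def body_cols(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.body_bins)

    def body_slope(self) -> float:
        """Least-squares slope of the mean profile across the gene body,
        per unit of scaled body position (0 at TSS, 1 at TES)."""
        y = self.profile[self.body_cols]
        x = (np.arange(y.size) + 0.5) / y.size
        ok = ~np.isnan(y)
        return float(np.polyfit(x[ok], y[ok], 1)[0])


def _binned_rates(
    pos: np.ndarray, edges: np.ndarray, widths: np.ndarray, scale: float
) -> np.ndarray:
    counts = np.diff(np.searchsorted(pos, edges))
    return counts / widths * scale


def _gene_column_values(
    rs_list: Sequence[StrandedReadSet],
    gene: GeneModel,
    flank: int,
    bin_width: int,
    body_bins: int,
    chrom_sizes: Mapping[str, int] | None,
) -> np.ndarray:
    """Per-column sense-strand signal for one gene, transcription orientation.

    Values are reads-per-bp rates scaled to a per-``bin_width`` CPM so that
    flank and body columns are comparable regardless of body column width.
    """
    iv = gene.interval
    n_flank = flank // bin_width
    left_edges = iv.start - flank + np.arange(n_flank + 1, dtype=float) * bin_width
    body_edges = np.linspace(iv.start, iv.end, body_bins + 1)
    right_edges = iv.end + np.arange(n_flank + 1, dtype=float) * bin_width
    edges = np.concatenate([left_edges, body_edges[1:-1], right_edges])
    widths = np.diff(edges)

    total_lib = sum(rs.library_size for rs in rs_list)
    scale = bin_width * 1e6 / total_lib if total_lib else 0.0
    pos = np.concatenate(
        [
            rs.positions.get((iv.chrom, gene.strand), np.empty(0, np.int64))
            for rs in rs_list
        ]
    )
    pos.sort()
    vals = _binned_rates(pos, edges, widths, scale)
    if chrom_sizes is not None:
        size = chrom_sizes[iv.chrom]
        invalid = (edges[:-1] < 0) | (edges[1:] > size)
        vals[invalid] = np.nan
    if gene.strand == "-":
        vals = vals[::-1]
    return vals


def scaled_metagene(
    treated: Sequence[StrandedReadSet],
    control: Sequence[StrandedReadSet],
    genes: Sequence[GeneModel],
    flank: int = 3000,
    bin_width: int = 50,
    body_bins: int = 100,
    pseudocount: float = 1.0,
    chrom_sizes: Mapping[str, int] | None = None,
) -> MetageneResult:
    """Scale-regions metagene of log2(treated/control) sense-strand signal.

    Flanks are binned at fixed ``bin_width``; each gene body is resampled to
    ``body_bins`` columns by length-weighted averaging, so every gene maps to
    the same column count. Minus-strand genes are reversed into transcription
    orientation. Replicates are pooled by summed counts.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    usable = [g for g in genes if g.length > 2 * bin_width]
    n_flank = flank // bin_width
    n_cols = 2 * n_flank + body_bins
    matrix = np.full((len(usable), n_cols), np.nan)
    for i, gene in enumerate(usable):
        v_t = _gene_column_values(treated, gene, flank, bin_width, body_bins, chrom_sizes)
        v_c = _gene_column_values(control, gene, flank, bin_width, body_bins, chrom_sizes)
        matrix[i] = np.log2((v_t + pseudocount) / (v_c + pseudocount))
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(matrix, axis=0) if usable else np.full(n_cols, np.nan)
    return MetageneResult(
        matrix=matrix,
        profile=profile,
        gene_ids=[g.gene_id for g in usable],
        n_flank_bins=n_flank,
        body_bins=body_bins,
    )


def reference_point_matrix(
    read_sets: Sequence[StrandedReadSet],
    genes: Sequence[GeneModel],
    flank: int = 3000,
    bin_width: int = 50,
    chrom_sizes: Mapping[str, int] | None = None,
) -> MetageneResult:
    """TSS-centered sense-strand CPM matrix (reference-point mode, no body scaling)."""
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width
    total_lib = sum(rs.library_size for rs in read_sets)
    scale = bin_width * 1e6 / total_lib if total_lib else 0.0
    matrix = np.full((len(genes), n_bins), np.nan)
    for i, gene in enumerate(genes):
        tss = gene.tss
        if gene.strand == "+":
            edges = tss - flank + np.arange(n_bins + 1, dtype=float) * bin_width
        else:
            edges = tss + flank - np.arange(n_bins + 1, dtype=float) * bin_width
            edges = edges[::-1]
        pos = np.concatenate(
            [
                rs.positions.get((gene.chrom, gene.strand), np.empty(0, np.int64))
                for rs in read_sets
            ]
        )
        pos.sort()
        vals = _binned_rates(pos, edges, np.diff(edges), scale / bin_width)
        vals = vals * bin_width  # back to per-bin counts scale
        if chrom_sizes is not None:
            invalid = (edges[:-1] < 0) | (edges[1:] > chrom_sizes[gene.chrom])
            vals[invalid] = np.nan
        if gene.strand == "-":
            vals = vals[::-1]
        matrix[i] = vals
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(matrix, axis=0) if len(genes) else np.full(n_bins, np.nan)
    return MetageneResult(
        matrix=matrix,
        profile=profile,
        gene_ids=[g.gene_id for g in genes],
        n_flank_bins=flank // bin_width,
        body_bins=0,
    )


def tes_group_stats(
    control: Sequence[StrandedReadSet],
    treated: Sequence[StrandedReadSet],
    windows: Sequence[GeneWindows],
    targets: pd.DataFrame,
) -> pd.DataFrame:
    """Per-target-class TES signal summary and treated-vs-control rank-sum test.

    For each class, every (gene, replicate) contributes one value of
    log10(TES CPM + 1); the two-sided Wilcoxon rank-sum test compares the
    pooled replicate-level value sets between conditions. Empty classes are
    skipped with a warning.
    """
    class_map = targets.set_index("gene_id")["target_class"]
    per_sample = {
        rs.sample_id: (rs.condition, count_window_reads(rs, windows)["tes_cpm"])
        for rs in list(control) + list(treated)
    }
    rows = []
    for cls in ("induced", "repressed", "neither"):
        genes_in_class = [
            w.gene_id for w in windows if class_map.get(w.gene_id) == cls
        ]
        if not genes_in_class:
            logger.warning("tes_group_stats: no genes in class %r", cls)
            continue
        vals: dict[str, list[float]] = {"control": [], "treated": []}
        for _, (cond, cpm) in per_sample.items():
            vals[cond].extend(np.log10(cpm.loc[genes_in_class].to_numpy() + 1.0))
        c = np.asarray(vals["control"])
        t = np.asarray(vals["treated"])
        q1c, med_c, q3c = np.percentile(c, [25, 50, 75])
        q1t, med_t, q3t = np.percentile(t, [25, 50, 75])
        rows.append(
            {
                "target_class": cls,
                "n_genes": len(genes_in_class),
                "median_control": med_c,
                "iqr_control": q3c - q1c,
                "median_treated": med_t,
                "iqr_treated": q3t - q1t,
                "p_ranksum": wilcoxon_rank_sum(t, c),
            }
        )
    return pd.DataFrame(rows)


def antisense_initiation(
    control: Sequence[StrandedReadSet],
    treated: Sequence[StrandedReadSet],
    peaks: Sequence[tuple[str, GenomicInterval, str]],
    flank: int = 1000,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Antisense 5'-end signal at peak centers, per condition, with log2 ratio.

    ``peaks`` holds (peak_id, interval, sense_strand) where sense_strand is
    the strand of the peak's annotated gene; reads on the opposite strand
    within center +/- flank are counted. Peaks with unknown sense strand are
    skipped with a warning.
    """
    lib_c = sum(rs.library_size for rs in control)
    lib_t = sum(rs.library_size for rs in treated)
    rows = []
    for peak_id, iv, sense in peaks:
        if sense not in ("+", "-"):
            logger.warning("antisense_initiation: peak %s has no annotated strand", peak_id)
            continue
        anti = "-" if sense == "+" else "+"
        center = int(iv.midpoint)
        lo, hi = center - flank, center + flank
        n_c = sum(_count_in(rs, iv.chrom, anti, lo, hi) for rs in control)
        n_t = sum(_count_in(rs, iv.chrom, anti, lo, hi) for rs in treated)
        cpm_c = n_c * 1e6 / lib_c if lib_c else 0.0
        cpm_t = n_t * 1e6 / lib_t if lib_t else 0.0
        rows.append(
            {
                "peak_id": peak_id,
                "antisense_cpm_control": cpm_c,
                "antisense_cpm_treated": cpm_t,
                "antisense_log2fc": np.log2((cpm_t + pseudocount) / (cpm_c + pseudocount)),
            }
        )
    return pd.DataFrame(rows)
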