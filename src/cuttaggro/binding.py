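"""CUT&Tag differential-binding analysis.

Fragments are unstranded intervals (one per sequenced fragment). Counting is
binary per peak: a fragment contributes 1 to every peak it overlaps by at
least 1 bp. Quantities are CPM-normalized (counts per million retained
fragments); differential binding is a per-peak Welch t-test on
log2(CPM + pseudocount) across replicates with Benjamini-Hochberg FDR over
all peaks, a transparent stand-in for affinity-model refits whose
configuration is rarely reproducible from a methods section.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as ctg_io
from .intervals import GenomicInterval, merge_intervals
from .stats import bh_fdr, spearman_matrix

logger = logging.getLogger(__name__)


@dataclass
class FragmentSet:
    """Length-filtered fragments for one sample.

    ``fragments`` maps chrom -> (starts, ends), both int64, sorted by start.
    ``library_size`` is the number of retained fragments; ``n_filtered``
    counts fragments removed by the length filter.
    """

    sample_id: str
    condition: str
    replicate: int
    fragments: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    library_size: int = 0
    n_filtered: int = 0

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        condition: str,
        replicate: int,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        max_fragment_len: int = 1000,
    ) -> "FragmentSet":
        lengths = ends - starts
        keep = lengths < max_fragment_len
        n_filtered = int((~keep).sum())
        chroms, starts, ends = chroms[keep], starts[keep], ends[keep]
        frag: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            s, e = starts[sel].astype(np.int64), ends[sel].astype(np.int64)
            order = np.argsort(s, kind="mergesort")
            frag[str(chrom)] = (s[order], e[order])
        return cls(
            sample_id=sample_id,
            condition=condition,
            replicate=replicate,
            fragments=frag,
            library_size=int(keep.sum()),
            n_filtered=n_filtered,
        )

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.fragments):
            s, e = self.fragments[chrom]
            for a, b in zip(s, e):
                rows.append((chrom, int(a), int(b), self.sample_id, 0, "."))
        return pd.DataFrame(rows, columns=ctg_io.BED6_COLUMNS)


def load_fragments(
    path: str | Path,
    sample_id: str,
    condition: str = "control",
    replicate: int = 1,
    max_fragment_len: int = 1000,
) -> FragmentSet:
    """Load a BED of fragments, dropping fragments >= ``max_fragment_len`` bp."""
    bed = ctg_io.read_bed6(path)
    fs = FragmentSet.from_arrays(
        sample_id,
        condition,
        replicate,
        bed["chrom"].to_numpy(),
        bed["start"].to_numpy(np.int64),
        bed["end"].to_numpy(np.int64),
        max_fragment_len=max_fragment_len,
    )
    if fs.n_filtered:
        logger.info(
            "%s: removed %d fragments >= %d bp", sample_id, fs.n_filtered, max_fragment_len
        )
    return fs


@dataclass
class PeakSet:
    """Named peak intervals, sorted by (chrom, start), unique names."""

    peaks: pd.DataFrame  # columns chrom, start, end, name

    def __post_init__(self) -> None:
        df = self.peaks
        if df["name"].duplicated().any():
            raise ValueError("peak names must be unique")
        key = df[["chrom", "start"]].apply(tuple, axis=1).tolist() if len(df) else []
        if key != sorted(key):
            raise ValueError("peaks must be sorted by (chrom, start)")

    @classmethod
    def from_bed(cls, path: str | Path) -> "PeakSet":
        bed = ctg_io.read_bed6(path)
        return cls(bed[["chrom", "start", "end", "name"]].copy())

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in self.peaks.itertuples(index=False)
        ]


def _chrom_counts(
    frag: tuple[np.ndarray, np.ndarray], starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Fragments overlapping each query interval, via two sorted projections."""
    f_starts, f_ends = frag
    f_ends_sorted = np.sort(f_ends)
    began = np.searchsorted(f_starts, ends, side="left")
    done = np.searchsorted(f_ends_sorted, starts, side="right")
    return began - done


def count_fragments(
    frag_sets: Sequence[FragmentSet], peaks: PeakSet
) -> pd.DataFrame:
    """Peak x sample overlap-count table (binary per fragment-peak pair)."""
    df = peaks.peaks
    out = pd.DataFrame(index=df["name"].to_numpy())
    out.index.name = "peak_id"
    for fs in frag_sets:
        counts = np.zeros(len(df), dtype=np.int64)
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in fs.fragments:
                continue
            counts[sub.index.to_numpy()] = _chrom_counts(
                fs.fragments[chrom],
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
            )
        out[fs.sample_id] = counts
    return out


def cpm_normalize(
    counts: pd.DataFrame, library_sizes: Mapping[str, int], pseudocount: float = 0.0
) -> pd.DataFrame:
    """counts-per-million: (count + pseudocount) * 1e6 / library_size."""
    cpm = counts.astype(float).copy()
    for col in cpm.columns:
        lib = library_sizes[col]
        if lib <= 0:
            raise ValueError(f"library size for {col} must be > 0")
        cpm[col] = (cpm[col] + pseudocount) * 1e6 / lib
    return cpm


def differential_binding(
    cpm: pd.DataFrame,
    groups: Mapping[str, str],
    control: str,
    treated: str,
    pseudocount: float = 1.0,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-peak differential binding between two conditions.

    log2fc = log2((mean CPM treated + psi) / (mean CPM control + psi)); p from
    a two-sided Welch (unequal-variance) t-test on log2(CPM + psi) across
    replicates; BH-FDR over all peaks. Peaks with identical values in both
    groups get p = 1.
    """
    ctrl_cols = [s for s in cpm.columns if groups.get(s) == control]
    trt_cols = [s for s in cpm.columns if groups.get(s) == treated]
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    ctrl = cpm[ctrl_cols].to_numpy(dtype=float)
    trt = cpm[trt_cols].to_numpy(dtype=float)
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(
            np.log2(trt + pseudocount),
            np.log2(ctrl + pseudocount),
            axis=1,
            equal_var=False,
        )
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "peak_id": cpm.index.to_numpy(),
            "mean_cpm_control": mean_c,
            "mean_cpm_treated": mean_t,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "significant": fdr < fdr_cut,
        }
    )


def frip(frags: FragmentSet, peaks: PeakSet) -> float:
    """Fraction of retained fragments overlapping >= 1 peak."""
    if frags.library_size == 0:
        raise ValueError("empty fragment set")
    merged = merge_intervals(peaks.intervals())
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    for iv in merged:
        by_chrom[iv.chrom][0].append(iv.start)  # type: ignore[union-attr]
        by_chrom[iv.chrom][1].append(iv.end)  # type: ignore[union-attr]
    n_in = 0
    for chrom, (f_starts, f_ends) in frags.fragments.items():
        if chrom not in by_chrom:
            continue
        p_starts = np.asarray(by_chrom[chrom][0], dtype=np.int64)
        p_ends = np.asarray(by_chrom[chrom][1], dtype=np.int64)
        # merged peaks are disjoint and sorted: the only candidate is the last
        # peak starting before the fragment end
        idx = np.searchsorted(p_starts, f_ends, side="left") - 1
        valid = idx >= 0
        hit = np.zeros(f_starts.size, dtype=bool)
        hit[valid] = p_ends[idx[valid]] > f_starts[valid]
        n_in += int(hit.sum())
    return n_in / frags.library_size


def replicate_correlation(cpm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-peak signal between samples."""
    if cpm.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = spearman_matrix(cpm.to_numpy(dtype=float))
    return pd.DataFrame(mat, index=cpm.columns, columns=cpm.columns)


@dataclass
class MetaprofileResult:
    """Per-site binned signal around element centers.

    ``matrix`` is sites x bins (CPM fragment counts per bin, NaN where a bin
    fell off the contig); ``profile`` is the column mean over valid rows;
    ``positions`` gives each bin's center offset from the site center, in
    transcription orientation (minus-strand rows are reversed so negative
    offsets are upstream).
    """

    matrix: np.ndarray
    profile: np.ndarray
    positions: np.ndarray

    def to_frames(self, site_ids: Sequence[str] | None = None):
        idx = site_ids if site_ids is not None else range(self.matrix.shape[0])
        mat = pd.DataFrame(self.matrix, index=idx, columns=self.positions.astype(int))
        prof = pd.DataFrame({"position": self.positions.astype(int), "mean": self.profile})
        return mat, prof


def site_metaprofile(
    frags: FragmentSet,
    sites: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    flank: int = 1500,
    bin_width: int = 10,
    normalize: bool = True,
) -> MetaprofileResult:
    """Binned fragment counts on site center +/- ``flank``.

    Each bin counts the fragments overlapping it by >= 1 bp, CPM-scaled when
    ``normalize``. Minus-strand sites are reversed so the left edge of the
    profile is always upstream. Bins beyond the contig are NaN and excluded
    from the column means.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width
    offsets = np.arange(n_bins + 1) * bin_width - flank
    scale = 1e6 / frags.library_size if normalize and frags.library_size else 1.0
    matrix = np.full((len(sites), n_bins), np.nan)
    for i, site in enumerate(sites):
        center = int(site.midpoint)
        edges = center + offsets
        chrom_len = chrom_sizes[site.chrom]
        frag = frags.fragments.get(site.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        counts = _chrom_counts(frag, edges[:-1], edges[1:]).astype(float)
        invalid = (edges[:-1] < 0) | (edges[1:] > chrom_len)
        counts[invalid] = np.nan
        if site.strand == "-":
            counts = counts[::-1]
        matrix[i] = counts * scale
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(matrix, axis=0) if len(sites) else np.full(n_bins, np.nan)
    centers = (offsets[:-1] + offsets[1:]) / 2.0
    return MetaprofileResult(matrix=matrix, profile=profile, positions=centers)
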