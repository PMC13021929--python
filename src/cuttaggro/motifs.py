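"""GGAA response-element scanning and classification.

Ewing-sarcoma fusion proteins of the EWS::ETS family bind GGAA-containing
response elements. Three element architectures are distinguished here:

* **microsatellites** -- maximal runs of >= ``min_units`` consecutive GGAA
  units with no spacer, the classical enhancer-like repeat elements;
* **isolated GGAA motifs** -- single GGAA/TTCC occurrences with no other
  GGAA/TTCC within ``min_gap`` bp (nearest-edge, boundary inclusive: a gap of
  exactly ``min_gap`` still counts as isolated);
* **tandem (heterotypic) sites** -- a GGAA within ``window`` bp
  (nearest-edge) of a cofactor consensus match (AP-1, RUNX2, E2F, FLI1),
  modeling cooperative binding. One GGAA may join several cofactor classes.

All scans report both strands; ``matched_seq`` is always stored as the
plus-strand slice of the genome (its reverse complement matches the motif for
minus-strand sites). Ambiguity codes in the *sequence* never match; ambiguity
codes in a *pattern* expand to their IUPAC base sets.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, edge_gap, require_sorted

IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

GGAA = "GGAA"
TTCC = "TTCC"

#: Default cofactor consensus patterns (short IUPAC consensi; configurable).
DEFAULT_COFACTOR_PATTERNS: dict[str, str] = {
    "AP1": "TGASTCA",
    "RUNX2": "TGYGGTY",
    "E2F": "GCGSSAAA",
    "FLI1": "CCGGAAGT",
}


@dataclass(frozen=True)
class MotifSite:
    """A single motif occurrence."""

    interval: GenomicInterval
    motif_name: str
    matched_seq: str

    def __post_init__(self) -> None:
        if len(self.matched_seq) != self.interval.length:
            raise ValueError("matched_seq length must equal interval length")


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A maximal (GGAA)_k run; ``end - start == 4 * unit_count``."""

    interval: GenomicInterval
    unit_count: int

    def __post_init__(self) -> None:
        if self.interval.length != 4 * self.unit_count:
            raise ValueError("interval length must equal 4 * unit_count")


@dataclass(frozen=True)
class ResponseElement:
    """A classified GGAA-bearing element.

    ``element_class`` is one of ``microsatellite``, ``isolated_ggaa`` or
    ``tandem_ggaa_<cofactor>``; tandem classes carry the nearest qualifying
    cofactor occurrence as ``partner_site``.
    """

    site: "MotifSite | MicrosatelliteLocus"
    element_class: str
    partner_site: MotifSite | None = None
    gene_id: str | None = None

    @property
    def interval(self) -> GenomicInterval:
        return self.site.interval

    @property
    def span(self) -> GenomicInterval:
        """Interval covering the GGAA site and its partner (if any)."""
        iv = self.site.interval
        if self.partner_site is None:
            return iv
        p = self.partner_site.interval
        return GenomicInterval(iv.chrom, min(iv.start, p.start), max(iv.end, p.end))


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(IUPAC_BASES)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern:
        raise ValueError("empty motif pattern")
    bad = set(pattern) - set(IUPAC_BASES)
    if bad:
        raise ValueError(f"invalid IUPAC letters in pattern: {sorted(bad)}")
    return pattern


def reverse_complement(seq: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))


def _scan_positions(arr: np.ndarray, pattern: str) -> np.ndarray:
    """Start positions of exact IUPAC ``pattern`` matches on the given byte array.

    Sequence ambiguity codes never match: only concrete A/C/G/T letters can
    satisfy a pattern position.
    """
    k = len(pattern)
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    for i, ch in enumerate(pattern):
        allowed = np.frombuffer(IUPAC_BASES[ch].encode(), dtype=np.uint8)
        mask &= np.isin(arr[i : i + n], allowed)
    return np.flatnonzero(mask).astype(np.int64)


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def scan_ggaa(seq: str, chrom: str) -> list[MotifSite]:
    """All GGAA (+ strand) and TTCC (- strand) occurrences, overlapping included.

    Returns sites sorted by start. Occurrences containing ambiguity codes
    (including N) are never reported.
    """
    seq = _validate_seq(seq)
    arr = seq_to_array(seq)
    sites = [
        MotifSite(GenomicInterval(chrom, int(p), int(p) + 4, "+"), "GGAA", seq[p : p + 4])
        for p in _scan_positions(arr, GGAA)
    ] + [
        MotifSite(GenomicInterval(chrom, int(p), int(p) + 4, "-"), "GGAA", seq[p : p + 4])
        for p in _scan_positions(arr, TTCC)
    ]
    sites.sort(key=lambda s: s.interval.start)
    return sites


def find_microsatellites(
    seq: str, chrom: str, min_units: int = 4
) -> list[MicrosatelliteLocus]:
    """Maximal zero-spacer (GGAA)_k runs with ``k >= min_units``, both strands.

    Plus-strand GGAA runs and minus-strand runs (TTCC on the reference) are
    scanned separately and deduplicated by interval.
    """
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    seq = _validate_seq(seq)
    arr = seq_to_array(seq)
    loci: dict[tuple[int, int], MicrosatelliteLocus] = {}
    for unit, strand in ((GGAA, "+"), (TTCC, "-")):
        starts = set(int(p) for p in _scan_positions(arr, unit))
        for s in sorted(starts):
            if s - 4 in starts:
                continue  # not a run start
            k = 1
            while s + 4 * k in starts:
                k += 1
            if k >= min_units:
                iv = GenomicInterval(chrom, s, s + 4 * k, strand)
                loci.setdefault((s, s + 4 * k), MicrosatelliteLocus(iv, k))
    return [loci[key] for key in sorted(loci)]


def find_isolated_ggaa(
    sites: Sequence[MotifSite], min_gap: int = 20
) -> list[MotifSite]:
    """Sites whose nearest-edge gap to every *other* GGAA/TTCC site is >= ``min_gap``.

    A gap of exactly ``min_gap`` qualifies as isolated (boundary inclusive);
    overlapping sites are never isolated. Input must be sorted by
    (chrom, start).
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    ivs = [s.interval for s in sites]
    require_sorted(ivs, "sites")
    if not sites:
        return []
    max_len = max(iv.length for iv in ivs)
    isolated: list[MotifSite] = []
    n = len(sites)
    for i, site in enumerate(sites):
        iv = site.interval
        ok = True
        # left neighbors: with sorted starts, a left site j can violate only if
        # start_i - start_j < min_gap + max_len
        j = i - 1
        while j >= 0 and ivs[j].chrom == iv.chrom and iv.start - ivs[j].start < min_gap + max_len:
            if iv.start - ivs[j].end < min_gap:
                ok = False
                break
            j -= 1
        if ok:
            j = i + 1
            while j < n and ivs[j].chrom == iv.chrom and ivs[j].start - iv.start < min_gap + max_len:
                if ivs[j].start - iv.end < min_gap:
                    ok = False
                    break
                j += 1
        if ok:
            isolated.append(site)
    return isolated


def scan_cofactor_motifs(
    seq: str,
    chrom: str,
    patterns: Mapping[str, str] | None = None,
) -> list[MotifSite]:
    """Both-strand exact IUPAC matches for each named cofactor pattern.

    Palindromic matches (same interval on both strands) are reported once, on
    the plus strand. Result is sorted by (start, motif_name).
    """
    if patterns is None:
        patterns = DEFAULT_COFACTOR_PATTERNS
    seq = _validate_seq(seq)
    arr = seq_to_array(seq)
    sites: list[MotifSite] = []
    for name, pattern in patterns.items():
        pattern = _validate_pattern(pattern)
        k = len(pattern)
        fwd = set(int(p) for p in _scan_positions(arr, pattern))
        rev = set(int(p) for p in _scan_positions(arr, reverse_complement(pattern)))
        for p in sorted(fwd | rev):
            strand = "+" if p in fwd else "-"
            sites.append(
                MotifSite(GenomicInterval(chrom, p, p + k, strand), name, seq[p : p + k])
            )
    sites.sort(key=lambda s: (s.interval.start, s.motif_name))
    return sites


def classify_tandem_sites(
    ggaa: Sequence[MotifSite],
    cofactors: Sequence[MotifSite],
    window: int = 200,
) -> list[ResponseElement]:
    """Pair GGAA sites with nearby cofactor motifs into tandem elements.

    For each GGAA site and each cofactor class present in ``cofactors``, emits
    a ``tandem_ggaa_<class>`` element when the nearest-edge distance to some
    cofactor occurrence of that class is <= ``window``. The partner is the
    nearest qualifying occurrence (ties resolved to the smaller start). A
    single GGAA may yield one element per co-located cofactor class.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    require_sorted([s.interval for s in ggaa], "ggaa")
    require_sorted([s.interval for s in cofactors], "cofactors")

    by_class: dict[str, dict[str, list[MotifSite]]] = {}
    for c in cofactors:
        by_class.setdefault(c.motif_name, {}).setdefault(c.interval.chrom, []).append(c)

    elements: list[ResponseElement] = []
    for g in ggaa:
        giv = g.interval
        for name in sorted(by_class):
            chrom_sites = by_class[name].get(giv.chrom)
            if not chrom_sites:
                continue
            max_len = max(c.interval.length for c in chrom_sites)
            starts = [c.interval.start for c in chrom_sites]
            lo = bisect_left(starts, giv.start - window - max_len)
            hi = bisect_left(starts, giv.end + window + 1)
            best: MotifSite | None = None
            best_d = window + 1
            for c in chrom_sites[lo:hi]:
                d = edge_gap(giv, c.interval)
                if d < best_d or (d == best_d and best is not None and c.interval.start < best.interval.start):
                    best, best_d = c, d
            if best is not None and best_d <= window:
                elements.append(
                    ResponseElement(g, f"tandem_ggaa_{name.lower()}", partner_site=best)
                )
    return elements
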