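"""Synthetic genome, GRO-seq and CUT&Tag simulator with planted truth.

The generator emulates the structure of a drug-exposure study in a
GGAA-driven fusion-protein cell model:

* a random genome with genes planted in three length tertiles and three
  classes of GGAA response elements (microsatellites, isolated GGAAs with
  clean flanks, tandem GGAA+cofactor pairs);
* stranded GRO-seq 5'-end reads under an initiation x attrition model: the
  expected sense signal at distance ``d`` kb from the TSS of gene ``g`` in
  condition ``c`` is ``lambda_{g,c} * exp(-kappa_{g,c} * d)``, with a
  promoter-proximal pause boost over the first 300 bp and a short run-through
  past the TES; replicate counts are negative-binomial;
* CUT&Tag fragment pileups at planted elements under an occupancy model
  (expected fragments per element per replicate, NB-realized, Gaussian
  spread around the element center) over a uniform background, with true
  peaks emitted at element centers +/- 250 bp;
* a knockdown differential-expression table with planted induced/repressed
  targets, and truth tables for parameter-recovery tests.

Two exposure presets mirror the contrast the pipeline is built to detect:
``lce`` (low-concentration continuous) perturbs initiation only, ``hce``
(high-concentration intermittent) adds genome-wide attrition (reduced
processivity) on top of milder initiation effects.

Every output is deterministic under (config, preset): a single
``numpy.random.default_rng(seed)`` drives all sampling in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import io as ctg_io
from .binding import FragmentSet, PeakSet
from .intervals import GenomicInterval
from .nascent import StrandedReadSet
from .targets import GeneModel, annotate_nearest_gene

BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C = ord("C")
GGAA_BYTES = np.frombuffer(b"GGAA", dtype=np.uint8)
TTCC_BYTES = np.frombuffer(b"TTCC", dtype=np.uint8)

#: Concrete instances of the default cofactor consensi written into the genome.
COFACTOR_INSTANCES: dict[str, str] = {
    "AP1": "TGACTCA",
    "RUNX2": "TGTGGTT",
    "E2F": "GCGCCAAA",
    "FLI1": "CCGGAAGT",
}


@dataclass(frozen=True)
class GroEffects:
    """Per-preset perturbation of the initiation x attrition model."""

    name: str
    lambda_log2fc_induced: float = 0.0
    lambda_log2fc_repressed: float = 0.0
    lambda_log2fc_global: float = 0.0
    dkappa_per_kb: float = 0.0


PRESETS: dict[str, GroEffects] = {
    "null": GroEffects("null"),
    # initiation-only: induced targets lose, repressed targets gain initiation
    "lce": GroEffects("lce", -1.5, 1.5, 0.0, 0.0),
    # attrition genome-wide plus milder initiation effects and mild global induction
    "hce": GroEffects("hce", -0.75, 0.75, 0.3, 0.015),
}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults define the study-like conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 3_500_000
    margin: int = 10_000  # element/gene-free zone at contig ends
    # genes
    n_genes: int = 120
    gene_length_ranges: tuple[tuple[int, int], ...] = (
        (2_000, 13_900),
        (14_000, 50_000),
        (50_500, 120_000),
    )
    gene_gap_range: tuple[int, int] = (6_500, 9_000)
    n_induced: int = 20
    n_repressed: int = 20
    # elements
    n_microsat: int = 100
    n_isolated: int = 100
    n_tandem_per_class: int = 25
    microsat_units_range: tuple[int, int] = (4, 8)
    min_gap: int = 20
    pairing_window: int = 200
    element_spacing: int = 600
    peak_halfwidth: int = 250
    # GRO-seq
    n_replicates: int = 3
    gro_rate: float = 0.02  # expected sense reads / bp / replicate at the TSS
    gro_rate_log2_sd: float = 0.3  # between-gene variation of lambda
    pause_boost: float = 3.0
    pause_len: int = 300
    runthrough: int = 500  # bp of signal past the TES
    kappa_base: float = 0.002  # per-kb attrition in untreated cells
    gro_bin: int = 50
    gro_background: int = 5_000  # uniform background reads per replicate
    # CUT&Tag
    ct_mean_frags: float = 200.0  # expected fragments / element / replicate (control)
    ct_occ_log2_sd: float = 0.25
    ct_background: int = 50_000  # uniform background fragments per replicate
    ct_frag_mean: float = 180.0
    ct_frag_sd: float = 40.0
    ct_frag_max: int = 1000
    ct_spread: float = 60.0  # sd of fragment midpoints around the element center
    # binding perturbation: planted |delta log2 occupancy| magnitudes (half of
    # elements are nulls, the rest cycle through +/- these)
    occ_shift_magnitudes: tuple[float, ...] = (1.0, 1.5, 2.0)
    null_fraction: float = 0.5
    # shared
    nb_dispersion: float = 0.02  # NB: var = mu + phi * mu^2
    pseudocount: float = 1.0
    # antisense bursts at elements (off by default)
    antisense_enabled: bool = False
    antisense_fraction: float = 0.2
    antisense_mean: float = 50.0
    antisense_spread: float = 100.0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SimTruth:
    """Planted per-gene rates and per-element occupancies."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, length, tertile,
    #                      target_class, lambda_control, lambda_treated,
    #                      kappa_control, kappa_treated
    elements: pd.DataFrame  # element_id, chrom, start, end, center, element_class,
    #                         unit_count, partner, gene_id, occ_control, occ_treated,
    #                         dlog2_occ, antisense
    preset: str


@dataclass
class SimBundle:
    """Everything one simulated experiment produces, in memory."""

    config: SimConfig
    truth: SimTruth
    genome: dict[str, str]
    gene_models: list[GeneModel]
    gro: dict[str, list[StrandedReadSet]]  # condition -> replicates
    cuttag: dict[str, list[FragmentSet]]
    peaks: PeakSet
    de_table: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + phi mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def _scan_bytes(arr: np.ndarray, pat: np.ndarray) -> np.ndarray:
    k = pat.size
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    for i in range(k):
        mask &= arr[i : i + n] == pat[i]
    return np.flatnonzero(mask)


def _scrub_ggaa(arr: np.ndarray, lo: int, hi: int, keep: tuple[int, int], rng) -> None:
    """Mutate bases in ``[lo, hi)`` until no GGAA/TTCC occurrence other than
    the planted one at ``keep`` overlaps the window. Bases inside ``keep``
    are never touched."""
    lo = max(0, lo)
    hi = min(arr.size, hi)
    for _ in range(100):
        window = arr[lo:hi]
        offending = None
        for pat in (GGAA_BYTES, TTCC_BYTES):
            for p in _scan_bytes(window, pat):
                s = lo + int(p)
                if (s, s + 4) != keep:
                    offending = s
                    break
            if offending is not None:
                break
        if offending is None:
            return
        # mutate one base of the occurrence that is outside the planted site
        for off in range(4):
            pos = offending + off
            if not (keep[0] <= pos < keep[1]):
                current = arr[pos]
                choices = BASE_BYTES[BASE_BYTES != current]
                arr[pos] = rng.choice(choices)
                break
    raise RuntimeError("could not scrub GGAA/TTCC occurrences from flank")


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_tertile = cfg.n_genes // 3
    lengths: list[tuple[int, str]] = []
    names = ("small", "medium", "large")
    for t, (lo, hi) in enumerate(cfg.gene_length_ranges):
        n = per_tertile if t < 2 else cfg.n_genes - 2 * per_tertile
        for L in rng.integers(lo, hi + 1, size=n):
            lengths.append((int(L), names[t]))
    order = rng.permutation(len(lengths))
    rows = []
    chroms = cfg.chrom_names()
    ci = 0
    cursor = cfg.margin
    for k, idx in enumerate(order):
        L, tertile = lengths[idx]
        placed = False
        while not placed:
            gap = int(rng.integers(*cfg.gene_gap_range))
            start = cursor + gap
            end = start + L
            if end <= cfg.chrom_len - cfg.margin:
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((f"g{k:04d}", chroms[ci], start, end, strand, L, tertile))
                cursor = end
                placed = True
            else:
                ci += 1
                if ci >= len(chroms):
                    raise ValueError(
                        "gene placement does not fit; increase chrom_len or n_chroms"
                    )
                cursor = cfg.margin
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "length", "tertile"]
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _element_slots(cfg: SimConfig, genes: pd.DataFrame, rng) -> list[tuple[str, int]]:
    """Non-overlapping planting slots in the gaps between genes."""
    slots: list[tuple[str, int]] = []
    buffer = 1_000
    for chrom in cfg.chrom_names():
        sub = genes[genes["chrom"] == chrom]
        bounds = [(cfg.margin, None)]
        prev_end = cfg.margin
        for r in sub.itertuples(index=False):
            gap_lo, gap_hi = prev_end + buffer, r.start - buffer
            pos = gap_lo
            while pos + cfg.element_spacing <= gap_hi:
                slots.append((chrom, pos))
                pos += cfg.element_spacing
            prev_end = r.end
        gap_lo, gap_hi = prev_end + buffer, cfg.chrom_len - cfg.margin
        pos = gap_lo
        while pos + cfg.element_spacing <= gap_hi:
            slots.append((chrom, pos))
            pos += cfg.element_spacing
    order = rng.permutation(len(slots))
    return [slots[i] for i in order]


def _write_bytes(arr: np.ndarray, pos: int, seq: str) -> None:
    arr[pos : pos + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Random genome with planted genes and response elements.

    Returns (genome, genes table, elements table). Planted microsatellites
    cannot be extended by flanking chance units; planted isolated GGAAs have
    ``min_gap``-clean flanks; tandem pairs sit at a sampled edge distance
    within the pairing window.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    arrs = {
        chrom: BASE_BYTES[rng.integers(0, 4, size=cfg.chrom_len)]
        for chrom in cfg.chrom_names()
    }
    genes = _place_genes(cfg, rng)
    slots = _element_slots(cfg, genes, rng)
    n_needed = cfg.n_microsat + cfg.n_isolated + 4 * cfg.n_tandem_per_class
    if len(slots) < n_needed:
        raise ValueError(
            f"only {len(slots)} element slots for {n_needed} elements; "
            "increase chrom_len or reduce element counts"
        )

    rows = []
    si = 0

    def next_slot() -> tuple[str, int]:
        nonlocal si
        chrom, pos = slots[si]
        si += 1
        return chrom, pos + int(rng.integers(0, 40))

    for i in range(cfg.n_microsat):
        chrom, pos = next_slot()
        arr = arrs[chrom]
        k = int(rng.integers(cfg.microsat_units_range[0], cfg.microsat_units_range[1] + 1))
        _write_bytes(arr, pos, "GGAA" * k)
        end = pos + 4 * k
        # prevent chance extension of the planted run on either side
        if np.array_equal(arr[pos - 4 : pos], GGAA_BYTES):
            arr[pos - 2] = _C
        if np.array_equal(arr[end : end + 4], GGAA_BYTES):
            arr[end + 1] = _C
        rows.append((f"el{i:04d}", chrom, pos, end, "microsatellite", k, ""))

    for j in range(cfg.n_isolated):
        chrom, pos = next_slot()
        arr = arrs[chrom]
        _write_bytes(arr, pos, "GGAA")
        _scrub_ggaa(arr, pos - cfg.min_gap - 4, pos + 4 + cfg.min_gap + 4, (pos, pos + 4), rng)
        rows.append(
            (f"el{cfg.n_microsat + j:04d}", chrom, pos, pos + 4, "isolated_ggaa", 0, "")
        )

    base = cfg.n_microsat + cfg.n_isolated
    t = 0
    for cof in sorted(COFACTOR_INSTANCES):
        inst = COFACTOR_INSTANCES[cof]
        for _ in range(cfg.n_tandem_per_class):
            chrom, pos = next_slot()
            arr = arrs[chrom]
            gap = int(rng.integers(cfg.min_gap, cfg.pairing_window - 4))
            ggaa_first = rng.random() < 0.5
            if ggaa_first:
                _write_bytes(arr, pos, "GGAA")
                partner_start = pos + 4 + gap
                _write_bytes(arr, partner_start, inst)
                start, end = pos, partner_start + len(inst)
            else:
                _write_bytes(arr, pos, inst)
                partner_start = pos
                g_start = pos + len(inst) + gap
                _write_bytes(arr, g_start, "GGAA")
                start, end = pos, g_start + 4
            rows.append(
                (f"el{base + t:04d}", chrom, start, end, f"tandem_ggaa_{cof.lower()}", 0, cof)
            )
            t += 1

    elements = pd.DataFrame(
        rows, columns=["element_id", "chrom", "start", "end", "element_class", "unit_count", "partner"]
    )
    elements["center"] = (elements["start"] + elements["end"]) // 2
    genome = {chrom: arr.tobytes().decode("ascii") for chrom, arr in arrs.items()}
    return genome, genes, elements


def assign_truth(
    genes: pd.DataFrame,
    elements: pd.DataFrame,
    cfg: SimConfig,
    preset: str | GroEffects,
    rng: np.random.Generator,
) -> SimTruth:
    """Draw per-gene rates and per-element occupancies under a preset."""
    eff = PRESETS[preset] if isinstance(preset, str) else preset
    genes = genes.copy()
    n = len(genes)
    order = rng.permutation(n)
    target = np.full(n, "neither", dtype=object)
    target[order[: cfg.n_induced]] = "induced"
    target[order[cfg.n_induced : cfg.n_induced + cfg.n_repressed]] = "repressed"
    genes["target_class"] = target

    lam_c = cfg.gro_rate * 2.0 ** rng.normal(0.0, cfg.gro_rate_log2_sd, size=n)
    shift = np.full(n, eff.lambda_log2fc_global)
    shift[target == "induced"] += eff.lambda_log2fc_induced
    shift[target == "repressed"] += eff.lambda_log2fc_repressed
    genes["lambda_control"] = lam_c
    genes["lambda_treated"] = lam_c * 2.0**shift
    genes["kappa_control"] = cfg.kappa_base
    genes["kappa_treated"] = cfg.kappa_base + eff.dkappa_per_kb

    elements = elements.copy()
    m = len(elements)
    occ_c = cfg.ct_mean_frags * 2.0 ** rng.normal(0.0, cfg.ct_occ_log2_sd, size=m)
    n_null = int(round(cfg.null_fraction * m))
    shifts = np.zeros(m)
    mags = cfg.occ_shift_magnitudes
    signed = [s * mag for mag in mags for s in (1.0, -1.0)]
    for k in range(m - n_null):
        shifts[n_null + k] = signed[k % len(signed)]
    shifts = shifts[rng.permutation(m)]
    elements["occ_control"] = occ_c
    elements["dlog2_occ"] = shifts
    elements["occ_treated"] = occ_c * 2.0**shifts

    gene_models = [
        GeneModel(r.gene_id, GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand))
        for r in genes.itertuples(index=False)
    ]
    sites = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in elements.itertuples(index=False)
    ]
    elements["gene_id"] = annotate_nearest_gene(sites, gene_models)

    anti = np.zeros(m, dtype=bool)
    if cfg.antisense_enabled:
        n_anti = int(round(cfg.antisense_fraction * m))
        anti[rng.choice(m, size=n_anti, replace=False)] = True
    elements["antisense"] = anti
    return SimTruth(genes=genes, elements=elements, preset=eff.name)


def _positions_from_bins(
    rng: np.random.Generator, bin_starts: np.ndarray, widths: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    starts = np.repeat(bin_starts, counts)
    w = np.repeat(widths, counts)
    return (starts + np.floor(rng.random(total) * w)).astype(np.int64)


def simulate_groseq(
    truth: SimTruth, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, list[StrandedReadSet]]:
    """Stranded 5'-end read sets per condition x replicate."""
    out: dict[str, list[StrandedReadSet]] = {}
    gene_strand = truth.genes.set_index("gene_id")["strand"]
    for cond, lam_col, kap_col in (
        ("control", "lambda_control", "kappa_control"),
        ("treated", "lambda_treated", "kappa_treated"),
    ):
        sets = []
        for rep in range(1, cfg.n_replicates + 1):
            chroms_parts: list[np.ndarray] = []
            pos_parts: list[np.ndarray] = []
            strand_parts: list[np.ndarray] = []
            for g in truth.genes.itertuples(index=False):
                lam = getattr(g, lam_col)
                kap = getattr(g, kap_col)
                span = g.length + cfg.runthrough
                n_bins = (span + cfg.gro_bin - 1) // cfg.gro_bin
                bin_off = np.arange(n_bins, dtype=np.int64) * cfg.gro_bin
                widths = np.minimum(cfg.gro_bin, span - bin_off)
                d_kb = (bin_off + widths / 2.0) / 1000.0
                mu = lam * widths * np.exp(-kap * d_kb)
                mu = np.where(bin_off < cfg.pause_len, mu * cfg.pause_boost, mu)
                counts = _nb_draw(rng, mu, cfg.nb_dispersion)
                offs = _positions_from_bins(rng, bin_off, widths, counts)
                if g.strand == "+":
                    pos = g.start + offs
                else:
                    pos = (g.end - 1) - offs
                chroms_parts.append(np.full(pos.size, g.chrom, dtype=object))
                pos_parts.append(pos)
                strand_parts.append(np.full(pos.size, g.strand, dtype=object))
            # uniform background, both strands
            n_bg = cfg.gro_background
            if n_bg:
                bg_chrom = rng.choice(cfg.chrom_names(), size=n_bg)
                bg_pos = rng.integers(0, cfg.chrom_len, size=n_bg)
                bg_strand = rng.choice(["+", "-"], size=n_bg)
                chroms_parts.append(bg_chrom.astype(object))
                pos_parts.append(bg_pos.astype(np.int64))
                strand_parts.append(bg_strand.astype(object))
            # optional antisense bursts at flagged elements (treated only)
            if cfg.antisense_enabled and cond == "treated":
                flagged = truth.elements[truth.elements["antisense"]]
                for el in flagged.itertuples(index=False):
                    n_anti = int(_nb_draw(rng, np.array([cfg.antisense_mean]), cfg.nb_dispersion)[0])
                    if n_anti == 0:
                        continue
                    p = rng.normal(el.center, cfg.antisense_spread, size=n_anti)
                    p = np.clip(np.round(p), 0, cfg.chrom_len - 1).astype(np.int64)
                    sense = gene_strand[el.gene_id]
                    anti = "-" if sense == "+" else "+"
                    chroms_parts.append(np.full(n_anti, el.chrom, dtype=object))
                    pos_parts.append(p)
                    strand_parts.append(np.full(n_anti, anti, dtype=object))
            sets.append(
                StrandedReadSet.from_arrays(
                    f"gro_{truth.preset}_{cond}_r{rep}",
                    cond,
                    rep,
                    np.concatenate(chroms_parts),
                    np.concatenate(pos_parts),
                    np.concatenate(strand_parts),
                )
            )
        out[cond] = sets
    return out


def simulate_cuttag(
    truth: SimTruth, cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, list[FragmentSet]], PeakSet]:
    """Fragment sets per condition x replicate plus the true peak set."""
    out: dict[str, list[FragmentSet]] = {}
    for cond, occ_col in (("control", "occ_control"), ("treated", "occ_treated")):
        sets = []
        for rep in range(1, cfg.n_replicates + 1):
            chrom_parts: list[np.ndarray] = []
            start_parts: list[np.ndarray] = []
            end_parts: list[np.ndarray] = []
            counts = _nb_draw(
                rng, truth.elements[occ_col].to_numpy(dtype=float), cfg.nb_dispersion
            )
            for el, n_frag in zip(truth.elements.itertuples(index=False), counts):
                if n_frag == 0:
                    continue
                mids = rng.normal(el.center, cfg.ct_spread, size=n_frag)
                lens = np.clip(
                    np.round(rng.normal(cfg.ct_frag_mean, cfg.ct_frag_sd, size=n_frag)),
                    50,
                    cfg.ct_frag_max - 1,
                )
                starts = np.clip(np.round(mids - lens / 2.0), 0, cfg.chrom_len - 2).astype(np.int64)
                ends = np.minimum(starts + lens.astype(np.int64), cfg.chrom_len)
                chrom_parts.append(np.full(n_frag, el.chrom, dtype=object))
                start_parts.append(starts)
                end_parts.append(ends)
            n_bg = cfg.ct_background
            if n_bg:
                bg_chrom = rng.choice(cfg.chrom_names(), size=n_bg).astype(object)
                bg_len = np.clip(
                    np.round(rng.normal(cfg.ct_frag_mean, cfg.ct_frag_sd, size=n_bg)),
                    50,
                    cfg.ct_frag_max - 1,
                ).astype(np.int64)
                bg_start = rng.integers(0, cfg.chrom_len - cfg.ct_frag_max, size=n_bg)
                chrom_parts.append(bg_chrom)
                start_parts.append(bg_start.astype(np.int64))
                end_parts.append((bg_start + bg_len).astype(np.int64))
            sets.append(
                FragmentSet.from_arrays(
                    f"ct_{cond}_r{rep}",
                    cond,
                    rep,
                    np.concatenate(chrom_parts),
                    np.concatenate(start_parts),
                    np.concatenate(end_parts),
                    max_fragment_len=cfg.ct_frag_max,
                )
            )
        out[cond] = sets
    peaks_df = pd.DataFrame(
        {
            "chrom": truth.elements["chrom"],
            "start": truth.elements["center"] - cfg.peak_halfwidth,
            "end": truth.elements["center"] + cfg.peak_halfwidth,
            "name": "peak_" + truth.elements["element_id"],
        }
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out, PeakSet(peaks_df)


def generate_de_table(truth: SimTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Knockdown DE table consistent with the planted target labels.

    log2FoldChange is silenced-vs-control: induced targets drop (<= -1.2),
    repressed targets rise (>= +1.2), both well below the padj cutoff;
    non-targets sit inside the null box.
    """
    rows = []
    for g in truth.genes.itertuples(index=False):
        if g.target_class == "induced":
            lfc = -max(1.2, rng.normal(2.5, 0.5))
            padj = 10.0 ** rng.uniform(-8, -3)
        elif g.target_class == "repressed":
            lfc = max(1.2, rng.normal(2.5, 0.5))
            padj = 10.0 ** rng.uniform(-8, -3)
        else:
            lfc = float(np.clip(rng.normal(0.0, 0.3), -0.9, 0.9))
            padj = rng.uniform(0.02, 1.0)
        rows.append((g.gene_id, lfc, padj))
    return pd.DataFrame(rows, columns=["gene_id", "log2FoldChange", "padj"])


def simulate_dataset(
    cfg: SimConfig,
    preset: str | GroEffects = "lce",
    gro: bool = True,
    cuttag: bool = True,
) -> SimBundle:
    """Run the full generator in a fixed order under one RNG stream."""
    rng = np.random.default_rng(cfg.seed)
    genome, genes, elements = simulate_genome(cfg, rng)
    truth = assign_truth(genes, elements, cfg, preset, rng)
    gro_sets = simulate_groseq(truth, cfg, rng) if gro else {}
    if cuttag:
        ct_sets, peaks = simulate_cuttag(truth, cfg, rng)
    else:
        ct_sets, peaks = {}, PeakSet(
            pd.DataFrame(columns=["chrom", "start", "end", "name"])
        )
    de = generate_de_table(truth, rng)
    gene_models = [
        GeneModel(r.gene_id, GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand))
        for r in truth.genes.itertuples(index=False)
    ]
    return SimBundle(
        config=cfg,
        truth=truth,
        genome=genome,
        gene_models=gene_models,
        gro=gro_sets,
        cuttag=ct_sets,
        peaks=peaks,
        de_table=de,
    )


def write_truth_tables(truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctg_io.write_table(truth.genes, outdir / "truth_genes.tsv")
    ctg_io.write_table(truth.elements, outdir / "truth_elements.tsv")


def write_dataset(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, gene BED, element truth BED, read/fragment BEDs, truth
    tables, DE table and sample manifests; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "genome.fa"
    ctg_io.write_fasta(bundle.genome, paths["fasta"])

    genes_bed = bundle.truth.genes.rename(columns={"gene_id": "name"})[
        ["chrom", "start", "end", "name", "length", "strand"]
    ].rename(columns={"length": "score"})
    paths["genes"] = outdir / "genes.bed"
    ctg_io.write_bed6(genes_bed, paths["genes"])

    el = bundle.truth.elements
    el_bed = pd.DataFrame(
        {
            "chrom": el["chrom"],
            "start": el["start"],
            "end": el["end"],
            "name": el["element_class"],
            "score": el["unit_count"] * 100,
            "strand": "+",
        }
    )
    paths["elements"] = outdir / "truth_elements.bed"
    ctg_io.write_bed6(el_bed, paths["elements"])

    paths["peaks"] = outdir / "peaks.bed"
    pk = bundle.peaks.peaks.copy()
    pk["score"] = 0
    pk["strand"] = "."
    ctg_io.write_bed6(pk, paths["peaks"])

    paths["de"] = outdir / "de_table.tsv"
    ctg_io.write_table(bundle.de_table, paths["de"])
    write_truth_tables(bundle.truth, outdir)

    for assay, sets_by_cond, writer in (
        ("gro", bundle.gro, lambda s: s.to_bed()),
        ("cuttag", bundle.cuttag, lambda s: s.to_bed()),
    ):
        manifest_rows = []
        for cond, sets in sets_by_cond.items():
            for s in sets:
                path = outdir / f"{s.sample_id}.bed"
                ctg_io.write_bed6(writer(s), path)
                manifest_rows.append((s.sample_id, cond, s.replicate, path.name))
        if manifest_rows:
            manifest = pd.DataFrame(
                manifest_rows, columns=["sample_id", "condition", "replicate", "path"]
            )
            paths[f"{assay}_manifest"] = outdir / f"{assay}_manifest.tsv"
            ctg_io.write_table(manifest, paths[f"{assay}_manifest"])
    return paths


@dataclass(frozen=True)
class ExposureSpec:
    """Exposure (concentration x time) and cumulative-dose arithmetic."""

    concentration_nmol_l: float
    duration_h: float
    exposure_nmol_l_h: float
    per_dose_mg_kg: float | None = None
    n_doses: int | None = None
    total_dose_mg_kg: float | None = None


def exposure_and_dose(
    concentration_nmol_l: float,
    duration_h: float,
    per_dose_mg_kg: float | None = None,
    n_doses: int | None = None,
) -> ExposureSpec:
    """Exposure = concentration x time; total dose = per-dose x number of doses."""
    values = [concentration_nmol_l, duration_h]
    if per_dose_mg_kg is not None:
        values.append(per_dose_mg_kg)
    if n_doses is not None:
        values.append(n_doses)
    if any(v < 0 for v in values):
        raise ValueError("exposure/dose inputs must be non-negative")
    total = (
        per_dose_mg_kg * n_doses
        if per_dose_mg_kg is not None and n_doses is not None
        else None
    )
    return ExposureSpec(
        concentration_nmol_l=concentration_nmol_l,
        duration_h=duration_h,
        exposure_nmol_l_h=concentration_nmol_l * duration_h,
        per_dose_mg_kg=per_dose_mg_kg,
        n_doses=n_doses,
        total_dose_mg_kg=total,
    )
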