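"""End-to-end orchestration: simulate -> motifs -> targets -> bind -> gro -> integrate.

The pipeline either consumes user-supplied inputs (FASTA, gene BED, DE table,
fragment/read manifests, peak BED) or generates them with the built-in
simulator (``preset``). Stages run in dependency order; the final stage joins
differential-binding records with element classes, target classes, window
statistics and antisense statistics into one master table keyed by element.
Re-running with an unchanged config and seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, io as ctg_io
from .binding import (
    FragmentSet,
    PeakSet,
    count_fragments,
    cpm_normalize,
    differential_binding,
    frip,
    load_fragments,
    replicate_correlation,
    site_metaprofile,
)
from .intervals import GenomicInterval, intersect_intervals
from .motifs import (
    DEFAULT_COFACTOR_PATTERNS,
    classify_tandem_sites,
    find_isolated_ggaa,
    find_microsatellites,
    scan_cofactor_motifs,
    scan_ggaa,
    MicrosatelliteLocus,
    MotifSite,
    ResponseElement,
)
from .nascent import (
    StrandedReadSet,
    antisense_initiation,
    elongation_index,
    load_reads,
    pooled_window_counts,
    scaled_metagene,
    tes_group_stats,
    windows_for_genes,
)
from .simulate import PRESETS, SimConfig, simulate_dataset, write_dataset
from .targets import (
    GeneModel,
    annotate_nearest_gene,
    classify_targets,
    genes_from_bed,
    partition_by_length_tertiles,
)

logger = logging.getLogger(__name__)

try:  # python >= 3.11
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    import tomli as tomllib  # type: ignore[no-redef]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults.

    Either ``preset`` (simulate inputs) or the full set of input paths must
    be provided. Unknown keys in a TOML config are rejected.
    """

    out_dir: str = "ctg_out"
    seed: int = 0
    preset: str | None = None
    # inputs (required when preset is None)
    fasta: str | None = None
    genes: str | None = None
    de_table: str | None = None
    gro_manifest: str | None = None
    cuttag_manifest: str | None = None
    peaks: str | None = None
    # motif tunables
    min_units: int = 4
    min_gap: int = 20
    pairing_window: int = 200
    # target tunables
    lfc_cut: float = 1.0
    padj_cut: float = 0.01
    # binding tunables
    max_fragment_len: int = 1000
    fdr_cut: float = 0.05
    flank_bind: int = 1500
    bin_bind: int = 10
    # GRO-seq tunables
    flank_gro: int = 3000
    bin_gro: int = 50
    body_bins: int = 100
    antisense_flank: int = 1000
    pseudocount: float = 1.0
    # simulator overrides (passed to SimConfig)
    sim: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        if self.preset is None:
            required = ("fasta", "genes", "de_table", "gro_manifest", "cuttag_manifest", "peaks")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    f"no preset requested and input paths missing: {missing}"
                )

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return digest[:16]


@dataclass
class RunReport:
    """Structured per-stage summary; serialized as sorted JSON."""

    version: str
    config_hash: str
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def add(self, stage: str, **stats: Any) -> None:
        if stage in self.stages:
            raise ValueError(f"stage {stage!r} reported twice")
        self.stages[stage] = stats

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "stages": self.stages,
        }
        return json.dumps(payload, sort_keys=True, indent=2, default=float)


def _load_manifest_fragments(path: Path, max_len: int) -> list[FragmentSet]:
    manifest = ctg_io.read_manifest(path)
    sets = []
    for r in manifest.itertuples(index=False):
        p = Path(r.path)
        if not p.is_absolute():
            p = path.parent / p
        sets.append(
            load_fragments(p, r.sample_id, r.condition, int(r.replicate), max_fragment_len=max_len)
        )
    return sets


def _load_manifest_reads(path: Path) -> list[StrandedReadSet]:
    manifest = ctg_io.read_manifest(path)
    sets = []
    for r in manifest.itertuples(index=False):
        p = Path(r.path)
        if not p.is_absolute():
            p = path.parent / p
        sets.append(load_reads(p, r.sample_id, r.condition, int(r.replicate)))
    return sets


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages; writes stage outputs under ``cfg.out_dir``.

    A failing stage halts the run with the stage named; outputs written so
    far are retained next to a ``FAILED_<stage>`` marker file.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config_hash=cfg.config_hash())
    stage = "init"
    try:
        # ---- simulate (optional) ------------------------------------------
        stage = "simulate"
        if cfg.preset is not None:
            sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
            bundle = simulate_dataset(sim_cfg, preset=cfg.preset)
            paths = write_dataset(bundle, out / "sim")
            cfg.fasta = str(paths["fasta"])
            cfg.genes = str(paths["genes"])
            cfg.de_table = str(paths["de"])
            cfg.gro_manifest = str(paths["gro_manifest"])
            cfg.cuttag_manifest = str(paths["cuttag_manifest"])
            cfg.peaks = str(paths["peaks"])
            report.add(
                stage,
                preset=cfg.preset,
                n_genes=len(bundle.truth.genes),
                n_elements=len(bundle.truth.elements),
                n_gro_samples=sum(len(v) for v in bundle.gro.values()),
                n_cuttag_samples=sum(len(v) for v in bundle.cuttag.values()),
            )
        else:
            report.add(stage, preset=None)

        # ---- motifs --------------------------------------------------------
        stage = "motifs"
        genome = ctg_io.read_fasta(cfg.fasta)
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        ggaa_sites: list[MotifSite] = []
        microsats: list[MicrosatelliteLocus] = []
        cofactors: list[MotifSite] = []
        for chrom in sorted(genome):
            seq = genome[chrom]
            ggaa_sites.extend(scan_ggaa(seq, chrom))
            microsats.extend(find_microsatellites(seq, chrom, min_units=cfg.min_units))
            cofactors.extend(scan_cofactor_motifs(seq, chrom, DEFAULT_COFACTOR_PATTERNS))
        isolated = find_isolated_ggaa(ggaa_sites, min_gap=cfg.min_gap)
        micro_elements = [ResponseElement(m, "microsatellite") for m in microsats]
        ctg_io.write_bed6(ctg_io.elements_to_bed(micro_elements), out / "microsatellites.bed")
        ctg_io.write_bed6(
            ctg_io.elements_to_bed([ResponseElement(s, "isolated_ggaa") for s in isolated]),
            out / "isolated_ggaa.bed",
        )
        report.add(
            stage,
            n_ggaa=len(ggaa_sites),
            n_microsatellites=len(microsats),
            n_isolated=len(isolated),
            n_cofactor_sites=len(cofactors),
        )

        # ---- targets -------------------------------------------------------
        stage = "targets"
        de = ctg_io.read_table(cfg.de_table)
        target_table = classify_targets(de, lfc_cut=cfg.lfc_cut, padj_cut=cfg.padj_cut)
        gene_models = genes_from_bed(ctg_io.read_bed6(cfg.genes))
        tertiles = partition_by_length_tertiles(gene_models)
        ctg_io.write_table(target_table, out / "targets.tsv")
        tert_df = tertiles.classes.reset_index()
        with open(out / "tertiles.tsv", "w") as fh:
            fh.write(
                f"# tertile boundaries: b1={tertiles.boundaries[0]:.1f} "
                f"b2={tertiles.boundaries[1]:.1f}\n"
            )
            tert_df.to_csv(fh, sep="\t", index=False)
        n_by_class = target_table["target_class"].value_counts().to_dict()
        report.add(
            stage,
            n_genes=len(gene_models),
            n_induced=int(n_by_class.get("induced", 0)),
            n_repressed=int(n_by_class.get("repressed", 0)),
            tertile_boundaries=[round(b, 1) for b in tertiles.boundaries],
        )

        # ---- bind ----------------------------------------------------------
        stage = "bind"
        frag_sets = _load_manifest_fragments(Path(cfg.cuttag_manifest), cfg.max_fragment_len)
        peaks = PeakSet.from_bed(cfg.peaks)
        counts = count_fragments(frag_sets, peaks)
        lib_sizes = {fs.sample_id: fs.library_size for fs in frag_sets}
        cpm = cpm_normalize(counts, lib_sizes)
        groups = {fs.sample_id: fs.condition for fs in frag_sets}
        diff = differential_binding(
            cpm, groups, "control", "treated", pseudocount=cfg.pseudocount, fdr_cut=cfg.fdr_cut
        )
        frips = {fs.sample_id: round(frip(fs, peaks), 4) for fs in frag_sets}
        corr = replicate_correlation(cpm)
        off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        ctg_io.write_table(cpm.reset_index(), out / "binding_cpm.tsv")
        ctg_io.write_table(diff, out / "differential_binding.tsv")
        ctg_io.write_table(corr.reset_index(names="sample_id"), out / "replicate_correlation.tsv")
        # element-centered metaprofiles per condition, pooled replicates
        micro_sites = [m.interval for m in microsats]
        for cond in sorted({fs.condition for fs in frag_sets}):
            pooled = pool_fragment_sets([fs for fs in frag_sets if fs.condition == cond])
            prof = site_metaprofile(
                pooled, micro_sites, chrom_sizes, flank=cfg.flank_bind, bin_width=cfg.bin_bind
            )
            _, prof_df = prof.to_frames()
            ctg_io.write_table(prof_df, out / f"metaprofile_microsat_{cond}.tsv")
        report.add(
            stage,
            n_peaks=len(peaks),
            n_significant=int(diff["significant"].sum()),
            frip=frips,
            min_replicate_correlation=round(float(np.nanmin(off_diag)), 4),
        )

        # ---- gro -----------------------------------------------------------
        stage = "gro"
        read_sets = _load_manifest_reads(Path(cfg.gro_manifest))
        ctrl = [rs for rs in read_sets if rs.condition == "control"]
        trt = [rs for rs in read_sets if rs.condition == "treated"]
        windows = windows_for_genes(gene_models)
        wc_c = pooled_window_counts(ctrl, windows)
        wc_t = pooled_window_counts(trt, windows)
        ei = elongation_index(wc_c, wc_t, pseudocount=cfg.pseudocount)
        ei = ei.join(tertiles.classes)
        mean_delta_by_tertile = {
            t: round(float(ei.loc[ei["tertile"] == t, "delta_ei"].mean()), 4)
            for t in ("small", "medium", "large")
        }
        metagene = scaled_metagene(
            trt,
            ctrl,
            gene_models,
            flank=cfg.flank_gro,
            bin_width=cfg.bin_gro,
            body_bins=cfg.body_bins,
            pseudocount=cfg.pseudocount,
            chrom_sizes=chrom_sizes,
        )
        tes_stats = tes_group_stats(ctrl, trt, windows, target_table)
        gene_by_id = {g.gene_id: g for g in gene_models}
        peak_ivs = peaks.intervals()
        peak_genes = annotate_nearest_gene(peak_ivs, gene_models)
        anti_peaks = [
            (name, iv, gene_by_id[gid].strand)
            for name, iv, gid in zip(peaks.peaks["name"], peak_ivs, peak_genes)
        ]
        anti = antisense_initiation(
            ctrl, trt, anti_peaks, flank=cfg.antisense_flank, pseudocount=cfg.pseudocount
        )
        ctg_io.write_table(wc_c.reset_index(), out / "window_counts_control.tsv")
        ctg_io.write_table(wc_t.reset_index(), out / "window_counts_treated.tsv")
        ctg_io.write_table(ei.reset_index(names="gene_id"), out / "elongation_index.tsv")
        prof_df = pd.DataFrame(
            {"column": np.arange(metagene.profile.size), "log2fc": metagene.profile}
        )
        ctg_io.write_table(prof_df, out / "metagene_profile.tsv")
        ctg_io.write_table(tes_stats, out / "tes_group_stats.tsv")
        ctg_io.write_table(anti, out / "antisense_initiation.tsv")
        report.add(
            stage,
            n_windows=len(windows),
            mean_delta_ei_by_tertile=mean_delta_by_tertile,
            metagene_body_slope=round(metagene.body_slope(), 4),
        )

        # ---- integrate -----------------------------------------------------
        stage = "integrate"
        sig_peaks = diff.loc[diff["significant"], "peak_id"]
        peak_map = peaks.peaks.set_index("name")
        sig_ivs = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in peak_map.loc[sig_peaks].itertuples(index=False)
        ]
        sig_ivs.sort(key=lambda iv: (iv.chrom, iv.start))
        iso_ivs = [s.interval for s in isolated]
        retained_set = {
            (iv.chrom, iv.start, iv.end)
            for iv in intersect_intervals(iso_ivs, sig_ivs)
        }
        retained = [
            s for s in isolated if (s.interval.chrom, s.interval.start, s.interval.end) in retained_set
        ]
        tandem = classify_tandem_sites(retained, cofactors, window=cfg.pairing_window)
        elements = (
            micro_elements
            + [ResponseElement(s, "isolated_ggaa") for s in retained]
            + tandem
        )
        master = integrate_element_table(
            elements, gene_models, target_table, diff, peaks, ei, wc_c, wc_t, anti,
            pseudocount=cfg.pseudocount,
        )
        ctg_io.write_table(master, out / "master_elements.tsv")
        report.add(
            stage,
            n_elements=len(elements),
            n_master_rows=len(master),
            n_retained_isolated=len(retained),
            n_tandem=len(tandem),
        )
    except Exception:
        (out / f"FAILED_{stage}").touch()
        logger.exception("pipeline failed in stage %r", stage)
        raise
    (out / "run_report.json").write_text(report.to_json() + "\n")
    return report


def pool_fragment_sets(sets: list[FragmentSet]) -> FragmentSet:
    """Merge replicate fragment sets into one pooled set (summed library)."""
    if not sets:
        raise ValueError("no fragment sets to pool")
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for fs in sets:
        for chrom, (s, e) in fs.fragments.items():
            chroms.append(np.full(s.size, chrom, dtype=object))
            starts.append(s)
            ends.append(e)
    return FragmentSet.from_arrays(
        f"pooled_{sets[0].condition}",
        sets[0].condition,
        0,
        np.concatenate(chroms),
        np.concatenate(starts),
        np.concatenate(ends),
        max_fragment_len=np.iinfo(np.int32).max,
    )


def integrate_element_table(
    elements: list[ResponseElement],
    gene_models: list[GeneModel],
    target_table: pd.DataFrame,
    diff: pd.DataFrame,
    peaks: PeakSet,
    ei: pd.DataFrame,
    wc_control: pd.DataFrame,
    wc_treated: pd.DataFrame,
    antisense: pd.DataFrame | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One master row per (element, class label), joined to every statistic.

    Missing joins are explicit NA values, never dropped rows: the number of
    rows out always equals the number of elements in.
    """
    target_map = target_table.set_index("gene_id")["target_class"]
    diff_map = diff.set_index("peak_id")
    anti_map = (
        antisense.set_index("peak_id") if antisense is not None and len(antisense) else None
    )
    # element -> overlapping peak (first by coordinate)
    pk = peaks.peaks
    pk_by_chrom = {c: sub.reset_index(drop=True) for c, sub in pk.groupby("chrom")}

    def overlapping_peak(iv: GenomicInterval) -> str | None:
        sub = pk_by_chrom.get(iv.chrom)
        if sub is None:
            return None
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        hit = np.flatnonzero((s < iv.end) & (e > iv.start))
        return str(sub["name"].iloc[hit[0]]) if hit.size else None

    gene_ids = annotate_nearest_gene([el.interval for el in elements], gene_models)
    tes_log2fc = np.log2(
        (wc_treated["tes_cpm"] + pseudocount) / (wc_control["tes_cpm"] + pseudocount)
    )
    rows = []
    seen: set[tuple] = set()
    for el, gid in zip(elements, gene_ids):
        iv = el.interval
        key = (iv.chrom, iv.start, iv.end, el.element_class)
        if key in seen:
            raise ValueError(f"duplicate element id {key}")
        seen.add(key)
        peak_id = overlapping_peak(iv)
        rec = diff_map.loc[peak_id] if peak_id in diff_map.index else None
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "element_class": el.element_class,
                "gene_id": gid,
                "target_class": target_map.get(gid, "NA"),
                "peak_id": peak_id,
                "binding_log2fc": rec["log2fc"] if rec is not None else np.nan,
                "binding_fdr": rec["fdr"] if rec is not None else np.nan,
                "delta_ei": ei["delta_ei"].get(gid, np.nan),
                "tes_log2fc": tes_log2fc.get(gid, np.nan),
                "antisense_log2fc": (
                    anti_map["antisense_log2fc"].get(peak_id, np.nan)
                    if anti_map is not None and peak_id is not None
                    else np.nan
                ),
            }
        )
    master = pd.DataFrame(rows)
    return master.sort_values(
        ["chrom", "start", "end", "element_class"], kind="mergesort"
    ).reset_index(drop=True)
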