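# cuttaggro

Integrated CUT&Tag + GRO-seq analysis of GGAA response elements: who binds
where, and what that binding does to nascent transcription.

Ewing-sarcoma cells are driven by an EWS::ETS fusion transcription factor
that binds GGAA-containing response elements. Drugs that displace or
stabilize the fusion protein can act through two distinct transcriptional
mechanisms: changing **initiation** at target promoters, or impairing
**RNA-polymerase-II processivity** so that elongating signal decays along the
gene body. This package implements, as a tested and reusable pipeline, the
analyses needed to tell those mechanisms apart from paired CUT&Tag
(binding) and GRO-seq (nascent transcription) data, together with a
synthetic-data generator that plants known truth for validation. It is
aimed at computational biologists working with nascent-transcription and
antibody-tagmentation assays.

## What it computes

**Response-element stratification** (`cuttaggro.motifs`)
GGAA/TTCC scanning on both strands; maximal (GGAA)ₖ microsatellites
(k ≥ 4 by default); *isolated* GGAAs — no other GGAA/TTCC within 20 bp
(nearest-edge, boundary inclusive); *tandem* heterotypic elements — a GGAA
within 200 bp of an AP-1, RUNX2, E2F or FLI1 consensus; half-open interval
intersection. All scanners are tested for exact agreement with brute-force
oracles.

**Target classification** (`cuttaggro.targets`)
From a knockdown DE table (log₂FC of silenced vs. control, adjusted p):
induced targets have log₂FC ≤ −1 and padj < 0.01 (the fusion protein
induces them, silencing lowers them), repressed targets the mirror image.
Nearest-TSS annotation of elements/peaks; gene-length tertiles at the
empirical 1/3 and 2/3 quantiles.

**Differential binding** (`cuttaggro.binding`)
Binary fragment-per-peak counting, CPM normalization, per-peak Welch t-test
on log₂(CPM+1) with Benjamini–Hochberg FDR, FRiP, Spearman replicate
correlation, element-centered metaprofiles (±1.5 kb, 10 bp bins), and
cumulative hypergeometric motif enrichment.

**Initiation vs. processivity** (`cuttaggro.nascent`)
Sense-strand 5′-end counting in the windows
TSS [−300, +30), body [TSS+30, TES−30), TES [−30, +300);
the elongation index `EI = log2((TES_CPM + 1) / (TSS_CPM + 1))` and its
treated-minus-control change ΔEI; scale-regions metagene matrices of
log₂(treated/control); log₂-ratio tracks with group scaling to the control
maximum; TES violin statistics with a two-sided Wilcoxon rank-sum test;
antisense-initiation detection at binding peaks.

**Simulator** (`cuttaggro.simulate`)
Plants genes in three length tertiles and 300 response elements into a
random genome; GRO-seq reads follow
`mu(d) = lambda_{g,c} * exp(-kappa_{g,c} * d_kb)` with a promoter-proximal
pause boost and negative-binomial replicate noise; CUT&Tag fragments follow
a per-element occupancy model over a uniform background. The `lce` preset
perturbs initiation only; `hce` adds genome-wide attrition (Δκ).
Exposure arithmetic (concentration × time, per-dose × n-doses) is included
as a small experiment-design utility.

## Worked example

```bash
python examples/03_initiation_vs_processivity.py
```

prints (seed 1, default simulation):

```
--- preset lce ---
metagene body slope:        +0.008
mean delta-EI small/medium/large: +0.15 / +0.30 / -0.12
TES rank-sum p, induced targets:  2.91e-14
--- preset hce ---
metagene body slope:        -0.827
mean delta-EI small/medium/large: +0.02 / -0.49 / -1.96
TES rank-sum p, induced targets:  1.45e-06
```

The initiation-only exposure leaves the metagene log₂-ratio profile flat
across the gene body (slope ≈ 0) while strongly suppressing induced-target
TES signal; the attrition exposure produces a negative body slope and a ΔEI
that worsens with gene length (large < medium < small), the signature of
impaired processivity. `examples/02_differential_binding_recovery.py` shows
the binding side: rank correlation 0.93 between estimated and planted
occupancy changes, sensitivity 0.91 at FDR < 0.05, null false-positive rate
0.07.

The same analyses run from the shell:

```bash
ctg simulate --preset lce --seed 1 --out-dir sim/
ctg motifs   --fasta sim/genome.fa --out-dir motifs/
ctg targets  --de sim/de_table.tsv --genes sim/genes.bed --out targets.tsv
ctg bind     --fragments sim/cuttag_manifest.tsv --peaks sim/peaks.bed --out-dir bind/
ctg gro      --reads sim/gro_manifest.tsv --genes sim/genes.bed --targets targets.tsv --out-dir gro/
ctg run      --preset lce --seed 1 --out-dir ctg_out/   # everything + master table
```

`ctg run` finishes with `master_elements.tsv`: one row per
(element, class) joining binding log₂FC/FDR, target class, ΔEI, TES log₂FC
and antisense statistics, plus a `run_report.json` with per-stage counts and
a config hash; reruns with the same config and seed are byte-identical.

## Layout

```
src/cuttaggro/   intervals, motifs, targets, stats, binding, nascent,
                 simulate, pipeline, cli, io
tests/           unit + property + acceptance suites (brute-force oracles in
                 tests/_oracles.py)
examples/        four narrative scripts, one per capability
docs/methods.md  model, parameter and design notes
```
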