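# Methods

## The problem and the model

Paired CUT&Tag and GRO-seq experiments ask two coupled questions: where does
a GGAA-binding fusion transcription factor sit on chromatin, and what does a
perturbation of its binding do to nascent transcription? The package
formalizes the second question as an **initiation × attrition** model of
sense-strand GRO-seq signal. For gene *g* in condition *c*, the expected
5′-end density at distance *d* kb downstream of the TSS is

    mu_{g,c}(d) = lambda_{g,c} * exp(-kappa_{g,c} * d) * pause(d)

where `lambda` is the initiation rate (reads/bp/replicate at the TSS),
`kappa` the per-kb exponential attrition of elongating polymerase, and
`pause(d)` a constant boost (default 3×) over the first 300 bp emulating
promoter-proximal pausing. Exponential attrition is the minimal model
consistent with a monotone downward metagene slope; no termination-site
structure is modeled.

Two derived read-outs separate the mechanisms:

* the **elongation index** `EI = log2((TES_CPM + psi)/(TSS_CPM + psi))` and
  its change `dEI = EI_treated − EI_control`. Because λ and the pause factor
  cancel inside the within-sample ratio, `dEI ≈ log2(exp(-dkappa * L_kb))`:
  an initiation-only perturbation leaves dEI at 0, attrition makes it
  negative in proportion to gene length. This is the basis of the
  closed-form acceptance check (10 kb genes, dkappa = 0.1/kb, dEI → −1.443).
* the **scale-regions metagene** of per-bin `log2((treated+psi)/(control+psi))`:
  flat across the resampled gene body for an initiation shift, negatively
  sloped under attrition.

Window conventions (transcription coordinates, half-open):
TSS window `[TSS−300, TSS+30)`, gene body `[TSS+30, TES−30)`, TES window
`[TES−30, TES+300)`. The three windows tile `[TSS−300, TES+300)`; genes
with length ≤ 60 bp have an empty body and are skipped with a warning. The
TSS-window orientation (300 bp upstream, 30 bp into the gene) was chosen so
that the three windows tile the locus consistently with the unambiguous
body and TES definitions. Reads are 5′-end positions and counting is
sense-strand only, as appropriate for a strand-specific run-on assay;
antisense signal is analyzed separately at peak centers.

## Element stratification rules

* **Microsatellite**: maximal run of ≥ `min_units` (default 4) consecutive
  GGAA units with zero spacer, scanned as GGAA runs (+) and TTCC runs (−)
  and deduplicated by interval. The repeat-unit threshold is configurable
  because published microsatellite catalogs differ in the motif model used.
* **Isolated GGAA**: no other GGAA/TTCC occurrence within `min_gap`
  (default 20 bp) by nearest-edge distance; a gap of exactly 20 bp counts as
  isolated (the boundary-inclusive reading keeps the rule deterministic).
  Overlapping occurrences are never isolated.
* **Tandem element**: a GGAA whose nearest-edge distance to a cofactor
  consensus (AP-1 `TGASTCA`, RUNX2 `TGYGGTY`, E2F `GCGSSAAA`, FLI1
  `CCGGAAGT`) is ≤ `window` (default 200 bp). One GGAA can join several
  cofactor classes; the partner is the nearest qualifying occurrence, ties
  to the smaller start. The consensus strings are short IUPAC defaults, not
  literature position-weight matrices; they are overridable per scan, and
  all distances are nearest-edge to match the overlap semantics of interval
  intersection.

Nearest-gene annotation uses the TSS closest to the site midpoint with
lexicographic tie-breaking — deliberately simpler and more deterministic
than full genic-feature hierarchies. Length tertiles use type-7
(linear-interpolation) quantiles at 1/3 and 2/3; boundaries are always
recomputed from the supplied annotation and reported, never hard-coded.

## Differential binding

Fragments ≥ 1000 bp are discarded at load time. Counting is binary per
(fragment, peak) overlap of ≥ 1 bp. Differential binding is a per-peak
Welch (unequal-variance) t-test on `log2(CPM + 1)` across replicates with
Benjamini–Hochberg FDR over all peaks and a 0.05 significance cut. This is
a deliberate, transparent stand-in for affinity-model refits: it is
deterministic, testable against simulation truth, and its operating
characteristics (sensitivity, false-positive rate, rank agreement) are part
of the acceptance suite. The pseudocount of 1 CPM bounds log ratios at zero
counts. Spearman correlations are mid-rank Pearson on per-peak CPMs;
correlation against a constant column is reported as missing, not 0.

## Statistical kernels

`bh_fdr` is the standard step-up with monotonicity enforcement. The
Wilcoxon rank-sum test enumerates the exact null when n ≤ 12 without ties,
otherwise uses the normal approximation with tie correction and a 0.5
continuity correction; fully tied samples give p = 1. Hypergeometric motif
enrichment is the upper cumulative tail P[X ≥ k]. All three are
cross-checked in the tests against independent implementations
(statsmodels, scipy, direct PMF summation) — the library implementations
never stand in for the package's own.

## Simulator: what it emulates, and what it does not

Defaults define a study-like experiment: 2 chromosomes × 3.5 Mb, 120 genes
planted in three length tertiles (2–13.9 kb, 14–50 kb, 50.5–120 kb,
mirroring transcriptome-scale tertile boundaries near 14 kb / 50 kb),
20 induced and 20 repressed targets, 300 elements (100 microsatellites,
100 isolated GGAAs, 25 tandem sites per cofactor class), 3 replicates per
condition. GRO-seq rate λ = 0.02 reads/bp/replicate with 0.3 log₂ SD
between genes (~10⁵ reads/replicate), baseline κ = 0.002/kb, 500 bp of
run-through past the TES so the TES window sees signal, plus 5000 uniform
background reads. CUT&Tag plants ~200 fragments/element/replicate
(0.25 log₂ SD), fragment length N(180, 40) truncated to [50, 1000), 60 bp
midpoint spread, 50 000 background fragments; true peaks are element
centers ± 250 bp. Replicate noise is negative-binomial with dispersion
φ = 0.02 (var = μ + φμ²), a typical high-count replicate dispersion for
count assays; Poisson noise would understate replicate scatter.

Occupancy perturbation: half the elements are nulls, the rest cycle through
Δlog₂ occupancy of ±1, ±1.5, ±2. Exposure presets: `lce` shifts initiation
only (induced targets ×2^−1.5, repressed ×2^+1.5); `hce` adds Δκ = 0.015/kb
genome-wide plus milder initiation effects (±0.75) and a +0.3 global
induction. Antisense bursts at elements are available but off by default.

Planting guarantees recoverability: microsatellite runs cannot be extended
by chance flanking units, isolated GGAAs get scrubbed 20 bp flanks, tandem
pairs are written at a sampled edge distance within the window, and all
elements sit ≥ 600 bp apart in intergenic space. Chance background motifs
are legitimate discoveries and are validated against the brute-force
oracles rather than the truth table.

Not emulated: sequencing error, mappability, fragment GC bias, enhancer
RNAs, overlapping genes, termination-zone structure, and spike-in
normalization. Passing tests therefore demonstrate correctness of the
quantitation and inference machinery under the stated generative model, not
robustness to alignment artifacts or to normalization regimes beyond CPM.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; BED written as-is.
* Pseudocount ψ = 1 CPM in all log ratios; bins 50 bp (GRO) / 10 bp
  (CUT&Tag metaprofiles); gene bodies resampled to 100 columns by
  length-weighted averaging; metagene/metaprofile bins falling off a contig
  are missing values excluded from column means.
* Replicates are pooled by summed counts for tracks, profiles and the
  elongation index; replicate-level values feed the rank-sum statistics.
* All randomness flows from one `numpy.random.default_rng(seed)` in a fixed
  generation order, making every simulator and pipeline output
  byte-identical under a fixed (config, seed); the run report carries a
  config hash that changes iff a tunable changes.
* Problem sizes in the tests and the acceptance script (default simulation,
  200 oracle sequences of 10 kb, 1000 null trials, 30-gene closed-form
  check) are the package's chosen validation scale: large enough for stable
  Monte-Carlo estimates at the stated tolerances, small enough to run
  routinely.

## Known limitations

The differential-binding stand-in assumes roughly log-normal replicate
variation at moderate counts; very low-count peaks are better served by
count-model refits. The Welch test with 3 replicates has limited power at
|Δlog₂| < 1 (by design the acceptance bar applies at ≥ 1). Nearest-TSS
annotation ignores genic context (intron vs. promoter), and the window
quantitation double-counts reads shared by overlapping genes (none exist in
the simulator). The exposure presets encode qualitative, not fitted,
effect sizes.
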