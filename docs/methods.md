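# Methods

## The problem being modelled

Cell-free DNA (cfDNA) in plasma and urine carries the CpG methylation
signature of the cells it came from, so bulk methylation sequencing of cfDNA
can be deconvolved into tissue-of-origin (TOO) proportions. The measurement,
however, is filtered through library preparation. Double-stranded library
preparation (dsLP) blunts fragment ends before adapter ligation: 5′
single-stranded overhangs ("jagged ends") are filled in by extending the
complementary strand's recessed 3′ end, and the polymerase uses unmethylated
cytosines. Every CpG in a fill-in tract is therefore reported unmethylated
regardless of its biological state. Single-stranded preparation (ssLP)
ligates splint adapters to denatured strands without end repair and leaves
methylation patterns untouched. Urinary cfDNA is substantially more jagged
than plasma cfDNA, so the dsLP artifact is much larger there.

This package implements that mechanism as a generative model plus the full
analysis stack used to detect and quantify its consequences: within-read
M-bias profiles, the jagged index JI-U, global CpG/CHH methylation,
spike-in conversion QC, and two TOO deconvolution algorithms.

## Generative model

One simulated sample is fully determined by a `SimConfig`:

1. **Origin and placement.** Each fragment draws a tissue from the mixture,
   a length from a truncated normal (default mean 165 bp, sd 20 bp, floor
   50 bp — nucleosome-scale plasma cfDNA; the urine preset uses 150/25), and
   a placement anchored on a uniformly chosen atlas CpG so that every
   fragment covers reference sites. Each covered CpG's methylation state is
   Bernoulli with the tissue's atlas beta; both strands share the truth.
2. **Jagged ends.** Each fragment end independently carries a 5′ overhang
   with probability `jag_prob`; lengths are geometric with configurable
   mean (a long-tailed family, since overhangs range from absent to almost
   the whole fragment), truncated at fragment length − 1. A constant-length
   variant exists for limit tests. Only 5′ overhangs are generated; 3′
   overhang digestion is outside the model (it leaves no methylation trace).
3. **Library preparation.** dsLP fills each overhang by extending the
   complementary strand's recessed 3′ end; filled-in CpGs become
   unmethylated and are flagged in a per-position repair mask. ssLP
   denatures the duplex and keeps each strand at its physical length.
   Sequencing samples one strand per fragment uniformly; read 1 starts at
   the molecule's 5′ end, read 2 at its 3′ end. Geometry therefore places
   fill-in product at the 5′ start of read 2, reproducing the read-2 M-bias
   of end-repaired libraries. (Real urinary dsLP data also show a read-1
   bias whose cause is not established; the model does not attempt it.)
4. **Conversion.** Enzymatic conversion reads an unmethylated C as T with
   probability `conversion_rate` (default 0.994, matching typical EM-seq
   conversion) and a methylated C as C with probability `protection_rate`
   (default 0.99; the protection channel itself is near-complete, and
   apparent spike-in methylation below that reflects other artifacts).
   5-hmC is treated as methylated — the chemistry protects both. Fully
   methylated pUC19 and unmethylated lambda spike-ins pass through the same
   channel. CHH cytosines (default 20 per fragment, true methylation 0.003)
   go through the conversion channel only, so the apparent CHH rate is
   dominated by conversion failure; no library-specific CHH difference is
   modelled.

All randomness flows from `SimConfig.seed` through per-stage child streams
(fragments / jags / conversion / spike-ins). Conversion noise is drawn for
every fragment CpG whether or not the prepared molecule covers it, which
couples matched-seed ssLP and dsLP runs by common random numbers: with
`jag_prob = 0` the two libraries are bit-identical, and with jag every
difference is attributable to end repair rather than to noise resampling.

## Reference atlases

`make_toy_atlas` builds matched site-based and fragment-level references
over a synthetic chromosome: one marker block of `n_sites_per_tissue` CpGs
(10 bp spacing, 1 kb inter-block gaps so fragments never straddle blocks)
per tissue, hypomethylated (`low_beta`, default 0.1) in the target tissue
and `high_beta` (default 0.9) elsewhere. Encoding specificity as
hypomethylation keeps the two atlases consistent, since the fragment-level
method counts mostly-unmethylated fragments. The reference U fraction is
computed analytically as `BinomCDF(floor(0.25 k); k, beta)` for a fragment
covering all `k` block CpGs. Real published atlases (25-tissue site-based,
36-cell-type fragment-level) are emulated in shape only; their contents are
not reproduced.

## Analysis stack

* **Site counts** honour a per-read 5′ trim (`TrimPolicy`; the scenario
  runner uses 2/2 for ssLP and 2/5 for dsLP) and mate-overlap
  deduplication in which the read-1 call wins — the common extractor
  convention; the winner does not matter here because both mates report the
  same converted molecule.
* **M-bias** is computed on untrimmed calls (it is the diagnostic that
  motivates trimming). Flatness is summarized as the maximum per-position
  |z| against the pooled mean with binomial SEs; shape is tested by a
  hand-rolled pool-adjacent-violators isotonic fit whose call-weighted RMS
  residual (in SE units) measures consistency with a monotone
  non-decreasing profile over the fill-in region.
* **JI-U** pools window calls across fragments before forming
  `(M1 − M2)/M1 × 100` (robust at low per-read CpG counts), with M1 the
  first 30 bp of read 1 and M2 the first 30 sequenced bp of read 2 — the
  window at the molecule's 3′ end, where fill-in lands. The alternative
  reading (read-2's own 3′-most 30 bp, `r2_window="three_prime"`) is
  implemented and demonstrably blind to fill-in; it is provided as a
  documented switch. Results with fewer than `min_calls` (default 50) per
  window or M1 = 0 are reported as undefined, never as 0.
* **Site-based deconvolution** minimizes ‖Ax − b‖² with 0 ≤ xᵢ ≤ 1 and
  Σx ≤ 1 by SLSQP (deterministic start 1/T, ftol 1e-9, ≤ 500 iterations);
  the inequality constraint is the only reading consistent with reporting
  an undetermined percentage, which is 1 − Σx. Missing sites are dropped
  row-wise; optional sqrt-coverage row weighting is off by default. An
  exhaustive simplex-grid search (`brute_force_deconv`, T ≤ 4) is the
  independent oracle.
* **Fragment-level deconvolution** classifies each fragment within a block
  as U/X/M by its methylated-call fraction (≤ 0.25 / ≥ 0.75, ≥ 3
  informative CpGs; boundaries inclusive, '.' ignored), regresses observed
  block U fractions on the reference by NNLS over blocks with ≥ 10
  classified fragments, and normalizes the weights to proportions (raw
  weights also reported).
* **Comparisons** use two-sided paired/unpaired t-tests with Bonferroni
  correction over an explicitly recorded family (here: the metric × fluid
  panel of one grid). Zero-variance nonzero differences raise a degenerate-
  input error rather than emitting p = 0; identical inputs give p = 1.

## Scenario grid and problem sizes

`run_scenario_grid` executes plasma-like (jag_prob 0.3, mean jag 8 bp) ×
urine-like (0.8, 25 bp) × {ssLP, dsLP} on matched seeds, optionally
down-sampling all runs of a replicate to a common depth before analysis.
The presets are illustrative parameterizations chosen so the fluids are
ordered in jaggedness; they are not estimates from data. Desk-scale sizes
are used throughout: 12k fragments per grid run, 50k for mixture-recovery
studies, 1e5 spike-in calls — large enough that binomial error is well
below the effect sizes of interest.

## What the simulation does and does not show

Passing tests demonstrate that the analysis stack correctly recovers known
mixtures from unbiased data, that the end-repair mechanism alone reproduces
the qualitative phenomenology (read-2 M-bias ramp, depressed global
methylation, inflated undetermined fraction, JI-U ordering urine > plasma,
JI-U ≈ 0 for ssLP regardless of jaggedness), and that both deconvolution
algorithms respond to the bias differently (site-based: undetermined
absorbs it; fragment-level: spurious shifts in recovered composition). The
synthetic genome has three equivalent marker blocks and two-level betas, so
absolute metric values (e.g. global methylation ≈ 63% under the default
mixture) are properties of the toy atlas, not predictions for human data;
real-data features not emulated include sequence-dependent coverage,
atlas noise and collinearity between related cell types, PCR duplication,
the unexplained read-1 bias of urinary dsLP data, and library-specific CHH
differences.

## Numerical and degenerate-input conventions

Zero informative calls, empty spike-in sets, empty comparison families and
underdetermined fits raise explicit errors instead of returning 0. M-bias
positions without calls are NaN. SLSQP failures raise with solver status.
Proportion vectors are clipped to [0, 1] and renormalized only when the sum
exceeds 1 by floating-point error; the undetermined fraction is floored at
0. The PAVA fit and simplex grid are exact (no tolerance parameters).
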