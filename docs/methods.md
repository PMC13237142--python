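# Methods

## Overview

`kdprof` models concentration-dependent affinity enrichment: an immobilized
small-molecule ligand (here, biotinylated inositol-pyrophosphate analogs) is
presented to a cell lysate over an 11-point concentration series, captured
proteins are quantified by TMT reporter ions, and the per-protein enrichment
curve is summarized by an apparent dissociation constant K_D^app. Everything
downstream — binder classification, probe-vs-probe differential enrichment,
the compound-specificity ANOVA, over-representation analysis, and the
pyrophosphoprotein candidate funnel — consumes the outputs of that core fit.
The package is exercised end-to-end on synthetic data with known ground
truth, so every stage has a recoverable right answer.

## Titration design

The default design is a zero-ligand control plus ten three-fold dilution
steps down from 100 µM (exact values `100/3^k`, k = 9..0), one TMT channel
per concentration, three biological replicates, four probes, and four lysate
conditions (cytosolic/nuclear × EDTA/Mg²⁺). Display rounding (33.3, 11.1,
0.005 µM, …) is cosmetic; computations use the exact grid. The design object
validates that concentrations are strictly increasing after the leading 0.

## Dose–response model and fit-acceptance cascade

Per protein, each replicate's channel vector is divided by its own maximum
("max-normalization"), replicates with any missing channel are discarded
(a protein must be *fully quantified* in a replicate to use it), and
proteins quantified in at least two replicates are averaged channel-wise
(mean ± SEM). Max-normalization is per protein by default because it makes
replicate curves commensurable before averaging; a per-sample variant is
available behind a switch.

The mean profile is fit with the Hill-like binding isotherm

    R(c) = b + (t − b) · c^h / (c^h + K^h),   t ≥ b ≥ 0,  h > 0,

which is finite at c = 0, so the control channel constrains the baseline
directly. K is reported as K_D^app in µM. The direction constraint t ≥ b
encodes the assay physics — enrichment cannot decrease with more immobilized
ligand — so decreasing profiles fail the fit rather than producing a
spurious K.

Numerics: for fixed (K, h) the optimal (b, t) solve a 2×2 constrained
linear least-squares problem analytically, so the nonlinear search runs
over (log₁₀K, h) only. A vectorized coarse grid (24 log-spaced K × 9
slopes) seeds a bounded trust-region polish (`scipy.optimize.least_squares`,
ftol/xtol/gtol 1e-12); near-ties prefer the smaller slope. K is bounded to
[c_min/20, 20·c_max] and h to (0, 10]; a solution at a bound is flagged
`boundary`. Non-convergence yields a flagged result, never an exception.
On noiseless profiles the fit recovers (K, h) to ~1e-12 relative error and
agrees with an exhaustive grid-search oracle within grid resolution.

A fit is accepted (`pass_all`) only if it clears three gates, all
configurable with these defaults:

* coefficient of determination R² ≥ 0.9 (computed over channel means);
* extra-sum-of-squares F-test against the constant-mean null, p ≤ 0.05,
  with df₁ = 3 and df₂ = n_channels − 4 (7 for the default design);
* log₂ fold-change between the top-concentration and zero-control channel
  means ≥ 1, with an epsilon floor of half the smallest positive mean so a
  zero control cannot produce an infinite ratio.

Pearson tiers (moderate/good/perfect at r > 0.90/0.95/0.99) are descriptive
annotations and deliberately not part of `pass_all`. Accepted binders are
classified by strict cutoffs K_D^app < 1 / < 5 / < 25 µM (`sub1`/`sub5`/
`sub25`, else `weak`); the < 5 µM tier is the physiologically motivated
cutoff for the less abundant pyrophosphate species. Binder sets are
compared by pairwise overlap, either in full or truncated to the top N by
ascending K_D^app (ties broken by protein id).

## Differential statistics

Probe-vs-probe comparisons use the single channel nearest 33.3 µM across
multiplexes. Zeros are treated as missing at ingest; intensities are
log₂-transformed; proteins must be quantified in ≥ 2 of 3 replicates in at
least one condition; each sample is median-shifted to the common median.
The two-group test is a linear-model t-test with empirical-Bayes variance
moderation: the prior (d₀, s₀²) is estimated by moment matching on
log-variances through digamma/trigamma relations (trigamma inverted by
Newton iteration), posterior variances are
s̃² = (d₀s₀² + d·s²)/(d₀ + d), and the moderated t has d₀ + d degrees of
freedom. Two degenerate regimes are handled explicitly: literally identical
variances pool to that exact common value (moderation is a no-op), while a
spread smaller than chi-square sampling noise pools to the bias-corrected
moment estimate, keeping null p-values uniform. The implementation matches
the reference R implementation (limma) to machine precision on
heterogeneous-variance data. Significance uses |log₂FC| > 1 and p < 0.05
(static mode); dynamic mode derives thresholds as median ± 2.5·MAD of the
fold-change distribution (raw MAD, factor configurable) and falls back to
static below 50 results or at zero MAD.

The compound-specificity screen imputes left-censored missing values with a
MinProb draw: per sample, missing entries ~ Normal(µ, σ) with µ the 0.01
quantile of that sample's observed values and σ = tune_sigma × the median
per-protein SD (per-protein SDs computed across samples, median over
proteins observed in that sample; the sample SD is the fallback when no
protein has two observations). The completed matrix enters a main-effects
three-way ANOVA (compound + fraction + treatment, no interactions — the
selection rule names exactly three effects), computed vectorially from QR
projections of the shared balanced design; per-factor p-values receive BH
correction across proteins, and `compound_specific` requires
q_compound < 0.05 with q_fraction and q_treatment ≥ 0.05. Selected rows are
z-scored (sample SD, n − 1) and clustered with Euclidean distance and
complete linkage, matching common heatmap-tool defaults; zero-variance rows
are excluded and reported.

## Over-representation analysis

Binder lists are tested against GMT gene sets with the one-sided
hypergeometric upper tail (equivalent to one-sided Fisher), computed via
the survival function for numerical stability, BH-adjusted across sets.
The background universe must be supplied explicitly — typically all
quantified proteins — because no default background is defensible. iBAQ
rank annotation orders proteins by abundance and reports each highlighted
binder's rank and −log₁₀(iBAQ) plus the span in orders of magnitude, the
check that high-affinity hits are not simply the abundant proteins.

## Pyrophosphoprotein candidate funnel

Candidates are proteins with at least one Ser/Thr phospho-acceptor that (a)
sits in a kinase motif of the acidophilic or proline-directed class and (b)
lies inside an intrinsically disordered region. Motifs are position-indexed
residue-class constraints anchored on the acceptor; the shipped defaults
are documented approximations (proline-directed: P at +1; acidophilic:
D/E at +2 or +3, or D/E at −3) and are user-overridable — no fidelity to
proprietary scoring matrices is claimed. Disorder is profiled by a sliding
window (21 residues, shrinking symmetrically at termini) over the TOP-IDP
residue propensity scale min-max scaled to [0, 1], thresholded at 0.5 into
maximal closed intervals; externally computed per-residue disorder scores
can be imported, in which case only the thresholding applies. Coordinates
are 1-based closed throughout.

The mass utilities compute monoisotopic masses from standard atomic masses
(pyrophosphate H₄P₂O₇ = 177.9432 Da, the neutral loss that triggers EThcD
re-acquisition of pyrophosphopeptide precursors) and test whether a
precursor/fragment m/z gap matches that loss at a given charge within a
ppm tolerance (default 20 ppm, the usual MS2 tolerance regime).

## Synthetic data generator

The generator emulates the statistical structure of reporter-ion titration
data, not the spectra: per (protein, probe, condition) a protein is a
binder with configurable probability; binders follow the Hill curve with
K log-uniform over the configured range, slope h ~ U[0.8, 1.5], baseline
response ~ U[0.02, 0.15] of the unit plateau; non-binders are flat. Channel
abundances are the response times a per-protein base abundance drawn
log₁₀-normal(6, 1.1) — spanning more than four orders of magnitude, so it
doubles as an iBAQ proxy. Noise is multiplicative lognormal with CV 0.12
(typical of reporter-ion quantification; keeps intensities positive), and
dropout is missing-not-at-random: values in the lowest global intensity
decile are set missing with probability 0.10. Ground truth (binder flags,
K, h, baseline/plateau, base abundance) is always written as a sidecar.
Replicate-level variability differs between instruments and labeling
batches, so the CV is a documented stand-in exposed as a parameter.

Sequence fixtures are built from residue pools that exclude Ser/Thr except
where motifs are planted, so the funnel truth is exact by construction;
ordered blocks use order-promoting residues, the central disordered block
uses disorder-promoting ones, and planted sites keep a 15-residue margin
from block edges so the windowed score is unambiguous. Gene-set fixtures
can force an exact engineered overlap with a query list. What the
generator does not emulate: reporter-ion interference and isotope impurity,
peptide-to-protein roll-up, correlated replicate effects, batch structure,
and real disorder/motif statistics — passing tests demonstrate correctness
of the statistical machinery under the stated model, not performance on
real lysate data.

## Pipeline and reproducibility

The `run` command executes simulate → ingest → normalize/merge → fit →
classify → overlap → differential → ANOVA/clustering → enrichment →
candidate screen, with per-stage enable flags. A single global seed fans
out to per-stage generators via `numpy.random.SeedSequence([seed,
stage_id])`, so stages are independently reproducible; two runs with the
same seed produce byte-identical result tables, verified by SHA-256 digests
recorded in the run manifest alongside the full config snapshot.

Problem sizes used by the shipped checks (the package's own choice of
desk-scale defaults): 1000 binders for parameter recovery, 5000 flat
proteins for false-positive control, 2000 proteins for null calibration,
200 simulation runs for FDR control, 400 sequences for the funnel, and a
1000-protein × 4-probe × 4-condition demo (500 proteins in the acceptance
script's determinism check, which runs the demo twice).

## Known limitations

* K_D^app is assay-conditioned (immobilized, derivatized ligand;
  non-equilibrium washes) and will deviate from thermodynamic K_D; values
  are comparative, not absolute.
* K values outside roughly the channel range [0.005, 100] µM are not
  identifiable from the design and either hit the fit bounds (flagged) or
  fail the cascade.
* The F-test operates on channel means (df₂ = 7), not on all replicate
  points; a per-point mode would change its calibration.
* The built-in disorder engine is a propensity smoother, not an
  energy-based predictor; for fidelity to dedicated predictors, import
  their per-residue scores.
* Duplicate protein-group rows are rejected rather than aggregated;
  upstream summarization is out of scope.
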