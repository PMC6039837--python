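# Methods

This note documents the models, estimators and numerical choices behind
`megnet_vns`, and what the synthetic data does and does not emulate.

## Phase-locking connectivity

Functional connectivity between two sensors is the phase-locking value

    PLV = | E[ exp( j (phi_1(t) - phi_2(t)) ) ] |,

the magnitude of the time-averaged unit phasor of the instantaneous phase
difference.  PLV is amplitude-blind: it detects weak synchronisation
regimes in which phases couple while amplitudes do not, which is why it is
the connectivity measure of choice for epilepsy cohorts where excessive
neuronal synchrony is the phenomenon of interest.

Estimation follows the epoch-then-bin convention:

1. each run is analysed in 25 one-Hz-wide bins with centers 4, 5, …, 28 Hz
   (the nominal 4–30 Hz range; see *Bin grid* below);
2. per bin, the continuous run is band-pass filtered (zero-phase Butterworth,
   order 4 via forward–backward second-order sections, 1 Hz bandwidth) and
   the instantaneous phase extracted with the analytic signal (Hilbert);
3. the phase series is segmented into consecutive non-overlapping 3-s
   epochs (trailing remainder discarded), PLV is computed per epoch, and
   averaged across epochs;
4. bin-level PLV is averaged over the bins of each canonical band:
   theta [4, 8) Hz (bins 4–7), alpha [8, 12) Hz (bins 8–11),
   beta [12, 30) Hz (bins 12–28).

The averaging order — epochs first, then bins — is pinned by a unit test,
because swapping it changes the estimate.

*Filtering on the continuous run.*  Band-passing 3-s segments with a
1-Hz-wide IIR filter leaves most of each segment inside the filter
transient, so the implementation filters the whole run once per bin and
epochs the resulting phase series instead.  The per-epoch estimator is
unchanged; only the phase extraction is better conditioned (and ~100×
cheaper).  `bin_phase` still accepts arbitrary segments with an explicit
`trim_edges` parameter for callers who need per-segment filtering.

*Bin grid.*  A 4–30 Hz range in 1-Hz steps would give 27 values; the bin
count is fixed at 25 with centers 4…28 Hz so that the count, the 1-Hz
spacing and the band edges are all preserved.  Band membership is decided
by the bin center with half-open intervals.

## Cost thresholding and graph measures

A PLV matrix is binarised by retaining the strongest fraction *C* (the
*cost*) of its `n(n-1)/2` possible edges — exactly `ceil(C·m)` edges, with
ties at the cutoff broken by ascending (row, col) index so the edge count
is deterministic.  Because the retained edge set is nested in *C*, global
efficiency is non-decreasing in cost.

The analysis cost is fixed at **C = 0.10** for every subject and band.  The
calibration utility `gce_scan` reproduces the procedure that justifies it:
global cost efficiency `GCE(C) = E(C) − C`, with `E` the mean inverse
shortest-path length over ordered pairs, has a positive interior maximum
near 10% cost on economical small-world networks; the scan's default grid
is 0.01–0.50 in steps of 0.01 and the first maximum wins ties.

Three global measures are computed on the binary graph:

* **Modularity Q** — quality of the best community partition (segregation).
  Optimised with the Leiden refinement of Louvain-style greedy multilevel
  moving (`leidenalg`), 100 seeded restarts by default, resolution γ = 1;
  Q of the winning partition is evaluated with the standard Newman formula.
  Leiden was chosen over a pure Louvain implementation because it is
  seeded, deterministic, C-fast, and does not suffer from the
  oscillation-non-termination failure mode of greedy node moving on small
  graphs; on all ≤8-node test graphs it attains the exhaustive-search
  optimum.
* **Transitivity T** — `3·triangles / connected triples`, defined as 0 when
  no length-2 path exists.
* **Characteristic path length (CPL)** — mean shortest-path length over
  reachable unordered pairs.  Disconnected graphs average over reachable
  pairs only and record the reachable-pair fraction; an edgeless graph is
  an error, not a number.

Graphs are **binary** after thresholding, with a weighted CPL/efficiency
mode (distance = 1/weight) available behind a flag.  Published CPL
magnitudes of ~0.04–0.09 on comparable data are not reproducible under any
standard binary or weighted convention we identified; we therefore pin the
textbook binary definitions and make no attempt to match those magnitudes.
Measures are computed per run and averaged over a subject's (three) runs,
except for the reliability analysis, which consumes the per-run values.

## Synthetic cohort

The generator produces multichannel oscillatory time series whose pairwise
phase coupling is controllable, not biophysically modelled.  Channel *c*'s
signal is a sum over the 25 analysis bins of unit-amplitude cosines whose
phase is a weighted mixture of three random walks (diffusion 4 rad²/s,
shared across components):

    theta_c = sqrt(w)·Psi_module(c) + sqrt(l_c)·Psi_global
              + sqrt(1 − w − l_c)·Xi_c

Squared mixture weights sum to one, so every channel has the same marginal
phase diffusion and signal variance; only between-channel phase correlation
varies.  `w` is the group's within-module coupling; `l_c` is the channel's
global-coupling weight.  Global weights are *bimodal*: a per-subject random
"core" subset (40% of channels) couples at the full group strength, the
periphery at 10% of it.  A strong global component therefore creates a
densely synchronised core whose retained edges form a hub-like clique —
raising transitivity and eroding modularity — while strong within-module
coupling concentrates retained edges inside the ground-truth modules,
raising modularity.

Default group profiles (within, global): controls (0.52, 0.05), responders
(0.36, 0.52), non-responders (0.22, 0.72).  These were calibrated once, on
theta-band group medians, to reproduce the qualitative clinical pattern —
modularity controls > responders > non-responders and transitivity the
reverse — which is the only constraint the study design imposes; effect
*magnitudes* are unconstrained and not matched to any published table.
Patient runs default to 300 s and control runs to 360 s (5- vs 6-minute
sessions) at 508.6 Hz with 248 channels; tests and the acceptance script
use 24 channels, 24-s runs at 128 Hz, which preserves the pattern at a
fraction of the cost.  Sedation is flagged for half the patients but has
no simulated effect (an effect-size knob exists for power experiments).

What the generator does **not** emulate: sensor geometry and field spread,
1/f spectra and amplitude dynamics, artifacts, head movement, and —
importantly — realistic *between-subject* variability within a group.
Subjects of the same group differ only in their random core membership and
small loading jitter; synthetic controls are therefore nearly exchangeable,
and their test–retest ICC is near zero by construction even though the ICC
machinery itself is verified against closed forms.  Passing tests show the
pipeline's estimators and the group-level pattern are correct, not that
reliability or heritability magnitudes of real MEG are reproduced.

## Twin traits and heritability

Quantitative traits on a pedigree follow the AE variance-components model:

    sigma_p² = sigma_g² + sigma_e²,    Omega = 2Phi·sigma_g² + I·sigma_e²,
    h² = sigma_g² / sigma_p²

with the relatedness matrix 2Φ equal to 1 for MZ co-twins, ½ for DZ
co-twins and full siblings, 0 across families, 1 on the diagonal.  There is
no shared-environment (C) component, and environmental effects are taken as
uncorrelated among family members.

Estimation is maximum likelihood.  2Φ is eigendecomposed once; in its
eigenbasis the covariance is diagonal (`h²·λ_i + 1 − h²` up to the profiled
scale σ_p²), so the likelihood is profiled over h² on [0, 1] with GLS fixed
effects and closed-form σ_p² at each ratio, and a bounded 1-D search
(tolerance 1e-6) finds the optimum — no multivariate optimiser.
Significance of h² uses the likelihood-ratio test against σ_g² = 0 with the
boundary-corrected null mixture ½χ²₀ + ½χ²₁ (Λ = 0 ⇒ p = 0.5); the
significance threshold is p < 0.01, uncorrected.

Traits are rank-based inverse-normal transformed (Blom offsets,
`(r − 3/8)/(n + 1/4)`, ties share the mean rank) *before* the fit, and the
standard covariate block — sex, age, age², age×sex, age²×sex, with age
centred — enters as fixed effects inside the ML fit; a residualise-first
option exists.  The reported "variance explained by covariates" is the
covariates-only OLS R², labelled as such.  The twin-trait simulator draws
the genetic component through an eigen-factorisation of 2Φ (exact for the
singular MZ blocks), with σ_g² = h² and σ_e² = 1 − h² before covariate
effects.

In the orchestrated pipeline, heritability runs on simulated twin traits
rather than on graph features of the simulated cohort: the signal generator
controls coupling per *group*, not per genotype, so genetic structure can
only enter through the trait simulator.

## Reliability

Test–retest reliability across the three runs is the two-way-ANOVA
intraclass correlation

    ICC = (MS_b − MS_E) / (MS_b + (k − 1)·MS_E),  k = 3,

with subject and session main effects — algebraically the consistency form
ICC(3,1), which the formula *is*; session-level offsets do not count
against reliability.  Negative estimates are reported as computed and rated
"poor".  Ratings: poor < 0.2 ≤ fair < 0.4 ≤ moderate < 0.6 ≤ good < 0.8 ≤
excellent.  The patient groups are pooled into a single "patients" stratum.

## Group statistics

Responder/non-responder differences per feature (3 measures × 3 bands) use
a two-way ANOVA with factors VNS response and sedation status, fit as a
main-effects model with Type II sums of squares (the design is unbalanced
and the interaction is omitted).  Because equal-variance assumptions fail
for some measures, the null distribution of each F is built
non-parametrically: residuals of the reduced model (the factor of interest
removed) are resampled with replacement (default n = 10,000), added back to
the reduced fit, and F recomputed; `p = (1 + #{F* ≥ F})/(n_boot + 1)`.
A case-resampling alternative is available behind a flag.  Measured type-I
error at the clinical design sizes (9 vs 14, α = 0.05) is ≈0.05.

The nine response p-values are Benjamini–Hochberg FDR-adjusted at the 0.05
level, and the BH critical values `(i/m)·q` are emitted alongside for
transparency.  Control-vs-patient-group comparisons use the two-sided
Wilcoxon rank-sum (Mann–Whitney) test — exact null for small tie-free
samples, tie-corrected normal approximation otherwise.  A paired
signed-rank mode exists but deliberately errors on unequal sample sizes:
a paired test is not computable between 89 controls and 14 or 9 patients,
so the unpaired rank test is the default for that comparison.

## Classification

Three groups — non-responder (NR), responder (R), control (C) — are
classified with Gaussian naive Bayes: empirical class priors, per-class
per-feature Gaussian likelihoods, variances floored at 1e-9 × the largest
feature variance, posterior ties resolved to the lexicographically first
class.  Features are transitivity and modularity (CPL is excluded: it does
not separate the patient groups), in four menus: theta, alpha, or beta
(2 features each), or all three bands (6 features).  No standardisation:
GNB is location-scale parametric per class.

Validation is stratified 10-fold cross-validation.  Folds are dealt
round-robin per class after shuffling, so fold sizes differ by at most one
and every training set retains all classes even though the NR class (9
members) is smaller than the fold count — plain stratified splitters
refuse this design.  Because controls outnumber the patient groups, each
repetition draws 14 controls without replacement, cross-validates the
resulting 9 + 14 + 14 cohort, and the confusion matrix (rows = actual,
summing to 9/14/14), one-vs-rest metrics and AUCs are averaged over 1000
repetitions as real numbers, rounding only for display.

Per-class metrics are one-vs-rest: sensitivity TP/actual, specificity
TN/actual-negatives, PPV TP/predicted-positive (undefined → NaN, never 0),
accuracy (TP+TN)/total, and the Mann–Whitney AUC of the class posterior
(ties ½).  Weighted averages weight classes by size (9, 14, 14); NaNs are
excluded with weights renormalised.  The chance level of the three-class
problem is 33%; a `permute_labels` mode re-shuffles labels inside every
repetition to realise that null empirically.

## Orchestration and reproducibility

A single master seed is expanded into per-stage child seeds with
`numpy.random.SeedSequence.generate_state` under fixed stage names
(cohort, graph, pedigree, stats, classify), so stages re-run independently
yet reproducibly; the same seed yields byte-identical tables.  Every run
emits a provenance record (package version, master and stage seeds, full
config) sufficient to reproduce any output.  All tables are written as TSV
and Markdown.

## Problem sizes

Full-scale defaults (248 channels, 5–6-minute runs, 1000 repetitions,
10,000 bootstrap draws) are what a real analysis would use.  The test
suite and the acceptance script run the same code on scaled-down cohorts —
24 channels, 24-s runs at 128 Hz, 3 runs per subject, 20 Leiden restarts,
500 CV repetitions, 500 bootstrap draws per dataset — sizes chosen so the
group pattern, calibration rates and recovery targets are measured with
adequate Monte-Carlo precision while the whole pipeline stays
single-CPU-friendly.

## Known limitations

* Within-group between-subject variance is minimal (see above): synthetic
  control ICCs are near zero and no attempt is made to match published
  reliability or heritability magnitudes of graph features; heritability is
  validated by parameter recovery on simulated twin traits instead.
* CPL magnitudes on published data are unexplained under standard
  conventions; we report textbook binary CPL.
* The bootstrap-ANOVA null construction (residual resampling under the
  reduced model) is one defensible reading of "bootstrap resampling with
  replacement"; a case-resampling variant is provided for sensitivity
  checks.
* The exact fold-assignment and AUC-averaging conventions of comparable
  published analyses are unstated; stratified folds and class-size-weighted
  AUC averaging are used and documented here.
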