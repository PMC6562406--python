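# Methods

## Substrate model

The reference substrate is mature human H3.1 (initiator Met removed, A = 1);
the peptide families analysed (3–8, 9–17, 18–26, 27–40, 73–83) are identical
in mouse H3, so one reference serves both species. Chemical derivatization is
modelled as a single protein-level d3-acetylation round: every lysine that is
unmodified in vivo carries d3-acetyl (+45.029396 Da exact), every
monomethylated lysine carries d3-acetyl+methyl (+59.045046 Da), and me2, me3
and endogenous ac lysines are unreactive. Peptide N-termini are not
derivatized, and N-terminal (A1) derivatization is off by default. Because
derivatized or modified lysines are never cleaved by trypsin, in-silico
digestion reduces to cleavage strictly C-terminal of arginine; missed
cleavages concatenate adjacent fragments.

Masses use full-precision monoisotopic constants internally (residue masses
from pyteomics; me1 = 14.015650, ac = 42.010565, me3 = 42.046950; proton
1.0072765; Arg-10 delta 10.00827 = 6·Δ13C + 4·Δ15N). The values printed in a
typical search configuration for this workflow (+45.0294, +14.016, +28.031,
+42.046, +42.010, +59.0454) are stored separately as "configured" echoes; the
printed me3/ac values are truncations of the exact values, not roundings, and
are never used for m/z computation. Heavy-channel m/z adds the Arg-10 delta
per arginine before dividing by charge.

The default library opens K4, K9, K14, K18, K23, K27, K36 and K79 to five
states each (derivatized-unmodified, me1-on-derivatized, me2, me3, ac); K37
is held at the derivatized-unmodified state because no reported mark involves
it and the restriction keeps the default library at 85 peptidoforms.

## Quantification

XICs are traced per run by summing all centroids within a ppm window
(default 10 ppm; the target m/z is rounded to four decimals before matching)
per MS1 scan inside a retention-time window (default ±2 min around the
expected apex; the simulated-data drivers use ±0.4 min because simulated
peaks are narrow), and integrated trapezoidally. AUCs of the 2+ and 3+
precursors are summed per form; the light and heavy channels are independent
extractions.

Isobaric peptidoforms — identical modification multisets placed on different
lysines — share one trace. The manual expert curation of the original
workflow is replaced by a deterministic rule: local maxima (above 2% of the
trace maximum, with equal prominence floor) are apexes; the trace is split at
the intensity minima between consecutive apexes; segment areas are assigned
to forms in expected elution order. If fewer apexes are found than forms, the
whole set is flagged unresolved and all its areas are withheld — the paper's
handling of unresolvable co-elution is not stated, and withholding is this
package's convention (guessing an apportionment would bias %RA silently).
Identification filtering keeps records with search score ≥ 60 and site
localization probability ≥ 0.75 (strictly-below semantics, boundary kept).

## Abundance statistics

%RA uses a per-sample observed-forms denominator: forms missing in a sample
shrink that sample's denominator. L/H ratios divide per-channel %RA; a heavy
observation without a light counterpart is dropped, while a light observation
without heavy keeps its %RA but has a missing ratio (the drop rule is stated
only in the heavy-without-light direction). Channel denominators are
per-channel independent by default; a joint mode restricted to forms observed
in both channels exists for sensitivity analysis. Normalization divides each
column by the mean of its present values within a scope (per group or across
all samples — a config switch, since both scopes are used in different
displays); it is idempotent and leaves column means at 1. Condition
comparisons ("ratios of ratios", e.g. G2-M over G1-S) divide matched
replicate rows elementwise.

Total marks sum member %RA within each channel first and then take the
ratio. A ratio of sums is the natural reading of "the L/H ratio of the total
mark" and is invariant to channel scaling; the sum-of-per-form-ratios
alternative is available as a mode. Partially missing members contribute 0
when at least one member is observed (flagged as partial); a channel with no
member observed yields a missing mark.

## Group tests and multivariate displays

Student's t-tests are two-sided with pooled variance (Welch optional),
run on log2 ratios; under the generator's lognormal noise the null is then
exactly normal. Direction is the sign of mean(A) − mean(B); significance
tiers are p < 0.05 (dark) and p < 0.1 (light), with p < 0.05 at only two
measurements per group demoted to light. No multiple-testing correction is
applied to per-form PTM comparisons (the workflow's exploratory convention);
Benjamini–Hochberg FDR (step-up, statsmodels) is applied where a screened
catalogue is interrogated. Identical paired vectors get t = 0, p = 1 by
convention; a constant nonzero paired difference gets p = 0 (unbounded
statistic) — neither arises in practice with continuous data.

Ki-67 correlations are Pearson with the two-sided p from the t transform;
the display rule is the literal r > 0.4 (an absolute-value mode exists, since
the rule's treatment of negative correlations is not stated). PCA filters
samples with more than 10 missing values, then features with no valid value
in one group or more than 5 missing values, imputes the remainder with the
feature mean over retained samples, centers, and decomposes by SVD.
Clustering is UPGMA (average linkage) on correlation distance (1 − Pearson r,
pairwise complete); constant items are excluded and reported; scipy's
linkage provides the deterministic lowest-index tie-break. Dendrograms export
to Newick.

## Synthetic cohorts

The generator emulates the study's structure at desk scale: two groups of 8
matched samples by default, a fixed heavy spike-in profile shared by all
runs, and a group effect expressed as a fold change on the members of a total
mark followed by renormalization of the family to 100. Note the induced mark
ratio differs from the nominal fold change because of renormalization (e.g. a
0.5 fold change on a 20% mark yields 10/90·100 = 11.1%, a mark-ratio change
of 0.556): ground truth is always the renormalized profile, and recovery is
judged against it. Baseline %RA profiles are fixed, literature-plausible
tissue values (e.g. H3K9me2 ≈ 24%, total K14ac ≈ 20% of the 9–17 family);
the real cohort's per-form values live in supplementary datasets that are not
reproduced here, so these defaults are this package's choice.

Noise is multiplicative lognormal on AUCs (sd 0.2 on log2 by default — the
standard model for MS intensities; no noise model is stated in the source
workflow), plus a per-sample, per-channel loading scale (sd 0.3 log2) that
%RA cancels by construction. Missingness drops light-channel observations at
a configured rate (the spike-in is present in every run). The Ki-67 index is
generated as a linear function of the sample's realized (noisy, scale-free)
log2 mark ratio plus Gaussian noise calibrated so the population correlation
equals the configured r, then clipped to [0, 100].

Simulated signals are Gaussian elution peaks (sd 0.08 min, scans every
0.02 min, ±4 sd — ≥ 30 points per peak, keeping trapezoidal integration
error well under 0.5%) at the theoretical light/heavy m/z for charges 2+
(70%) and 3+ (30%), with areas proportional to the true AUCs and optional
uniform m/z jitter in ppm. Within a family, apexes are spaced 0.6 min apart
in enumeration order; shrinking the spacing below the resolvable width emits
co-eluting isobars and exercises the unresolved-flagging path. What the
generator does not model: chromatographic drift and RT misalignment across
runs, isotopic envelopes and interference, profile-mode peaks, MS2, and FFPE
storage artifacts beyond a per-storage-type form-exclusion mask. Passing
tests therefore demonstrate correctness of the quantification arithmetic and
statistics under the assumed noise structure, not robustness to real
chromatographic pathology.

## Enzyme catalogue

The histone-modifying-enzyme table ships with 88 entries — 17
acetyltransferases, 18 deacetylases, 32 methyltransferases, 21 demethylases —
curated from the canonical enzyme families (GNAT/MYST/p300 and nuclear-
receptor coactivators; HDAC1–11 and SIRT1–7; the KMT2/SETD/NSD/SUV39/EZH/
DOT1L/KMT5 sets; KDM1–8 with PHF2/PHF8/JMJD6) with reported substrate
residues per entry. The exact membership of the original 88-gene list is not
printed in the source text, so the packaged file is a documented curated
stand-in that reproduces the class composition; any user TSV with the same
columns replaces it. The consistency report joins significant mark changes
to substrate-matched writers and erasers and scores concordance (writer up ⇒
mark up; eraser up ⇒ mark down).

## Problem sizes

Default test and acceptance runs use the 85-form library, cohorts of 8+8
samples, 100-seed detection loops, and 3 null cohorts (255 feature tests) —
sizes chosen so the full pipeline, including peak-level simulation and
re-quantification of 16 runs, completes in seconds while keeping binomial
uncertainty on the reported rates a small fraction of the acceptance margins.
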