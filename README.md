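# histoptm

Quantification of histone H3 post-translational modifications (PTMs) from
bottom-up LC-MS with a super-SILAC spike-in, and the cohort statistics used to
compare tumor and normal tissues — including the aggregation of combinatorial
peptidoforms into single-residue "total mark" scores such as total H3K14ac.

## Who this is for

Proteomics groups profiling histone marks in clinical cohorts with the
d3-acetic-anhydride derivatization workflow: histones are chemically
d3-acetylated at the protein level (blocking tryptic cleavage at lysines, so
trypsin digests "Arg-C-like", strictly after arginine), digested, and every
modified form of each H3 peptide (3–8, 9–17, 18–26, 27–40, 73–83) is
quantified from its extracted ion chromatogram in a light (patient) and heavy
(Arg-10-labelled spike-in) channel.

## The model

For peptidoform *i* of a peptide family *F*, in one run and channel,

    %RA_i = 100 · AUC_i / Σ_{j ∈ F, observed} AUC_j

where AUC is the trapezoidal area of the XIC traced at the theoretical m/z
(2+ and 3+ summed) within a 10 ppm window. The super-SILAC ratio

    L/H_i = %RA_i(light) / %RA_i(heavy)

cancels per-sample processing variability (it is invariant under any global
rescaling of either channel). A total mark sums its member forms per channel
before taking the ratio, e.g.

    total H3K14ac = K14ac + K9me1K14ac + K9me2K14ac + K9me3K14ac + K9acK14ac

Group differences are tested with two-sided Student's t-tests on log2 L/H
ratios (paired across matched normal–tumor pairs where available), marks are
correlated with the Ki-67 proliferation index (Pearson, displayed at
r > 0.4), samples are clustered by UPGMA on correlation distance, and PCA
applies an explicit missing-value policy (drop samples with >10 missing
values, drop features invalid in a whole group or with >5 missing, impute the
rest with the feature mean). Because no public cohort ships with this
package, a synthetic-data module generates cohorts with known ground truth —
profile, effect sizes, noise — so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a simulated
cohort of 8 matched normal–tumor pairs in which the total-H3K14ac members are
halved in tumors (after family renormalization the mark drops from 20.0% to
11.1%), with lognormal intensity noise of sd 0.2 (log2):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_runs.py
python analysis/03_relative_abundance.py
python analysis/04_marks_and_stats.py
python analysis/05_hme_report.py
```

Output (abridged):

```
total-K14ac truth: normal 20.00%, tumor 11.11% (members renormalized after the 0.5 fold change)
quantified 16 runs, 2720 form/channel AUCs, 6 withheld as unresolved
recovery vs ground truth: median |rel err| = 3.54e-05, max = 1.13e-04
total H3K14ac paired t-test: t = -9.95, p = 2.21e-05, decrease in tumor (dark)
Ki-67 correlations displayed (r > 0.4): total_H3K9me3 (r=0.42)
catalogue: acetyltransferase=17, deacetylase=18, methyltransferase=32, demethylase=21, total=88
consistency report: 12 enzyme-mark pairs, 12 concordant / 0 discordant
```

Reading this: targeted XIC quantification recovers the simulated areas to
~0.01% (isobaric sets that co-elute are withheld, not guessed); the halved
K14ac signal is recovered as a significant decrease in tumors; the Ki-67
index correlates with the mark it was linked to in the simulation; and the
packaged histone-modifying-enzyme (HME) catalogue interprets the mark changes
against enzyme expression changes (here a synthetic table) — e.g. a
downregulated H3K14 acetyltransferase is concordant with a K14ac decrease.

Tables land under `results/` (`quant/auc.tsv`, `abundance/lh_ratios.tsv`,
`stats/mark_tests_paired.tsv`, `stats/sample_dendrogram.nwk`, ...).

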