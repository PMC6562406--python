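#!/usr/bin/env python
"""Aggregate total-mark scores and run the cohort statistics: tumor-vs-normal
t-tests (unpaired and paired on matched pairs), Ki-67 correlations, PCA with
the missing-value policy, and UPGMA clustering on correlation distance.

Reads results/abundance/ and results/sim/, writes results/stats/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from histoptm import abundance as ab
from histoptm import marks
from histoptm import stats as hstats

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(ROOT / "sim" / "metadata.tsv", sep="\t").set_index(
        "sample_id", drop=False
    )
    ra = pd.read_csv(ROOT / "abundance" / "relative_abundance.tsv", sep="\t")
    ratios = pd.read_csv(
        ROOT / "abundance" / "lh_ratios.tsv", sep="\t", index_col=0
    )

    registry = marks.builtin_marks()
    mark_ratios = marks.mark_ratio_matrix(
        registry, ab.ra_matrix(ra, "light"), ab.ra_matrix(ra, "heavy")
    )
    mark_ratios.to_csv(out / "mark_ratios.tsv", sep="\t")

    log2_marks = ab.log2_transform(mark_ratios)
    unpaired = hstats.compare_groups(log2_marks, meta["group"], "tumor", "normal")
    paired = hstats.compare_groups(
        log2_marks, meta["group"], "tumor", "normal",
        paired=True, pairs=meta["pair_id"],
    )
    unpaired.to_csv(out / "mark_tests_unpaired.tsv", sep="\t")
    paired.to_csv(out / "mark_tests_paired.tsv", sep="\t")
    row = paired.loc["total_H3K14ac"]
    print(f"total H3K14ac paired t-test: t = {row['t']:.2f}, "
          f"p = {row['p']:.2e}, {row['direction']} in tumor ({row['tier']})")

    form_tests = hstats.compare_groups(
        ab.log2_transform(ratios), meta["group"], "tumor", "normal"
    )
    form_tests.to_csv(out / "form_tests_unpaired.tsv", sep="\t")
    n_sig = int((form_tests["p"] < 0.05).sum())
    print(f"form-level comparisons: {n_sig} of {form_tests['p'].notna().sum()} "
          "forms at p < 0.05")

    ki_rows = []
    for mark_name in mark_ratios.columns:
        res = hstats.pearson_vs_ki67(
            mark_ratios[mark_name].reindex(meta.index), meta["ki67"]
        )
        ki_rows.append({"mark": mark_name, **res})
    ki = pd.DataFrame(ki_rows).set_index("mark")
    ki.to_csv(out / "ki67_correlation.tsv", sep="\t")
    shown = ki[ki["display_flag"]]
    print("Ki-67 correlations displayed (r > 0.4): "
          + (", ".join(f"{m} (r={r:.2f})" for m, r in shown["r"].items())
             or "none"))

    pca = hstats.pca_with_policy(ab.log2_transform(ratios), meta["group"])
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    print(f"PCA: {len(pca.retained_samples)} samples x "
          f"{len(pca.retained_features)} forms retained; PC1 explains "
          f"{100 * pca.explained_variance_ratio[0]:.1f}% of variance")

    clust = hstats.hcluster(ab.log2_transform(ratios).fillna(0.0))
    (out / "sample_dendrogram.nwk").write_text(hstats.to_newick(clust) + "\n")
    print(f"UPGMA sample dendrogram written ({len(clust.labels)} leaves)")


if __name__ == "__main__":
    main()
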