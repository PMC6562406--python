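#!/usr/bin/env python
"""Turn measured AUCs into %RA per channel, super-SILAC L/H ratios, and the
normalized log2 ratio matrix used for heatmaps and clustering.

Reads results/quant/auc.tsv, writes results/abundance/.
"""

from pathlib import Path

import pandas as pd

from histoptm import abundance as ab
from histoptm import pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    auc = pd.read_csv(ROOT / "quant" / "auc.tsv", sep="\t")
    meta = pd.read_csv(ROOT / "sim" / "metadata.tsv", sep="\t").set_index(
        "sample_id", drop=False
    )
    tables = pipeline.auc_to_ratios(auc)

    out = ROOT / "abundance"
    out.mkdir(parents=True, exist_ok=True)
    tables["ra"].to_csv(out / "relative_abundance.tsv", sep="\t", index=False)
    tables["ratios"].to_csv(out / "lh_ratios.tsv", sep="\t")

    # normalized over the average within each group (the per-tumor-type scope)
    norm = ab.normalize_ratios(tables["ratios"], groups=meta["group"])
    log2norm = ab.log2_transform(norm)
    norm.to_csv(out / "lh_ratios_normalized.tsv", sep="\t")
    log2norm.to_csv(out / "lh_ratios_log2_normalized.tsv", sep="\t")

    n_missing = int(tables["ratios"].isna().sum().sum())
    print(f"L/H ratio matrix: {tables['ratios'].shape[0]} samples x "
          f"{tables['ratios'].shape[1]} forms, {n_missing} missing ratios")
    col_means = norm.mean(axis=0, skipna=True)
    print(f"normalized column means: {col_means.min():.6f}..{col_means.max():.6f} "
          "(1 by construction within scope)")


if __name__ == "__main__":
    main()
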