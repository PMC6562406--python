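#!/usr/bin/env python
"""Interpret the measured mark changes against the histone-modifying-enzyme
catalogue: class composition and a writer/eraser concordance report.

The enzyme expression table used here is synthetic (generated below with a
fixed seed, labelled as such) — in a real analysis it would be the exported
result of an external differential-expression run. Reads results/stats/,
writes results/hme/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from histoptm import hme
from histoptm.stats import bh_fdr

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20190525


def synthetic_expression_table(catalog: pd.DataFrame) -> pd.DataFrame:
    """Synthetic enzyme log2 fold changes: K14 acetyltransferases pushed down,
    K9 methyltransferases pushed up, everything else null noise."""
    rng = np.random.default_rng(SEED)
    lfc = rng.normal(0.0, 0.3, size=len(catalog))
    raw_p = rng.uniform(0.2, 1.0, size=len(catalog))
    for i, row in enumerate(catalog.itertuples(index=False)):
        subs = str(row.substrates).split(";")
        if row._1 == "acetyltransferase" and "H3K14" in subs:
            lfc[i] = rng.normal(-1.5, 0.3)
            raw_p[i] = rng.uniform(1e-6, 1e-3)
        elif row._1 == "methyltransferase" and "H3K9" in subs:
            lfc[i] = rng.normal(1.2, 0.3)
            raw_p[i] = rng.uniform(1e-6, 1e-3)
    padj = bh_fdr(raw_p)["padj"]
    return pd.DataFrame(
        {"symbol": catalog["symbol"], "log2fc": lfc, "padj": padj}
    )


def main() -> None:
    out = ROOT / "hme"
    out.mkdir(parents=True, exist_ok=True)
    catalog = hme.load_catalog()
    counts = hme.class_counts(catalog)
    pd.Series(counts).rename_axis("class").rename("n").to_csv(
        out / "class_counts.tsv", sep="\t"
    )
    print("catalogue: " + ", ".join(f"{k}={v}" for k, v in counts.items()))

    tests = pd.read_csv(
        ROOT / "stats" / "mark_tests_unpaired.tsv", sep="\t", index_col=0
    )
    mark_changes = (
        tests[tests["p"] < 0.05]
        .reset_index()[["feature", "direction"]]
        .rename(columns={"feature": "mark"})
    )
    expr = synthetic_expression_table(catalog)
    expr.to_csv(out / "synthetic_expression_changes.tsv", sep="\t", index=False)
    report = hme.consistency_report(mark_changes, catalog, expr)
    report.to_csv(out / "consistency_report.tsv", sep="\t", index=False)
    conc = report["concordant"].dropna()
    print(f"consistency report: {len(report)} enzyme-mark pairs, "
          f"{int(conc.sum())} concordant / {int((~conc).sum())} discordant")


if __name__ == "__main__":
    main()
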