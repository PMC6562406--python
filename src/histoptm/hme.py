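"""Histone-modifying-enzyme annotation and writer/eraser concordance.

The packaged catalogue lists 88 known or putative HMEs across four classes
(17 acetyltransferases, 18 deacetylases, 32 methyltransferases, 21
demethylases) with their reported substrate residues. It is a curated
stand-in assembled from the canonical enzyme families; any user file with the
same columns replaces it. The consistency report asks, for each measured mark
change, whether the expression changes of substrate-matched writers and
erasers point the same way (writer up predicts mark up, eraser up predicts
mark down).
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

CLASSES = (
    "acetyltransferase",
    "deacetylase",
    "methyltransferase",
    "demethylase",
)

_SUBSTRATE_RE = re.compile(r"^H[1-4][KR]\d+$")
_MARK_RE = re.compile(r"(H[1-4]K\d+)(me\d?|ac)")

# Which enzyme class writes / erases each modification kind.
_WRITER = {"ac": "acetyltransferase", "me": "methyltransferase"}
_ERASER = {"ac": "deacetylase", "me": "demethylase"}


def load_catalog(path=None) -> pd.DataFrame:
    """The HME catalogue (columns: symbol, class, substrates, notes)."""
    if path is None:
        ref = resources.files("histoptm") / "data" / "hme_catalog.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"symbol", "class", "substrates"}
    if not required <= set(df.columns):
        raise ValueError(f"catalogue must have columns {sorted(required)}")
    if df["symbol"].duplicated().any():
        dup = df.loc[df["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate catalogue symbols: {dup}")
    bad_class = set(df["class"]) - set(CLASSES)
    if bad_class:
        raise ValueError(f"unknown enzyme classes: {sorted(bad_class)}")
    for _, row in df.iterrows():
        for sub in str(row["substrates"]).split(";"):
            if not _SUBSTRATE_RE.match(sub):
                raise ValueError(
                    f"substrate {sub!r} of {row['symbol']} is not a "
                    "histone-residue token (e.g. H3K14)"
                )
    return df


def class_counts(catalog: pd.DataFrame) -> dict[str, int]:
    """Enzymes per class plus the total."""
    counts = {c: int((catalog["class"] == c).sum()) for c in CLASSES}
    counts["total"] = int(len(catalog))
    return counts


def parse_mark(mark_name: str) -> tuple[str, str]:
    """(residue, modification kind) from a mark name.

    ``total_H3K14ac`` -> ("H3K14", "ac"); ``total_H3K9me3`` -> ("H3K9", "me").
    """
    m = _MARK_RE.search(mark_name)
    if not m:
        raise ValueError(f"cannot parse a histone residue from {mark_name!r}")
    kind = "ac" if m.group(2) == "ac" else "me"
    return m.group(1), kind


def consistency_report(
    mark_changes: pd.DataFrame,
    catalog: pd.DataFrame,
    expression_changes: pd.DataFrame,
    padj_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Writer/eraser concordance between mark and enzyme-expression changes.

    ``mark_changes`` needs columns ``mark`` and ``direction``
    (increase/decrease); ``expression_changes`` needs ``symbol`` and
    ``log2fc`` (optional ``padj``, filtered at ``padj_cutoff``). Expression
    symbols absent from the catalogue are reported with role ``unmatched``.
    """
    for col in ("mark", "direction"):
        if col not in mark_changes.columns:
            raise ValueError(f"mark_changes missing column {col!r}")
    for col in ("symbol", "log2fc"):
        if col not in expression_changes.columns:
            raise ValueError(f"expression_changes missing column {col!r}")
    expr = expression_changes.copy()
    if "padj" in expr.columns:
        expr = expr[expr["padj"] < padj_cutoff]
    by_symbol = catalog.set_index("symbol")
    rows = []
    unmatched = expr.loc[~expr["symbol"].isin(by_symbol.index), "symbol"]
    for sym in unmatched:
        rows.append(
            {
                "mark": "", "enzyme": sym, "class": "", "role": "unmatched",
                "enzyme_direction": "", "mark_direction": "",
                "concordant": pd.NA,
            }
        )
    matched = expr[expr["symbol"].isin(by_symbol.index)]
    for mrow in mark_changes.itertuples(index=False):
        residue, kind = parse_mark(mrow.mark)
        mark_up = mrow.direction == "increase"
        for erow in matched.itertuples(index=False):
            cat = by_symbol.loc[erow.symbol]
            if residue not in str(cat["substrates"]).split(";"):
                continue
            if cat["class"] == _WRITER[kind]:
                role = "writer"
            elif cat["class"] == _ERASER[kind]:
                role = "eraser"
            else:
                continue
            enz_up = erow.log2fc > 0
            concordant = (enz_up == mark_up) if role == "writer" else (
                enz_up != mark_up
            )
            rows.append(
                {
                    "mark": mrow.mark,
                    "enzyme": erow.symbol,
                    "class": cat["class"],
                    "role": role,
                    "enzyme_direction": "up" if enz_up else "down",
                    "mark_direction": mrow.direction,
                    "concordant": bool(concordant),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mark", "enzyme", "class", "role", "enzyme_direction",
                 "mark_direction", "concordant"],
    )
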