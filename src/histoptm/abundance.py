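"""Relative abundances and super-SILAC ratios.

%RA of a peptidoform is its XIC area divided by the summed areas of all
*observed* forms of the same peptide family, in the same sample and channel,
times 100 — so the denominator of a sample shrinks when forms are missing in
that sample. The light channel carries the sample, the heavy channel the fixed
Arg-10 spike-in; their %RA ratio (L/H) cancels per-sample processing
variability, which makes it invariant under independent global rescaling of
either channel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AUC_COLUMNS = ("run_id", "family_id", "form_id", "channel", "auc")


def relative_abundance(
    auc_df: pd.DataFrame, joint_channels: bool = False
) -> pd.DataFrame:
    """Add per-(run, channel, family) %RA to a long AUC table.

    Missing/withheld AUCs (NaN) stay missing and are excluded from the
    denominator. A family whose observed areas sum to zero in a run/channel
    gets missing %RA throughout. With ``joint_channels`` both channels are
    restricted to the forms observed in light *and* heavy of that run, so
    their denominators cover the same form set (sensitivity mode; the default
    keeps per-channel independent denominators).
    """
    missing = set(AUC_COLUMNS) - set(auc_df.columns)
    if missing:
        raise ValueError(f"AUC table missing columns: {sorted(missing)}")
    df = auc_df.copy()
    if joint_channels:
        observed = df.dropna(subset=["auc"])
        counts = observed.groupby(["run_id", "form_id"])["channel"].nunique()
        both = counts[counts == 2].index
        key = pd.MultiIndex.from_frame(df[["run_id", "form_id"]])
        df = df[key.isin(both)]
    totals = df.groupby(["run_id", "channel", "family_id"])["auc"].transform(
        lambda s: s.sum(skipna=True)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        df["rel_abundance"] = 100.0 * df["auc"] / totals.where(totals > 0)
    return df


def ra_matrix(ra_df: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Pivot one channel of a %RA table to samples x forms."""
    sub = ra_df[ra_df["channel"] == channel]
    return sub.pivot_table(
        index="run_id", columns="form_id", values="rel_abundance",
        aggfunc="first", dropna=False,
    )


def lh_ratio(ra_df: pd.DataFrame) -> pd.DataFrame:
    """Samples x forms matrix of light/heavy %RA ratios.

    A heavy observation without a light counterpart is not considered for
    quantification; a light observation without heavy yields a missing ratio
    (its %RA remains available in the %RA table).
    """
    light = ra_matrix(ra_df, "light")
    heavy = ra_matrix(ra_df, "heavy")
    cols = light.columns.union(heavy.columns)
    idx = light.index.union(heavy.index)
    light = light.reindex(index=idx, columns=cols)
    heavy = heavy.reindex(index=idx, columns=cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = light / heavy.where(heavy > 0)
    return ratio


def normalize_ratios(
    matrix: pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Divide each value by the column mean of present values within scope.

    With ``groups`` (sample -> group label, e.g. tumor type) normalization is
    per group; without it, across all samples. Column means of present values
    become 1 in every scope, making the operation idempotent.
    """
    if groups is None:
        return matrix / matrix.mean(axis=0, skipna=True)
    g = groups.reindex(matrix.index)
    if g.isna().any():
        raise ValueError("group label missing for some samples")
    out = matrix.copy()
    for _, block_idx in matrix.groupby(g).groups.items():
        block = matrix.loc[block_idx]
        out.loc[block_idx] = block / block.mean(axis=0, skipna=True)
    return out


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; missing values preserved, nonpositive rejected."""
    bad = matrix.le(0)
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"nonpositive ratio at sample {matrix.index[r]!r}, "
            f"feature {matrix.columns[c]!r}"
        )
    return np.log2(matrix)


def condition_ratio(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> pd.DataFrame:
    """Elementwise A/B over paired replicates ("ratio of ratios").

    Rows are matched replicate pairs (identical index labels); missing on
    either side yields missing.
    """
    if not matrix_a.columns.equals(matrix_b.columns):
        raise ValueError("condition matrices must share identical columns")
    if not matrix_a.index.equals(matrix_b.index):
        raise ValueError("condition matrices must share replicate labels")
    with np.errstate(invalid="ignore", divide="ignore"):
        return matrix_a / matrix_b.where(matrix_b > 0)
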