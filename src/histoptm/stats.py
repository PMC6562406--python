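"""Cohort statistics: group tests, proliferation correlation, PCA, clustering.

Group comparisons use the two-sided Student's t-test (pooled variance by
default, Welch optional), with no multiple-testing correction on per-feature
PTM comparisons — the exploratory convention of this workflow. Displays use a
two-tier significance code (p < 0.05 dark, p < 0.1 light; p < 0.05 with only
two measurements per group is demoted to light). Benjamini-Hochberg FDR is
applied only where a screened catalogue is interrogated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    mean_a: float
    mean_b: float
    t: float
    p: float
    direction: str  # increase | decrease | none
    tier: str  # dark | light | ns | not_computable
    n_a: int
    n_b: int


def _tier(p: float, n_min: int) -> str:
    if np.isnan(p):
        return "not_computable"
    if p < 0.05:
        return "light" if n_min <= 2 else "dark"
    if p < 0.1:
        return "light"
    return "ns"


def ttest(
    values_a,
    values_b,
    paired: bool = False,
    feature: str = "",
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided t-test of group A vs group B; direction from mean(A)-mean(B).

    Missing values are dropped (pairwise for paired mode). Identical paired
    vectors have zero difference everywhere; by convention t = 0, p = 1.
    Insufficient data yields a not-computable result rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length vectors")
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
    else:
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n_a, n_b = len(a), len(b)
    enough = (n_a >= 2 and n_b >= 2) if not paired else n_a >= 2
    if not enough:
        return ComparisonResult(
            feature, np.nan, np.nan, np.nan, np.nan, "none",
            "not_computable", n_a, n_b,
        )
    if paired and np.allclose(a, b):
        t, p = 0.0, 1.0
    elif paired and np.ptp(a - b) == 0:
        # constant nonzero difference: zero variance, unbounded statistic
        t, p = np.sign(np.mean(a - b)) * np.inf, 0.0
    elif paired:
        t, p = sps.ttest_rel(a, b)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    diff = float(np.mean(a) - np.mean(b))
    direction = "increase" if diff > 0 else "decrease" if diff < 0 else "none"
    if np.isnan(p):
        direction = "none"
    return ComparisonResult(
        feature, float(np.mean(a)), float(np.mean(b)), float(t), float(p),
        direction, _tier(float(p), min(n_a, n_b)), n_a, n_b,
    )


def compare_groups(
    matrix: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    paired: bool = False,
    pairs: pd.Series | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature t-tests of ``group_a`` vs ``group_b`` over a samples x
    features matrix. For paired tests, ``pairs`` maps sample -> pair id and
    samples are matched by it.
    """
    g = groups.reindex(matrix.index)
    a_rows = matrix.loc[g == group_a]
    b_rows = matrix.loc[g == group_b]
    if paired:
        if pairs is None:
            raise ValueError("paired comparison requires pair ids")
        pa = pairs.reindex(a_rows.index)
        pb = pairs.reindex(b_rows.index)
        common = pa[pa.isin(pb.values)].sort_values()
        a_rows = a_rows.loc[common.index]
        b_rows = b_rows.set_axis(pb.values).loc[common.values]
    rows = []
    for col in matrix.columns:
        res = ttest(
            a_rows[col].to_numpy(), b_rows[col].to_numpy(),
            paired=paired, feature=str(col), equal_var=equal_var,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows).set_index("feature")


def pearson_vs_ki67(
    values, ki67, r_display_threshold: float = 0.4, absolute: bool = False
) -> dict:
    """Pearson correlation of a feature against the Ki-67 index.

    Returns r, the two-sided p (t transform), and ``display_flag`` — true when
    r exceeds the display threshold (literal r > 0.4; set ``absolute`` to use
    |r|) — plus ``asterisk`` for p < 0.05. Needs >= 3 complete pairs and
    nonzero variance on both sides; otherwise flagged not computable.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(ki67, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return {
            "r": np.nan, "p": np.nan, "n": len(x),
            "display_flag": False, "asterisk": False, "computable": False,
        }
    r, p = sps.pearsonr(x, y)
    shown = abs(r) if absolute else r
    return {
        "r": float(r), "p": float(p), "n": len(x),
        "display_flag": bool(shown > r_display_threshold),
        "asterisk": bool(p < 0.05), "computable": True,
    }


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    retained_samples: list
    retained_features: list
    imputed: pd.DataFrame


def pca_with_policy(
    matrix: pd.DataFrame,
    groups: pd.Series,
    max_missing_per_sample: int = 10,
    max_missing_per_feature: int = 5,
    n_components: int | None = None,
) -> PCAResult:
    """PCA with the missing-value policy of this workflow.

    Samples with more than ``max_missing_per_sample`` missing values are
    removed first; then features with no valid value in at least one group, or
    more than ``max_missing_per_feature`` missing values. Remaining holes are
    imputed with the feature mean across all retained samples, the matrix is
    column-centered and decomposed by SVD.
    """
    keep_samples = matrix.isna().sum(axis=1) <= max_missing_per_sample
    m = matrix.loc[keep_samples]
    if len(m) < 2:
        raise ValueError("fewer than 2 samples after filtering")
    g = groups.reindex(m.index)
    has_valid_everywhere = pd.concat(
        [m.loc[g == lab].notna().any(axis=0) for lab in g.unique()], axis=1
    ).all(axis=1)
    few_missing = m.isna().sum(axis=0) <= max_missing_per_feature
    keep_features = has_valid_everywhere & few_missing
    m = m.loc[:, keep_features]
    if m.shape[1] == 0:
        raise ValueError("no features left after filtering")
    imputed = m.fillna(m.mean(axis=0, skipna=True))
    centered = imputed - imputed.mean(axis=0)
    u, s, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    k = n_components or min(centered.shape)
    var = s**2 / (len(m) - 1)
    evr = var / var.sum()
    scores = pd.DataFrame(
        (u * s)[:, :k], index=m.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        vt[:k].T, index=m.columns, columns=scores.columns
    )
    return PCAResult(
        scores, loadings, evr[:k], list(m.index), list(m.columns), imputed
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list
    excluded: list


def hcluster(matrix: pd.DataFrame, axis: str = "samples") -> ClusterResult:
    """UPGMA (average linkage) on correlation distance (1 - Pearson r).

    ``axis`` "samples" clusters rows, "features" clusters columns. Items with
    zero variance (correlation undefined) are excluded and reported. Equal
    merge distances are broken deterministically toward the lowest index.
    """
    data = matrix if axis == "samples" else matrix.T
    if axis not in ("samples", "features"):
        raise ValueError(f"unknown axis {axis!r}")
    arr = data.to_numpy(dtype=float)
    variable = np.nanstd(arr, axis=1) > 0
    excluded = [lab for lab, ok in zip(data.index, variable) if not ok]
    data = data.loc[variable]
    if len(data) < 2:
        raise ValueError("need at least 2 variable items to cluster")
    # pairwise-complete Pearson correlation distance
    corr = data.T.corr(method="pearson")
    dist = (1.0 - corr).to_numpy()
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(squareform(dist, checks=False), method="average")
    return ClusterResult(link, list(data.index), excluded)


def _tree_to_newick(node, labels, parent_height: float) -> str:
    if node.is_leaf():
        return f"{labels[node.id]}:{parent_height - node.dist:.6g}"
    left = _tree_to_newick(node.left, labels, node.dist)
    right = _tree_to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{parent_height - node.dist:.6g}"


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string (branch lengths from merge heights)."""
    tree = sch.to_tree(result.linkage)
    return (
        f"({_tree_to_newick(tree.left, result.labels, tree.dist)},"
        f"{_tree_to_newick(tree.right, result.labels, tree.dist)});"
    )


def bh_fdr(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjusted p-values and pass flags."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, padj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"p": p, "padj": padj, "significant": reject})
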