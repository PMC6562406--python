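"""Single-residue "total mark" scores from combinatorial peptidoforms.

A total mark (e.g. total H3K14ac) is the summed abundance of every peptidoform
of one peptide family that carries the mark, regardless of co-occurring
modifications. Aggregation sums %RA within each channel first and then takes
the light/heavy ratio: a ratio of sums is invariant to global channel scaling,
whereas a sum of per-form ratios is not. The per-form-ratio alternative is kept
as a mode for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MarkDefinition:
    """Named set of peptidoforms summed into one single-residue score."""

    name: str
    family_id: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("mark must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("mark members must be distinct")
        for m in self.members:
            if not m.startswith(self.family_id + ":"):
                raise ValueError(
                    f"member {m} outside family {self.family_id}"
                )


def builtin_marks() -> dict[str, MarkDefinition]:
    """The total-mark registry used throughout the analysis.

    total_H3K14ac sums the five K14ac-bearing forms of the 9-17 peptide;
    total_H3K9me3 sums H3K9me3 and H3K9me3/K14ac; total_H3K27me3 sums
    H3K27me3 and H3K27me3/K36me1.
    """
    defs = [
        MarkDefinition(
            "total_H3K14ac",
            "H3_9-17",
            (
                "H3_9-17:K14ac",
                "H3_9-17:K9me1_K14ac",
                "H3_9-17:K9me2_K14ac",
                "H3_9-17:K9me3_K14ac",
                "H3_9-17:K9ac_K14ac",
            ),
        ),
        MarkDefinition(
            "total_H3K9me3",
            "H3_9-17",
            ("H3_9-17:K9me3", "H3_9-17:K9me3_K14ac"),
        ),
        MarkDefinition(
            "total_H3K27me3",
            "H3_27-40",
            ("H3_27-40:K27me3", "H3_27-40:K27me3_K36me1"),
        ),
    ]
    return {d.name: d for d in defs}


def load_mark_registry(path) -> dict[str, MarkDefinition]:
    """Registry from a TSV with columns name, family_id, members (';'-sep)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[row["name"]] = MarkDefinition(
            row["name"], row["family_id"], tuple(row["members"].split(";"))
        )
    return out


def aggregate_mark(
    mark: MarkDefinition,
    light_ra: pd.DataFrame,
    heavy_ra: pd.DataFrame,
    mode: str = "ratio_of_sums",
) -> pd.DataFrame:
    """Per-sample mark %RA in each channel and the mark L/H ratio.

    ``light_ra``/``heavy_ra`` are samples x forms %RA matrices. Missing
    members contribute 0 when at least one member is observed (flagged in the
    ``partial`` column); a channel with no member observed gives a missing
    mark value. ``mode`` "ratio_of_sums" (default) divides the channel sums;
    "sum_of_ratios" sums per-form L/H ratios instead.
    """
    if mode not in ("ratio_of_sums", "sum_of_ratios"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    members = list(mark.members)
    idx = light_ra.index.union(heavy_ra.index)
    sub_l = light_ra.reindex(index=idx, columns=members)
    sub_h = heavy_ra.reindex(index=idx, columns=members)
    n_obs_l = sub_l.notna().sum(axis=1)
    n_obs_h = sub_h.notna().sum(axis=1)
    sum_l = sub_l.sum(axis=1, skipna=True).where(n_obs_l > 0)
    sum_h = sub_h.sum(axis=1, skipna=True).where(n_obs_h > 0)
    if mode == "ratio_of_sums":
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = sum_l / sum_h.where(sum_h > 0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            per_form = sub_l / sub_h.where(sub_h > 0)
        ratio = per_form.sum(axis=1, skipna=True).where(
            per_form.notna().sum(axis=1) > 0
        )
    return pd.DataFrame(
        {
            "mark_ra_light": sum_l,
            "mark_ra_heavy": sum_h,
            "mark_ratio": ratio,
            "partial": (n_obs_l < len(members)) | (n_obs_h < len(members)),
        }
    )


def mark_ratio_matrix(
    registry: dict[str, MarkDefinition],
    light_ra: pd.DataFrame,
    heavy_ra: pd.DataFrame,
    mode: str = "ratio_of_sums",
) -> pd.DataFrame:
    """Samples x marks matrix of L/H mark ratios."""
    cols = {
        name: aggregate_mark(d, light_ra, heavy_ra, mode)["mark_ratio"]
        for name, d in registry.items()
    }
    return pd.DataFrame(cols)
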