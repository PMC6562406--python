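"""Synthetic cohorts and simulated MS1 signals with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
matched normal/tumor cohort, a combinatorial %RA profile per peptide family
(summing to 100 before noise), group-level effects expressed as fold changes on
the members of a total mark followed by family renormalization, a fixed heavy
spike-in composition shared by all samples, multiplicative lognormal noise on
AUCs, and an optional Ki-67 proliferation index linearly linked to a chosen
mark. Simulated signals are Gaussian elution peaks at the library's light and
heavy m/z for charges 2+ and 3+, with peak areas proportional to the true AUCs,
emitted as the centroided peak-table format the quantifier reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import PeptideLibrary, mz as _mz
from .marks import MarkDefinition, builtin_marks

# Baseline light-channel %RA per family. Named forms carry literature-plausible
# tissue values; the remaining combinatorial forms share the remainder evenly.
DEFAULT_BASELINE: dict[str, dict[str, float]] = {
    "H3_3-8": {
        "H3_3-8:unmod": 85.0,
        "H3_3-8:K4me1": 5.0,
        "H3_3-8:K4me2": 4.0,
        "H3_3-8:K4me3": 3.0,
        "H3_3-8:K4ac": 3.0,
    },
    "H3_9-17": {
        "H3_9-17:unmod": 12.0,
        "H3_9-17:K9me1": 16.0,
        "H3_9-17:K9me2": 24.0,
        "H3_9-17:K9me3": 14.0,
        "H3_9-17:K9ac": 4.0,
        "H3_9-17:K14ac": 10.0,
        "H3_9-17:K9me1_K14ac": 4.0,
        "H3_9-17:K9me2_K14ac": 2.5,
        "H3_9-17:K9me3_K14ac": 1.5,
        "H3_9-17:K9ac_K14ac": 2.0,
    },
    "H3_18-26": {
        "H3_18-26:unmod": 35.0,
        "H3_18-26:K18ac": 10.0,
        "H3_18-26:K23ac": 12.0,
        "H3_18-26:K18ac_K23ac": 5.0,
        "H3_18-26:K23me1": 8.0,
    },
    "H3_27-40": {
        "H3_27-40:unmod": 15.0,
        "H3_27-40:K27me1": 20.0,
        "H3_27-40:K27me2": 15.0,
        "H3_27-40:K27me3": 10.0,
        "H3_27-40:K27me3_K36me1": 3.0,
        "H3_27-40:K36me1": 8.0,
        "H3_27-40:K36me2": 10.0,
        "H3_27-40:K36me3": 4.0,
        "H3_27-40:K27me1_K36me1": 3.0,
    },
    "H3_73-83": {
        "H3_73-83:unmod": 55.0,
        "H3_73-83:K79me1": 20.0,
        "H3_73-83:K79me2": 18.0,
        "H3_73-83:K79me3": 5.0,
        "H3_73-83:K79ac": 2.0,
    },
}

# Family elution anchors (minutes) and within-family apex spacing.
DEFAULT_FAMILY_RT = {
    "H3_3-8": 16.0,
    "H3_9-17": 22.0,
    "H3_18-26": 28.0,
    "H3_27-40": 34.0,
    "H3_73-83": 40.0,
}


@dataclass(frozen=True)
class Ki67Config:
    """Per-sample proliferation index linearly linked to one mark.

    The index is generated from the sample's realized log2 mark ratio so that
    its Pearson correlation with the measured mark approaches ``r``.
    """

    mean: float = 30.0
    sd: float = 15.0
    linked_mark: str = "total_H3K9me3"
    r: float = 0.6


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a simulated cohort.

    groups: group name -> sample count (matched pairs when ``paired``).
    fold_changes: mark (or form id) -> fold change applied to the affected
        group's baseline members, after which the family renormalizes to 100.
    noise_sd: lognormal AUC noise, sd on the log2 scale.
    sample_scale_sd: per-sample loading variability (log2 sd), shared by all
        forms of a sample/channel — cancelled by the L/H ratio.
    missing_rate: fraction of light-channel form observations dropped at
        random (the spike-in is measured in every run).
    """

    groups: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 8, "tumor": 8}
    )
    affected_group: str = "tumor"
    fold_changes: Mapping[str, float] = field(
        default_factory=lambda: {"total_H3K14ac": 0.5}
    )
    noise_sd: float = 0.2
    sample_scale_sd: float = 0.3
    auc_scale: float = 1.0e7
    missing_rate: float = 0.0
    paired: bool = True
    storage: str = "frozen"
    ki67: Ki67Config | None = Ki67Config()
    rt_spacing: float = 0.6
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the downstream stages are graded against."""

    metadata: pd.DataFrame  # sample_id, group, pair_id, ki67, storage
    true_ra: pd.DataFrame  # group-level truth: group, form_id, channel, ra
    auc: pd.DataFrame  # run_id, family_id, form_id, channel, auc
    rt_expected: dict[str, float]
    profiles: dict[str, pd.Series]  # group -> light %RA profile (+ "heavy")
    config: CohortConfig


def expand_baseline(
    library: PeptideLibrary,
    named: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.Series:
    """Full %RA profile over every library form, summing to 100 per family."""
    named = DEFAULT_BASELINE if named is None else named
    values = {}
    for family in library.families:
        forms = [f.form_id for f in library.family_forms(family)]
        fam_named = dict(named.get(family, {}))
        unknown = set(fam_named) - set(forms)
        if unknown:
            raise ValueError(f"baseline names unknown forms: {sorted(unknown)}")
        assigned = sum(fam_named.values())
        if assigned > 100.0:
            raise ValueError(f"family {family} baseline exceeds 100%")
        rest = [f for f in forms if f not in fam_named]
        share = (100.0 - assigned) / len(rest) if rest else 0.0
        for f in forms:
            values[f] = fam_named.get(f, share)
    return pd.Series(values, name="ra")


def _resolve_members(
    key: str, registry: dict[str, MarkDefinition], forms: Sequence[str]
) -> list[str]:
    if key in registry:
        return list(registry[key].members)
    if key in forms:
        return [key]
    raise ValueError(f"fold-change target {key!r} is neither a mark nor a form")


def apply_fold_changes(
    profile: pd.Series,
    fold_changes: Mapping[str, float],
    library: PeptideLibrary,
    registry: dict[str, MarkDefinition] | None = None,
) -> pd.Series:
    """Scale designated members and renormalize each family to 100."""
    registry = registry or builtin_marks()
    out = profile.copy()
    forms = list(profile.index)
    for key, fc in fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for {key!r} must be positive")
        for member in _resolve_members(key, registry, forms):
            out[member] = out[member] * fc
    fam_of = {f.form_id: f.family_id for f in library}
    fams = pd.Series({f: fam_of[f] for f in out.index})
    totals = out.groupby(fams).transform("sum")
    out = 100.0 * out / totals
    if ((out <= 0) | (out >= 100)).any() and len(out) > 1:
        bad = out[(out <= 0) | (out >= 100)]
        raise ValueError(
            f"fold change drives %RA outside (0,100): {list(bad.index)[:3]}"
        )
    return out


def assign_retention_times(
    library: PeptideLibrary, rt_spacing: float = 0.6
) -> dict[str, float]:
    """Deterministic apex per form: family anchor + enumeration-order offset."""
    rts = {}
    for family in library.families:
        base = DEFAULT_FAMILY_RT.get(family, 20.0)
        for i, form in enumerate(library.family_forms(family)):
            rts[form.form_id] = base + i * rt_spacing
    return rts


def generate_cohort(
    config: CohortConfig,
    library: PeptideLibrary | None = None,
    baseline: Mapping[str, Mapping[str, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Ground-truth cohort: per-sample AUCs, metadata, and true profiles."""
    library = library or PeptideLibrary.build()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    registry = builtin_marks()
    base_profile = expand_baseline(library, baseline)
    profiles: dict[str, pd.Series] = {"heavy": base_profile}
    for group in config.groups:
        if group == config.affected_group and config.fold_changes:
            profiles[group] = apply_fold_changes(
                base_profile, config.fold_changes, library, registry
            )
        else:
            profiles[group] = base_profile
    fam_of = {f.form_id: f.family_id for f in library}

    meta_rows, auc_rows = [], []
    sample_log_mark: dict[str, float] = {}
    ki_mark_members: list[str] = []
    ki_family_forms: list[str] = []
    if config.ki67:
        ki_mark = registry[config.ki67.linked_mark]
        ki_mark_members = list(ki_mark.members)
        ki_family_forms = [
            f.form_id for f in library.family_forms(ki_mark.family_id)
        ]
    pair_counter = 0
    for group, size in config.groups.items():
        for i in range(size):
            sample_id = f"{group}_{i + 1:02d}"
            pair_id = i + 1 if config.paired else pair_counter
            pair_counter += 1
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "pair_id": pair_id,
                    "storage": config.storage,
                }
            )
            light_true = profiles[group]
            noisy = {}
            for channel, true_ra in (
                ("light", light_true),
                ("heavy", profiles["heavy"]),
            ):
                scale = config.auc_scale * 2.0 ** rng.normal(
                    0.0, config.sample_scale_sd
                )
                noise = 2.0 ** rng.normal(
                    0.0, config.noise_sd, size=len(true_ra)
                )
                auc = scale * (true_ra.to_numpy() / 100.0) * noise
                keep = np.ones(len(true_ra), dtype=bool)
                if channel == "light" and config.missing_rate > 0:
                    keep = rng.random(len(true_ra)) >= config.missing_rate
                ser = pd.Series(auc, index=true_ra.index)
                noisy[channel] = ser
                for form_id, value in ser[keep].items():
                    auc_rows.append(
                        {
                            "run_id": sample_id,
                            "family_id": fam_of[form_id],
                            "form_id": form_id,
                            "channel": channel,
                            "auc": value,
                        }
                    )
            if config.ki67:
                # link to the %RA-based mark ratio the pipeline measures,
                # which is free of the per-sample loading scale
                num = noisy["light"].loc[ki_mark_members].sum() / (
                    noisy["light"].loc[ki_family_forms].sum()
                )
                den = noisy["heavy"].loc[ki_mark_members].sum() / (
                    noisy["heavy"].loc[ki_family_forms].sum()
                )
                sample_log_mark[sample_id] = float(np.log2(num / den))

    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    if config.ki67:
        z = pd.Series(sample_log_mark).reindex(metadata.index)
        z = (z - z.mean()) / (z.std(ddof=0) or 1.0)
        eps = rng.normal(0.0, 1.0, size=len(z))
        k = config.ki67
        ki = k.mean + k.sd * (k.r * z.to_numpy() + np.sqrt(1 - k.r**2) * eps)
        metadata["ki67"] = np.clip(ki, 0.0, 100.0)
    else:
        metadata["ki67"] = np.nan

    true_rows = []
    for label, prof in profiles.items():
        channel = "heavy" if label == "heavy" else "light"
        group = "spike-in" if label == "heavy" else label
        for form_id, ra in prof.items():
            true_rows.append(
                {
                    "group": group,
                    "channel": channel,
                    "family_id": fam_of[form_id],
                    "form_id": form_id,
                    "true_ra": ra,
                }
            )
    return GroundTruth(
        metadata=metadata,
        true_ra=pd.DataFrame(true_rows),
        auc=pd.DataFrame(auc_rows),
        rt_expected=assign_retention_times(library, config.rt_spacing),
        profiles=profiles,
        config=config,
    )


def apply_storage_mask(
    truth: GroundTruth,
    exclusions: Mapping[str, Sequence[str]],
) -> GroundTruth:
    """Drop light-channel observations of forms unreliable per storage type.

    ``exclusions`` maps a storage label (e.g. ``FFPE``) to the form ids that
    cannot be quantified from tissue stored that way; samples with other
    storage types are untouched. This is the only representation of storage
    artifacts here — no attempt is made to model them quantitatively.
    """
    storage = truth.metadata.set_index("sample_id")["storage"]
    auc = truth.auc
    drop = pd.Series(False, index=auc.index)
    for label, forms in exclusions.items():
        affected = storage[storage == label].index
        drop |= (
            auc["run_id"].isin(affected)
            & auc["form_id"].isin(list(forms))
            & (auc["channel"] == "light")
        )
    return GroundTruth(
        truth.metadata, truth.true_ra, auc[~drop].reset_index(drop=True),
        truth.rt_expected, truth.profiles, truth.config,
    )


def true_mark_ratio(
    truth: GroundTruth, mark: MarkDefinition, group: str
) -> float:
    """Ground-truth L/H ratio of a mark for one group (noise-free)."""
    light = truth.profiles[group].loc[list(mark.members)].sum()
    heavy = truth.profiles["heavy"].loc[list(mark.members)].sum()
    return float(light / heavy)


@dataclass(frozen=True)
class PeakShapeConfig:
    """Gaussian elution-shape parameters for simulated MS1 signals."""

    peak_sigma: float = 0.08  # minutes
    dt: float = 0.02  # scan spacing, minutes
    n_sigma: float = 4.0
    charge_split: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.7, 3: 0.3}
    )
    mz_jitter_ppm: float = 0.0
    families: tuple[str, ...] | None = None  # restrict emitted families


def simulate_peaks(
    truth: GroundTruth,
    library: PeptideLibrary,
    shape: PeakShapeConfig = PeakShapeConfig(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Centroided peak table for every run of the cohort.

    Each observed form/channel/charge becomes a Gaussian elution peak at its
    theoretical m/z whose area equals the true AUC times the charge split.
    Forms whose apexes sit closer than the resolvable width are emitted
    co-eluting (exercising the isobaric-resolution flagging downstream).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    for family in library.families:
        fam_rts = sorted(
            truth.rt_expected[f.form_id]
            for f in library.family_forms(family)
            if f.form_id in truth.rt_expected
        )
        if len(fam_rts) > 1 and min(np.diff(fam_rts)) < 2 * shape.peak_sigma:
            import warnings

            warnings.warn(
                f"{family}: apex spacing below resolvable width; "
                "co-eluting forms emitted",
                stacklevel=2,
            )
    forms = {f.form_id: f for f in library}
    rows = []
    auc = truth.auc
    if shape.families is not None:
        auc = auc[auc["family_id"].isin(shape.families)]
    for rec in auc.itertuples(index=False):
        form = forms[rec.form_id]
        apex = truth.rt_expected[rec.form_id]
        lo = apex - shape.n_sigma * shape.peak_sigma
        hi = apex + shape.n_sigma * shape.peak_sigma
        idx = np.arange(np.ceil(lo / shape.dt), np.floor(hi / shape.dt) + 1)
        rt = idx * shape.dt
        shape_vals = np.exp(-0.5 * ((rt - apex) / shape.peak_sigma) ** 2) / (
            shape.peak_sigma * np.sqrt(2 * np.pi)
        )
        for charge, split in shape.charge_split.items():
            target = _mz(form, charge, rec.channel)
            if shape.mz_jitter_ppm > 0:
                jitter = rng.uniform(-1, 1, size=len(rt))
                mz_vals = target * (1 + jitter * shape.mz_jitter_ppm * 1e-6)
            else:
                mz_vals = np.full(len(rt), target)
            intens = rec.auc * split * shape_vals
            rows.append(
                pd.DataFrame(
                    {
                        "run_id": rec.run_id,
                        "rt": rt,
                        "mz": mz_vals,
                        "intensity": intens,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["run_id", "rt", "mz", "intensity"])
    return (
        pd.concat(rows, ignore_index=True)
        .sort_values(["run_id", "rt", "mz"], kind="stable")
        .reset_index(drop=True)
    )
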