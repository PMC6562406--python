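"""Extracted-ion-chromatogram quantification of targeted precursors.

For every peptidoform x charge x SILAC channel, the intensity of centroids
within a ppm window around the theoretical m/z (rounded to four decimals) is
traced across retention time and integrated by the trapezoidal rule. Isobaric
peptidoforms — distinct modification placements with identical mass — share one
trace; multi-apex traces are split at inter-apex valleys and apexes are assigned
to forms by their expected elution order. Sets that cannot be resolved are
flagged and their areas withheld rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .library import PeptideLibrary, mz as _theoretical_mz

UNRESOLVED = "unresolved"


@dataclass
class Spectrum:
    """One centroided MS1 scan (retention time in minutes)."""

    run_id: str
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.retention_time < 0:
            raise ValueError("retention time must be >= 0")
        if np.any(np.diff(self.mz) < 0):
            raise ValueError("spectrum peaks must be sorted by m/z")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class XICTrace:
    """Summed in-tolerance intensity per scan for one target m/z."""

    target_mz: float
    rt: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def auc(self) -> float:
        return integrate_auc(self)


@dataclass(frozen=True)
class IdentificationRecord:
    """Search-engine evidence for one peptidoform (score + site confidence)."""

    form_id: str
    score: float
    localization_prob: float
    rt_apex: float

    def __post_init__(self):
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError("localization probability must be in [0, 1]")


def extract_xic(
    spectra: Sequence[Spectrum],
    target_mz: float,
    ppm_tolerance: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> XICTrace:
    """Trace the summed intensity of centroids within ``ppm_tolerance``.

    The target m/z is rounded to four decimals before matching. An empty
    spectra set yields an empty trace.
    """
    if ppm_tolerance <= 0:
        raise ValueError("ppm tolerance must be positive")
    target = round(float(target_mz), 4)
    half_width = target * ppm_tolerance * 1e-6
    rts, sums = [], []
    for s in spectra:
        if rt_window is not None and not (
            rt_window[0] <= s.retention_time <= rt_window[1]
        ):
            continue
        lo = np.searchsorted(s.mz, target - half_width, side="left")
        hi = np.searchsorted(s.mz, target + half_width, side="right")
        rts.append(s.retention_time)
        sums.append(float(s.intensity[lo:hi].sum()))
    order = np.argsort(rts) if rts else []
    return XICTrace(
        target,
        np.asarray(rts, dtype=float)[order] if rts else np.empty(0),
        np.asarray(sums, dtype=float)[order] if rts else np.empty(0),
    )


def integrate_auc(trace: XICTrace) -> float:
    """Trapezoidal area under the trace; fewer than two points gives 0."""
    if len(trace.rt) < 2:
        return 0.0
    if np.any(np.diff(trace.rt) < 0):
        raise ValueError("trace retention times must be sorted")
    return float(np.trapezoid(trace.intensity, trace.rt))


def _apexes(trace: XICTrace, rel_height: float = 0.02) -> np.ndarray:
    """Indices of local maxima, ignoring ripples below ``rel_height`` x max."""
    if len(trace.intensity) == 0 or trace.intensity.max() <= 0:
        return np.empty(0, dtype=int)
    floor = rel_height * trace.intensity.max()
    peaks, _ = find_peaks(trace.intensity, height=floor, prominence=floor)
    return peaks


def resolve_isobaric(
    trace: XICTrace, rt_order_template: Sequence[str]
) -> dict[str, float | None]:
    """Apportion a shared isobaric trace among co-measured peptidoforms.

    ``rt_order_template`` lists the form ids in expected elution order. The
    trace is split at the intensity valleys between consecutive apexes and the
    segment areas are assigned to the forms in template order. If fewer apexes
    than forms are found, the set is unresolvable: every form maps to ``None``.
    """
    forms = list(rt_order_template)
    if not forms:
        raise ValueError("rt_order_template must name at least one form")
    if len(forms) == 1:
        return {forms[0]: integrate_auc(trace)}
    apex = _apexes(trace)
    if len(apex) < len(forms):
        return {f: None for f in forms}
    if len(apex) > len(forms):
        # keep the n tallest apexes, preserving elution order
        tallest = np.sort(
            apex[np.argsort(trace.intensity[apex])[-len(forms):]]
        )
        apex = tallest
    boundaries = [0]
    for a, b in zip(apex[:-1], apex[1:]):
        boundaries.append(a + int(np.argmin(trace.intensity[a : b + 1])))
    boundaries.append(len(trace.rt) - 1)
    out: dict[str, float | None] = {}
    for form, lo, hi in zip(forms, boundaries[:-1], boundaries[1:]):
        seg = XICTrace(trace.target_mz, trace.rt[lo : hi + 1],
                       trace.intensity[lo : hi + 1])
        out[form] = integrate_auc(seg)
    return out


def filter_identifications(
    records: Iterable[IdentificationRecord],
    min_score: float = 60.0,
    min_loc_prob: float = 0.75,
) -> list[IdentificationRecord]:
    """Drop identifications below the score or site-localization thresholds.

    Boundary values are kept: the rule removes records strictly below.
    """
    return [
        r
        for r in records
        if r.score >= min_score and r.localization_prob >= min_loc_prob
    ]


@dataclass
class QuantConfig:
    """Targeted-quantification settings.

    ppm_tolerance: centroid matching half-window, parts per million.
    charges: precursor charges summed per form.
    rt_window: half-width (minutes) around the expected apex.
    """

    ppm_tolerance: float = 10.0
    charges: tuple[int, ...] = (2, 3)
    rt_window: float = 2.0


def _isobaric_groups(
    forms, channel: str, charge: int, ppm_tolerance: float
) -> list[list]:
    """Greedy grouping of forms whose theoretical m/z agree within tolerance."""
    with_mz = sorted(
        ((f, _theoretical_mz(f, charge, channel)) for f in forms),
        key=lambda t: t[1],
    )
    groups: list[list] = []
    for f, m in with_mz:
        if groups and (m - groups[-1][-1][1]) / m * 1e6 <= ppm_tolerance:
            groups[-1].append((f, m))
        else:
            groups.append([(f, m)])
    return groups


def quantify_run(
    spectra: Sequence[Spectrum],
    library: PeptideLibrary,
    config: QuantConfig,
    rt_expected: Mapping[str, float],
) -> pd.DataFrame:
    """Per-form, per-channel AUC for one run, summed over precursor charges.

    ``rt_expected`` maps form id to expected apex retention time (minutes) —
    from identifications on real runs, from ground truth on simulated ones.
    Forms without detectable signal are absent from the output; unresolvable
    isobaric sets appear with missing AUC and an ``unresolved`` flag.
    """
    if not spectra:
        return pd.DataFrame(
            columns=["run_id", "family_id", "form_id", "channel", "auc", "flag"]
        )
    run_id = spectra[0].run_id
    records: dict[tuple[str, str], dict] = {}
    for family in library.families:
        fam_forms = [
            f for f in library.family_forms(family) if f.form_id in rt_expected
        ]
        if not fam_forms:
            continue
        for channel in ("light", "heavy"):
            for charge in config.charges:
                groups = _isobaric_groups(
                    fam_forms, channel, charge, config.ppm_tolerance
                )
                for group in groups:
                    ordered = sorted(
                        group, key=lambda t: rt_expected[t[0].form_id]
                    )
                    ids = [f.form_id for f, _ in ordered]
                    lo = min(rt_expected[i] for i in ids) - config.rt_window
                    hi = max(rt_expected[i] for i in ids) + config.rt_window
                    trace = extract_xic(
                        spectra,
                        float(np.mean([m for _, m in ordered])),
                        config.ppm_tolerance,
                        (lo, hi),
                    )
                    if trace.auc == 0.0:
                        continue  # no signal for this ion
                    assigned = (
                        resolve_isobaric(trace, ids)
                        if len(ids) > 1
                        else {ids[0]: integrate_auc(trace)}
                    )
                    for fid, area in assigned.items():
                        rec = records.setdefault(
                            (fid, channel),
                            {
                                "run_id": run_id,
                                "family_id": family,
                                "form_id": fid,
                                "channel": channel,
                                "auc": 0.0,
                                "flag": "",
                            },
                        )
                        if area is None:
                            rec["flag"] = UNRESOLVED
                        else:
                            rec["auc"] += area
                            rec[f"auc_z{charge}"] = (
                                rec.get(f"auc_z{charge}", 0.0) + area
                            )
    rows = []
    for rec in records.values():
        if rec["flag"] == UNRESOLVED:
            rec["auc"] = np.nan
        if rec["auc"] == 0.0 and rec["flag"] == "":
            continue
        rows.append(rec)
    df = pd.DataFrame(
        rows,
        columns=["run_id", "family_id", "form_id", "channel", "auc", "flag",
                 "auc_z2", "auc_z3"],
    )
    return df.sort_values(["family_id", "form_id", "channel"]).reset_index(
        drop=True
    )
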