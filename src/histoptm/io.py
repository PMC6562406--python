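"""Readers and writers for spectra and tabular results.

Two spectrum sources are supported: centroided MS1 runs in mzML (read through
pyteomics) and a simplified long-format peak table TSV with columns
``run_id, rt, mz, intensity`` (retention time in minutes) — the format the
simulator writes, so simulated runs round-trip through the same quantifier.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .xic import Spectrum

PEAK_TABLE_COLUMNS = ("run_id", "rt", "mz", "intensity")


def write_peak_table(df: pd.DataFrame, path) -> None:
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    df.loc[:, PEAK_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def spectra_from_frame(df: pd.DataFrame) -> "list[Spectrum]":
    """Group a single-run peak table into RT-ordered centroid spectra."""
    from .xic import Spectrum

    runs = df["run_id"].unique()
    if len(runs) != 1:
        raise ValueError(f"expected a single run, got {list(runs)}")
    spectra = []
    for rt, grp in df.groupby("rt", sort=True):
        order = np.argsort(grp["mz"].to_numpy())
        spectra.append(
            Spectrum(
                run_id=str(runs[0]),
                retention_time=float(rt),
                mz=grp["mz"].to_numpy()[order],
                intensity=grp["intensity"].to_numpy()[order],
            )
        )
    return spectra


def read_mzml(path, run_id: str | None = None) -> "list[Spectrum]":
    """Centroided MS1 spectra from an mzML file (RT converted to minutes)."""
    from pyteomics import mzml as _mzml

    from .xic import Spectrum

    rid = run_id or str(path)
    spectra = []
    with _mzml.read(str(path)) as reader:
        for scan in reader:
            if scan.get("ms level", 1) != 1:
                continue
            rt = scan["scanList"]["scan"][0]["scan start time"]
            unit = getattr(rt, "unit_info", "minute")
            rt_min = float(rt) / 60.0 if str(unit).startswith("s") else float(rt)
            mz_arr = np.asarray(scan["m/z array"], dtype=float)
            int_arr = np.asarray(scan["intensity array"], dtype=float)
            order = np.argsort(mz_arr)
            spectra.append(
                Spectrum(rid, rt_min, mz_arr[order], int_arr[order])
            )
    spectra.sort(key=lambda s: s.retention_time)
    return spectra
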