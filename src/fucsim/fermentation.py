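"""Fermentation outcome metrics: titer, substrate consumption, molar yield, fold change.

Works on shake-flask style time-course tables (time, OD600, glucose, acetate,
lactaldehyde, 1,2-propanediol, L-fuculose). Missing measurements — blank cells
or the "ND" token for product lost during derivatization — are excluded from
every statistic, never imputed as zero.

Definitions used throughout:

* **titer** — maximum observed product concentration (mg/L); an ``endpoint``
  mode is available for the last present value.
* **substrate consumed** — first present LAD concentration minus the minimum
  present LAD concentration (mM).
* **molar yield %** — 100 × (titer / MW_fuculose) / consumed, i.e. moles of
  product per mole of LAD consumed. MW(L-fuculose) = 164.16 g/mol,
  MW(lactaldehyde) = 74.08 g/mol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MW_FUCULOSE",
    "MW_LAD",
    "TimeCourse",
    "FermentationSummary",
    "read_timecourse",
    "write_timecourse",
    "summarize_fermentation",
    "fold_improvement",
]

MW_FUCULOSE = 164.16  # g/mol
MW_LAD = 74.08  # g/mol

_COLUMNS = ("time", "od600", "glucose", "acetate", "lad", "pdo", "fuculose")


@dataclass
class TimeCourse:
    """A sampled fermentation series; NaN marks a missing measurement.

    Units: time h; od600 dimensionless; glucose, acetate g/L; lad, pdo mM;
    fuculose mg/L. Time must be strictly increasing with at least two points;
    present concentrations must be non-negative.
    """

    time: np.ndarray
    od600: np.ndarray | None = None
    glucose: np.ndarray | None = None
    acetate: np.ndarray | None = None
    lad: np.ndarray | None = None
    pdo: np.ndarray | None = None
    fuculose: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size < 2:
            raise ValueError("time course needs at least two time points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in _COLUMNS[1:]:
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(f"column '{name}' length differs from time")
            present = arr[~np.isnan(arr)]
            if np.any(present < 0):
                raise ValueError(f"column '{name}' has negative concentrations")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time}
        for name in _COLUMNS[1:]:
            arr = getattr(self, name)
            if arr is not None:
                data[name] = arr
        return pd.DataFrame(data)


@dataclass
class FermentationSummary:
    max_titer: float  # mg/L
    time_of_max: float  # h
    substrate_consumed: float  # mM LAD
    molar_yield_pct: float
    fold_vs_reference: float | None = None


def read_timecourse(source) -> TimeCourse:
    """Read a time-course CSV (S3-style schema) into a :class:`TimeCourse`.

    Header names are matched case-insensitively; "ND" and blank cells parse as
    missing. Unknown columns raise a warning and are ignored; non-monotone
    time or negative concentrations raise ``ValueError``.
    """
    df = pd.read_csv(source, na_values=["ND", "nd", "N.D.", ""], skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    unknown = [c for c in df.columns if c not in _COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
    if "time" not in df.columns:
        raise ValueError("time course is missing the 'time' column")
    kwargs = {c: df[c].to_numpy(dtype=float) for c in _COLUMNS if c in df.columns}
    return TimeCourse(**kwargs)


def write_timecourse(tc: TimeCourse, path, nd_token: str = "ND") -> None:
    """Write a time course as CSV, rendering missing values as ``nd_token``."""
    df = tc.to_frame()
    Path(path).write_text(df.to_csv(index=False, na_rep=nd_token, float_format="%.6g"))


def _present(arr: np.ndarray) -> np.ndarray:
    return arr[~np.isnan(arr)]


def summarize_fermentation(
    tc: TimeCourse,
    titer_mode: str = "max",
    reference_titer: float | None = None,
) -> FermentationSummary:
    """Titer, LAD consumption and molar yield of one fermentation run.

    Requires at least one present value in both the fuculose and the LAD
    series. The yield is computed on a consumed-substrate molar basis (see
    module docstring); if no substrate was consumed the yield is 0 for a zero
    titer and NaN otherwise.
    """
    if tc.fuculose is None or _present(tc.fuculose).size == 0:
        raise ValueError("product (fuculose) series has no present values")
    if tc.lad is None or _present(tc.lad).size == 0:
        raise ValueError("substrate (lad) series has no present values")

    if titer_mode == "max":
        idx = int(np.nanargmax(tc.fuculose))
    elif titer_mode == "endpoint":
        idx = int(np.max(np.nonzero(~np.isnan(tc.fuculose))[0]))
    else:
        raise ValueError("titer_mode must be 'max' or 'endpoint'")
    titer = float(tc.fuculose[idx])
    t_max = float(tc.time[idx])

    lad_present = _present(tc.lad)
    first_lad = float(tc.lad[np.nonzero(~np.isnan(tc.lad))[0][0]])
    consumed = first_lad - float(np.min(lad_present))

    if consumed > 0:
        yield_pct = 100.0 * (titer / MW_FUCULOSE) / consumed
    else:
        yield_pct = 0.0 if titer == 0 else math.nan

    fold = fold_improvement(titer, reference_titer) if reference_titer else None
    return FermentationSummary(
        max_titer=titer,
        time_of_max=t_max,
        substrate_consumed=consumed,
        molar_yield_pct=yield_pct,
        fold_vs_reference=fold,
    )


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - int(math.floor(math.log10(abs(x)))) - 1)


def fold_improvement(titer: float, reference_titer: float) -> float:
    """Titer ratio against a reference process, to 3 significant figures.

    Scale-invariant: (k·a, k·b) gives the same ratio for any k > 0.
    """
    if reference_titer <= 0:
        raise ValueError("reference titer must be positive")
    return round_sig(titer / reference_titer, 3)
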