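"""Per-element instrument correction factors.

A correction factor for an element is the slope of the least-squares line
relating reference-assay concentrations (response) to instrument readings
(predictor). Applying a factor multiplies raw readings (and, in absolute
value, their instrument errors). Elements with no reference pairs carry an
explicit N/A factor and pass through application unchanged, flagged
uncalibrated. Negative factors are legal but warned about, and negative
corrected concentrations are floored at zero with a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import element_roster, err_col, ppm_col, write_table
from .simulate import PairedCalibrationSet

STATUS_OK = "ok"
STATUS_NA = "na"
STATUS_DEGENERATE = "degenerate"


class CalibrationMappingError(KeyError):
    """Raised when a table element has no entry (not even N/A) in the factors."""


@dataclass(frozen=True)
class ElementFactor:
    element: str
    factor: float | None
    fit_n: int
    fit_r2: float | None
    status: str = STATUS_OK


@dataclass
class CorrectionFactors:
    """Per-element regression slope factors with fit diagnostics."""

    factors: dict[str, ElementFactor]

    def __getitem__(self, element: str) -> ElementFactor:
        return self.factors[element]

    def __contains__(self, element: str) -> bool:
        return element in self.factors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "element": f.element,
                    "factor": f.factor,
                    "fit_n": f.fit_n,
                    "fit_r2": f.fit_r2,
                    "status": f.status,
                }
                for f in self.factors.values()
            ]
        )

    def to_csv(self, path: str | Path) -> Path:
        return write_table(self.to_frame(), path)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CorrectionFactors":
        factors = {}
        for _, row in frame.iterrows():
            factor = None if pd.isna(row["factor"]) else float(row["factor"])
            r2 = None if pd.isna(row["fit_r2"]) else float(row["fit_r2"])
            factors[row["element"]] = ElementFactor(
                element=row["element"],
                factor=factor,
                fit_n=int(row["fit_n"]),
                fit_r2=r2,
                status=str(row["status"]),
            )
        return cls(factors)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrectionFactors":
        return cls.from_frame(pd.read_csv(path, na_values=["NA"]))


@dataclass
class CorrectionFlags:
    """Bookkeeping from applying factors to a profile table."""

    uncalibrated: list[str] = field(default_factory=list)
    negative_factor: list[str] = field(default_factory=list)
    floored: dict[str, int] = field(default_factory=dict)


def fit_correction_factors(
    pairs: Mapping[str, PairedCalibrationSet | None],
    through_origin: bool = False,
) -> CorrectionFactors:
    """Fit one slope factor per element from paired reference/instrument data.

    Ordinary least squares of reference (response) on instrument (predictor)
    with an intercept; only the slope is retained. Elements mapped to None
    (no reference assay available) are recorded as N/A. A constant predictor
    yields a degenerate-fit entry for that element without blocking the rest.
    Negative slopes are returned as-is, never clamped.
    """
    out: dict[str, ElementFactor] = {}
    for el, ps in pairs.items():
        if ps is None:
            out[el] = ElementFactor(el, None, 0, None, STATUS_NA)
            continue
        x = np.asarray(ps.instrument_ppm, dtype=float)
        y = np.asarray(ps.reference_ppm, dtype=float)
        if np.ptp(x) == 0.0:
            out[el] = ElementFactor(el, None, ps.n, None, STATUS_DEGENERATE)
            continue
        if through_origin:
            slope = float(np.dot(x, y) / np.dot(x, x))
            resid = y - slope * x
            ss_tot = float(np.dot(y, y))
            r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else None
        else:
            fit = stats.linregress(x, y)
            slope = float(fit.slope)
            r2 = float(fit.rvalue**2)
        out[el] = ElementFactor(el, slope, ps.n, r2, STATUS_OK)
    return CorrectionFactors(out)


def apply_correction(
    table: pd.DataFrame,
    factors: CorrectionFactors,
    floor_negative: bool = True,
) -> tuple[pd.DataFrame, CorrectionFlags]:
    """Corrected concentration = factor x raw reading; errors scale by |factor|.

    Elements with an N/A (or degenerate) factor pass through unchanged and
    are flagged uncalibrated. An element entirely missing from the factors is
    a mapping error. Negative factors are applied as-is with a warning;
    resulting negative concentrations are floored at zero when
    ``floor_negative`` is set, with per-element flooring counts reported.
    """
    corrected = table.copy()
    flags = CorrectionFlags()
    for el in element_roster(table):
        if el not in factors:
            raise CalibrationMappingError(f"no correction-factor entry for element {el!r}")
        entry = factors[el]
        if entry.factor is None or entry.status != STATUS_OK:
            flags.uncalibrated.append(el)
            continue
        f = entry.factor
        if f < 0:
            warnings.warn(
                f"negative correction factor {f} for {el}; "
                "corrected concentrations will be floored at zero",
                stacklevel=2,
            )
            flags.negative_factor.append(el)
        corrected[ppm_col(el)] = corrected[ppm_col(el)] * f
        corrected[err_col(el)] = corrected[err_col(el)] * abs(f)
        if floor_negative:
            neg = corrected[ppm_col(el)] < 0
            if neg.any():
                flags.floored[el] = int(neg.sum())
                corrected.loc[neg, ppm_col(el)] = 0.0
    return corrected, flags
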