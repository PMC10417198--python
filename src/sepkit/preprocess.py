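"""Pre-treatment of profile tables before modelling.

Fixed order: (1) drop elements that are zero in more than a threshold
fraction of samples (strictly more than 80% by default), (2) within each
cluster of elements whose pairwise |Pearson r| meets an inclusive 0.8
threshold keep exactly one element, (3) z-scale the surviving columns to
mean 0 / sample SD 1, keeping the parameters for an exact inverse. Both
filters are computed on the full dataset before any train/test split, which
is the documented procedure this mirrors (and a known source of mild
leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import element_roster, err_col, ppm_col, write_table

DEFAULT_ZERO_THRESHOLD = 0.8
DEFAULT_R_THRESHOLD = 0.8


@dataclass(frozen=True)
class CorrelationRemoval:
    element: str
    kept_partner: str
    r: float


@dataclass
class PreprocessReport:
    removed_by_zero_filter: list[str] = field(default_factory=list)
    removed_by_correlation: list[CorrelationRemoval] = field(default_factory=list)
    scaling_params: pd.DataFrame | None = None

    def to_csv(self, path: str | Path) -> Path:
        rows = [
            {"step": "zero_filter", "element": el, "partner": "NA", "r": np.nan}
            for el in self.removed_by_zero_filter
        ]
        rows += [
            {"step": "correlation_filter", "element": r.element,
             "partner": r.kept_partner, "r": r.r}
            for r in self.removed_by_correlation
        ]
        return write_table(pd.DataFrame(rows, columns=["step", "element", "partner", "r"]), path)


def _drop_elements(table: pd.DataFrame, elements: list[str]) -> pd.DataFrame:
    cols = [c for el in elements for c in (ppm_col(el), err_col(el)) if c in table.columns]
    return table.drop(columns=cols)


def zero_fraction_filter(
    table: pd.DataFrame, threshold: float = DEFAULT_ZERO_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Remove elements whose zero fraction strictly exceeds the threshold."""
    if len(table) == 0:
        raise ValueError("table is empty")
    removed = []
    for el in element_roster(table):
        zero_frac = float((table[ppm_col(el)] == 0).mean())
        if zero_frac > threshold:
            removed.append(el)
    return _drop_elements(table, removed), removed


def correlation_filter(
    table: pd.DataFrame, r_threshold: float = DEFAULT_R_THRESHOLD
) -> tuple[pd.DataFrame, list[CorrelationRemoval]]:
    """Keep one element per group linked by |Pearson r| >= threshold.

    Repeatedly drops the element with the largest mean |r| to the remaining
    elements (among those involved in an over-threshold pair); ties are
    broken by roster order, dropping the later element. Constant columns have
    undefined correlations and are treated as uncorrelated, with a warning.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    roster = element_roster(table)
    values = {el: table[ppm_col(el)].to_numpy(dtype=float) for el in roster}
    constant = [el for el in roster if np.ptp(values[el]) == 0.0]
    if constant:
        warnings.warn(
            f"constant columns treated as uncorrelated: {constant}", stacklevel=2
        )
    active = [el for el in roster if el not in constant]
    corr = pd.DataFrame(values)[active].corr()

    removals: list[CorrelationRemoval] = []
    while len(active) >= 2:
        sub = corr.loc[active, active].abs()
        np.fill_diagonal(sub.values, 0.0)
        if not (sub.values >= r_threshold).any():
            break
        involved = [el for el in active if (sub.loc[el] >= r_threshold).any()]
        mean_abs = {el: float(sub.loc[el, [e for e in active if e != el]].mean())
                    for el in involved}
        best = max(mean_abs.values())
        # ties broken by roster order: among tied candidates drop the later one
        tied = [el for el in involved if mean_abs[el] == best]
        drop = max(tied, key=roster.index)
        others = [e for e in active if e != drop]
        partner = max(others, key=lambda e: sub.loc[drop, e])
        removals.append(
            CorrelationRemoval(
                element=drop, kept_partner=partner, r=float(corr.loc[drop, partner])
            )
        )
        active.remove(drop)
    kept = set(active) | set(constant)
    return _drop_elements(table, [el for el in roster if el not in kept]), removals


def scale(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-scale every element column to mean 0, sample SD 1.

    Returns the scaled table and a params frame (element, mean, sd) enabling
    an exact inverse transform. A zero-SD column is an error naming the
    element: it should have been filtered upstream.
    """
    scaled = table.copy()
    rows = []
    for el in element_roster(table):
        col = table[ppm_col(el)].to_numpy(dtype=float)
        mu = float(np.mean(col))
        sd = float(np.std(col, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"element {el!r} has zero variance; filter it before scaling")
        scaled[ppm_col(el)] = (col - mu) / sd
        rows.append({"element": el, "mean": mu, "sd": sd})
    return scaled, pd.DataFrame(rows)


def inverse_scale(table: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Undo :func:`scale` exactly, using the recorded per-element mean and SD."""
    out = table.copy()
    lookup = params.set_index("element")
    for el in element_roster(table):
        mu = float(lookup.loc[el, "mean"])
        sd = float(lookup.loc[el, "sd"])
        out[ppm_col(el)] = out[ppm_col(el)] * sd + mu
    return out


def preprocess(
    table: pd.DataFrame,
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full pre-treatment: zero filter, correlation filter, then scaling."""
    reduced, removed_zero = zero_fraction_filter(table, zero_threshold)
    reduced, removed_corr = correlation_filter(reduced, r_threshold)
    scaled, params = scale(reduced)
    report = PreprocessReport(
        removed_by_zero_filter=removed_zero,
        removed_by_correlation=removed_corr,
        scaling_params=params,
    )
    return scaled, report
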