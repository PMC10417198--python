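"""Profile quality-control statistics.

Three bespoke rules used to validate an elemental-profiling protocol:

* a detection-inclusion rule (a reading counts only when its instrument
  error is less than a fixed fraction of the concentration),
* an exposure-time optimizer driven by the improvement rate between
  consecutive slopes of the percent-error-vs-time curve,
* a repeatability delta comparing the instrument's self-reported error with
  the standard error of replicate readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import concentrations, errors

DEFAULT_DETECTION_RATIO = 1.0 / 3.0
DEFAULT_IMPROVEMENT_THRESHOLD = 33.0


class UndefinedPercentError(ValueError):
    """Raised when a percent error is requested for a non-positive concentration."""


class InsufficientSeriesError(ValueError):
    """Raised when an exposure series is too short to compute slope improvements."""


class InsufficientReplicatesError(ValueError):
    """Raised when fewer than two replicate readings are supplied."""


@dataclass(frozen=True)
class ExposureSeries:
    """Percent error of one element at each of an ordered set of exposure times."""

    element: str
    times_s: tuple[float, ...]
    percent_error: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        pe = np.asarray(self.percent_error, dtype=float)
        if t.size != pe.size:
            raise ValueError("times and percent errors must have equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("exposure times must be strictly increasing")
        if np.any(pe < 0):
            raise ValueError("percent errors must be non-negative")


@dataclass(frozen=True)
class RepeatabilitySummary:
    element: str | None
    average_instrument_error: float
    se: float
    delta: float
    n_rep: int
    interpretation: str = field(default="")


@dataclass(frozen=True)
class ExposureSelection:
    element: str
    selected_time_s: float
    slopes: tuple[float, ...]
    improvement_rates: tuple[float, ...]
    converged: bool
    zero_slope: bool


@dataclass(frozen=True)
class DetectionReport:
    pass_table: pd.DataFrame
    stats: pd.DataFrame
    roster: tuple[str, ...]
    empty_roster: bool


def percent_error(concentration: float, error: float) -> float:
    """100 * error / concentration for a single reading.

    Raises :class:`UndefinedPercentError` for non-positive concentrations so
    the caller can decide whether to exclude the reading.
    """
    if concentration <= 0:
        raise UndefinedPercentError(
            f"percent error undefined for concentration {concentration!r}"
        )
    if error < 0:
        raise ValueError("instrument error must be non-negative")
    return 100.0 * error / concentration


def detection_filter(
    table: pd.DataFrame,
    ratio: float = DEFAULT_DETECTION_RATIO,
    min_pass_fraction: float = 0.5,
) -> DetectionReport:
    """Per-reading detection flags and the per-element inclusion roster.

    A reading passes iff ``error < ratio * concentration`` (strict). Zero
    readings are neither pass nor fail. An element enters the roster iff it
    passes in more than ``min_pass_fraction`` of its nonzero readings.
    """
    conc = concentrations(table)
    err = errors(table)
    nonzero = conc > 0
    passed = (err.values < ratio * conc.values) & nonzero.values

    pass_table = pd.DataFrame(passed, index=conc.index, columns=conc.columns)
    pass_table = pass_table.astype("boolean").mask(~nonzero)

    n_nonzero = nonzero.sum(axis=0)
    n_pass = pd.DataFrame(passed, columns=conc.columns).sum(axis=0)
    frac = n_pass / n_nonzero.replace(0, np.nan)
    included = frac > min_pass_fraction

    stats = pd.DataFrame(
        {
            "element": conc.columns,
            "n_nonzero": n_nonzero.values,
            "n_pass": n_pass.values,
            "pass_fraction": frac.values,
            "included": included.fillna(False).values,
        }
    )
    roster = tuple(stats.loc[stats["included"], "element"])
    return DetectionReport(
        pass_table=pass_table,
        stats=stats,
        roster=roster,
        empty_roster=len(roster) == 0,
    )


def select_exposure_time(
    series: ExposureSeries,
    improvement_threshold: float = DEFAULT_IMPROVEMENT_THRESHOLD,
) -> ExposureSelection:
    """Pick the exposure time where the percent-error curve stops improving.

    Consecutive slopes ``S_k`` are taken between adjacent time points; the
    improvement rate from ``S_k`` to ``S_{k+1}`` is
    ``100 * |S_k - S_{k+1}| / |S_k|``. The selected time is the point shared
    by the first consecutive slope pair whose rate falls (strictly) below the
    threshold. A leading slope of exactly zero counts as 0% improvement
    (immediate stop) and is flagged. If no pair falls below the threshold the
    last time is returned, flagged not-converged.
    """
    t = np.asarray(series.times_s, dtype=float)
    y = np.asarray(series.percent_error, dtype=float)
    if t.size < 3:
        raise InsufficientSeriesError("need at least 3 time points (2 slopes)")

    slopes = np.diff(y) / np.diff(t)
    rates: list[float] = []
    zero_slope = False
    selected: float | None = None
    for k in range(slopes.size - 1):
        if slopes[k] == 0.0:
            rate = 0.0
            zero_slope = True
        else:
            rate = 100.0 * abs(slopes[k] - slopes[k + 1]) / abs(slopes[k])
        rates.append(rate)
        if selected is None and rate < improvement_threshold:
            selected = float(t[k + 1])  # the point shared by slopes k and k+1

    converged = selected is not None
    if selected is None:
        selected = float(t[-1])
    return ExposureSelection(
        element=series.element,
        selected_time_s=selected,
        slopes=tuple(float(s) for s in slopes),
        improvement_rates=tuple(rates),
        converged=converged,
        zero_slope=zero_slope,
    )


def repeatability_delta(
    readings: np.ndarray | list[float],
    instrument_errors: np.ndarray | list[float],
    element: str | None = None,
) -> RepeatabilitySummary:
    """Delta = mean per-reading instrument error minus the standard error.

    The standard error is the sample (n-1) standard deviation of the
    replicate readings divided by sqrt(n). A positive delta means replicate
    scatter is within the instrument's self-reported error.
    """
    x = np.asarray(readings, dtype=float)
    e = np.asarray(instrument_errors, dtype=float)
    if x.size < 2:
        raise InsufficientReplicatesError("need at least 2 replicate readings")
    if e.size != x.size:
        raise ValueError("one instrument error per reading is required")
    se = float(np.std(x, ddof=1) / np.sqrt(x.size))
    avg_err = float(np.mean(e))
    delta = avg_err - se
    interp = (
        "positive: scatter within instrument error"
        if delta >= 0
        else "negative: scatter exceeds instrument error"
    )
    return RepeatabilitySummary(
        element=element,
        average_instrument_error=avg_err,
        se=se,
        delta=delta,
        n_rep=int(x.size),
        interpretation=interp,
    )


def repeatability_summary(repeats: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`repeatability_delta` to a tidy replicate table.

    ``repeats`` has columns ``element, replicate, reading_ppm, error_ppm``.
    Returns one row per element: element, average_instrument_error, se,
    delta, n_rep.
    """
    rows = []
    for el, grp in repeats.groupby("element", sort=False):
        s = repeatability_delta(grp["reading_ppm"], grp["error_ppm"], element=el)
        rows.append(
            {
                "element": el,
                "average_instrument_error": s.average_instrument_error,
                "se": s.se,
                "delta": s.delta,
                "n_rep": s.n_rep,
            }
        )
    return pd.DataFrame(rows)


def exposure_report(
    selections: list[ExposureSelection], series: list[ExposureSeries]
) -> pd.DataFrame:
    """Long-format QC report: one row per (element, time point)."""
    by_el = {s.element: s for s in selections}
    rows = []
    for ser in series:
        sel = by_el[ser.element]
        for i, (t, pe) in enumerate(zip(ser.times_s, ser.percent_error)):
            rows.append(
                {
                    "element": ser.element,
                    "time_s": t,
                    "percent_error": pe,
                    "slope": sel.slopes[i - 1] if i >= 1 else np.nan,
                    "improvement_rate": (
                        sel.improvement_rates[i - 1]
                        if 1 <= i <= len(sel.improvement_rates)
                        else np.nan
                    ),
                    "selected": t == sel.selected_time_s,
                }
            )
    return pd.DataFrame(rows)
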