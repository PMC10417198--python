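"""Synthetic elemental-profile data with the structure the pipeline assumes.

Generates labelled profile tables (groups x samples with per-element
concentrations and instrument errors), paired reference-vs-instrument
calibration sets, replicate exposures, exposure-time percent-error curves,
and paired drying-treatment tables. Everything is driven by one
:class:`GeneratorConfig` and a single integer seed; sub-generators draw from
independent streams derived from that seed so whole-pipeline runs are
bit-reproducible.

The default configuration mimics a study design of 8 provenance groups
(6 sites, farmed/wild, raw/cooked) with 5 samples each, a 14-element profile
whose major elements (P, S, Cl, K, Ca) sit above 1000 ppm and whose minor
elements sit below 100 ppm, counting-statistics instrument errors that decay
with the square root of exposure time, and a heavily zero-inflated As
column. Effect sizes are illustrative only: no quantitative shifts are
published for site, cooking, or production contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import err_col, ppm_col
from .qc import ExposureSeries

# Fixed stream tags so each sub-generator gets an independent, stable stream
# from the one user-facing seed.
_STREAM_PROFILE = 1
_STREAM_CALIBRATION = 2
_STREAM_EXPOSURE = 3
_STREAM_REPEATS = 4
_STREAM_MOISTURE = 5

DEFAULT_ELEMENTS = (
    "P", "S", "Cl", "K", "Ca", "Mn", "Fe", "Ni", "Cu", "Zn", "As", "Sr", "Zr", "Th",
)


class ConfigurationError(ValueError):
    """Raised when a generator configuration references unknown elements."""


class InsufficientPairsError(ValueError):
    """Raised when fewer than 3 calibration pairs are requested."""


class InsufficientReplicatesError(ValueError):
    """Raised when fewer than 2 replicate exposures are requested."""


class DomainError(ValueError):
    """Raised for invalid exposure times."""


@dataclass(frozen=True)
class GroupDef:
    """One provenance group: unique site code, production, preparation, size."""

    site: str
    production: str  # "farmed" | "wild"
    preparation: str  # "raw" | "cooked"
    n_samples: int


@dataclass(frozen=True)
class PairedCalibrationSet:
    """Paired reference-assay and instrument readings for one element."""

    element: str
    reference_ppm: np.ndarray
    instrument_ppm: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_ppm, dtype=float)
        ins = np.asarray(self.instrument_ppm, dtype=float)
        if ref.shape != ins.shape or ref.ndim != 1:
            raise ValueError("reference and instrument vectors must pair 1:1")
        if ref.size < 3:
            raise InsufficientPairsError("need at least 3 pairs for a regression fit")
        object.__setattr__(self, "reference_ppm", ref)
        object.__setattr__(self, "instrument_ppm", ins)

    @property
    def n(self) -> int:
        return int(self.reference_ppm.size)


@dataclass(frozen=True)
class GeneratorConfig:
    element_roster: tuple[str, ...] = DEFAULT_ELEMENTS
    baseline_ppm: dict[str, float] = field(default_factory=dict)
    group_defs: tuple[GroupDef, ...] = ()
    # Multiplicative shifts. site_effects is keyed by site code; cooking
    # effects apply to cooked samples, production effects to wild samples.
    site_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    cooking_effects: dict[str, float] = field(default_factory=dict)
    production_effects: dict[str, float] = field(default_factory=dict)
    noise_cv: float | dict[str, float] = 0.1
    # error = k * sqrt(concentration) / sqrt(exposure_time_s)
    instrument_error_coeff: float | dict[str, float] = 1.0
    exposure_time_s: float = 60.0
    zero_inflation: dict[str, float] = field(default_factory=dict)
    # Deterministic zero pattern: for a listed element, exactly these row
    # indices stay nonzero and every other reading is zeroed.
    planted_nonzero: dict[str, tuple[int, ...]] = field(default_factory=dict)
    # True instrument bias b: instrument reading ~ reference / b, so b is the
    # correction factor a downstream regression should recover.
    bias_slope: dict[str, float] = field(default_factory=dict)
    calibration_noise_cv: float = 0.05
    reference_cv: float = 0.5
    # When True, profile concentrations are emitted on the uncorrected
    # instrument scale (divided by bias_slope) so a calibration stage has
    # something to undo.
    apply_bias_to_profile: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        roster = set(self.element_roster)
        for name, mapping in [
            ("baseline_ppm", self.baseline_ppm),
            ("cooking_effects", self.cooking_effects),
            ("production_effects", self.production_effects),
            ("zero_inflation", self.zero_inflation),
            ("planted_nonzero", self.planted_nonzero),
            ("bias_slope", self.bias_slope),
        ]:
            for el in mapping:
                if el not in roster:
                    raise ConfigurationError(f"{name} references unknown element {el!r}")
        for site, effects in self.site_effects.items():
            for el in effects:
                if el not in roster:
                    raise ConfigurationError(
                        f"site_effects[{site!r}] references unknown element {el!r}"
                    )
        if isinstance(self.noise_cv, dict):
            for el in self.noise_cv:
                if el not in roster:
                    raise ConfigurationError(f"noise_cv references unknown element {el!r}")
        if isinstance(self.instrument_error_coeff, dict):
            for el in self.instrument_error_coeff:
                if el not in roster:
                    raise ConfigurationError(
                        f"instrument_error_coeff references unknown element {el!r}"
                    )
        missing = [el for el in self.element_roster if el not in self.baseline_ppm]
        if missing:
            raise ConfigurationError(f"baseline_ppm missing elements: {missing}")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def _per_element(self, value: float | dict[str, float], el: str, default: float) -> float:
        if isinstance(value, dict):
            return value.get(el, default)
        return float(value)

    def noise_cv_for(self, el: str) -> float:
        return self._per_element(self.noise_cv, el, 0.0)

    def error_coeff_for(self, el: str) -> float:
        return self._per_element(self.instrument_error_coeff, el, 0.0)

    @property
    def n_samples_total(self) -> int:
        return sum(g.n_samples for g in self.group_defs)


def default_config(seed: int = 0) -> GeneratorConfig:
    """Configuration mirroring the 8-group x 5-sample reference design.

    Baselines put P, S, Cl, K, Ca above 1000 ppm and the minors below
    100 ppm. Cooked samples are shifted up in Cl, Zn, Th, Cu, Mn and down in
    Zr; wild samples carry more S and less Ni. The As column is planted to be
    nonzero in exactly 3 of the 40 samples (all raw). Effect sizes are
    illustrative defaults, not estimates.
    """
    groups = (
        GroupDef("1fr", "farmed", "raw", 5),
        GroupDef("2fr", "farmed", "raw", 5),
        GroupDef("2fc", "farmed", "cooked", 5),
        GroupDef("3fc-jan", "farmed", "cooked", 5),
        GroupDef("3fc-feb", "farmed", "cooked", 5),
        GroupDef("4fc", "farmed", "cooked", 5),
        GroupDef("5wr", "wild", "raw", 5),
        GroupDef("6wc", "wild", "cooked", 5),
    )
    baseline = {
        "P": 6000.0, "S": 3200.0, "Cl": 4500.0, "K": 3500.0, "Ca": 2000.0,
        "Mn": 15.0, "Fe": 45.0, "Ni": 8.0, "Cu": 25.0, "Zn": 60.0,
        "As": 2.0, "Sr": 30.0, "Zr": 6.0, "Th": 4.0,
    }
    # Mild per-site fingerprints on a few elements per site.
    site_effects = {
        "1fr": {"P": 1.10, "Sr": 1.25, "Zn": 0.90},
        "2fr": {"P": 1.05, "Sr": 1.15, "Zn": 0.95},
        "2fc": {"K": 1.15, "Mn": 1.30, "Cu": 0.85},
        "3fc-jan": {"Cl": 1.20, "Fe": 1.25, "Ni": 1.20},
        "3fc-feb": {"Cl": 1.12, "Fe": 1.18, "Ni": 1.25},
        "4fc": {"Ca": 1.20, "Th": 1.40, "S": 0.90},
        "5wr": {"Zn": 1.30, "Mn": 0.80, "P": 0.92},
        "6wc": {"Cu": 1.30, "Sr": 0.85, "K": 0.90},
    }
    cooking = {"Cl": 1.35, "Zn": 1.30, "Th": 1.40, "Cu": 1.25, "Mn": 1.30, "Zr": 0.65, "K": 0.85}
    production = {"S": 1.30, "Ni": 0.70}  # applied to wild samples
    bias = {
        "P": 0.7196, "S": 0.3138, "Cl": 0.6894, "K": 0.7977, "Ca": 1.1036,
        "Mn": 2.2247, "Fe": 0.4202, "Ni": 1.6250, "Cu": 0.4114, "Zn": 0.1765,
        "As": 2.1486, "Sr": 1.3978,
        # Zr and Th carry no bias entry: no reference assay, factor is N/A.
    }
    return GeneratorConfig(
        element_roster=DEFAULT_ELEMENTS,
        baseline_ppm=baseline,
        group_defs=groups,
        site_effects=site_effects,
        cooking_effects=cooking,
        production_effects=production,
        noise_cv=0.08,
        instrument_error_coeff=0.8,
        exposure_time_s=60.0,
        zero_inflation={},
        planted_nonzero={"As": (0, 7, 31)},  # three raw samples (1fr, 2fr, 5wr)
        bias_slope=bias,
        seed=seed,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=n)


def generate_profile_table(config: GeneratorConfig) -> pd.DataFrame:
    """One row per sample: labels, then per-element concentration and error.

    concentration = baseline x site x cooking x production effects x
    lognormal noise; the instrument error follows the counting-statistics
    model ``k * sqrt(concentration) / sqrt(t)``. Zero-inflation is applied
    after noise and zeroes both the concentration and its error.
    """
    if not config.group_defs:
        raise ConfigurationError("group_defs is empty")
    for g in config.group_defs:
        if g.n_samples < 2:
            raise ConfigurationError(f"group {g.site!r} must have >= 2 samples")

    rng = np.random.default_rng([config.seed, _STREAM_PROFILE])
    n = config.n_samples_total

    labels: list[dict[str, str]] = []
    for g in config.group_defs:
        for i in range(g.n_samples):
            labels.append(
                {
                    "sample_id": f"{g.site}-{i + 1:02d}",
                    "site": g.site,
                    "production": g.production,
                    "preparation": g.preparation,
                }
            )
    table = pd.DataFrame(labels)

    site_of_row = table["site"].to_numpy()
    cooked = (table["preparation"] == "cooked").to_numpy()
    wild = (table["production"] == "wild").to_numpy()

    t = config.exposure_time_s
    for el in config.element_roster:
        mult = np.ones(n)
        for site, effects in config.site_effects.items():
            mult[site_of_row == site] *= effects.get(el, 1.0)
        mult[cooked] *= config.cooking_effects.get(el, 1.0)
        mult[wild] *= config.production_effects.get(el, 1.0)

        conc = config.baseline_ppm[el] * mult * _lognormal_noise(
            rng, config.noise_cv_for(el), n
        )
        if config.apply_bias_to_profile and el in config.bias_slope:
            conc = conc / config.bias_slope[el]
        err = config.error_coeff_for(el) * np.sqrt(np.abs(conc)) / math.sqrt(t)

        if el in config.planted_nonzero:
            keep = np.zeros(n, dtype=bool)
            keep[list(config.planted_nonzero[el])] = True
            conc = np.where(keep, conc, 0.0)
            err = np.where(keep, err, 0.0)
        elif config.zero_inflation.get(el, 0.0) > 0.0:
            zero = rng.uniform(size=n) < config.zero_inflation[el]
            conc = np.where(zero, 0.0, conc)
            err = np.where(zero, 0.0, err)

        table[ppm_col(el)] = conc
        table[err_col(el)] = err
    return table


def generate_paired_calibration_set(
    config: GeneratorConfig, element: str, n: int
) -> PairedCalibrationSet:
    """Paired reference/instrument readings with a planted bias slope.

    Reference values are drawn lognormally around the element baseline;
    instrument values are ``reference / bias_slope`` plus centred noise on
    the instrument scale, so an OLS fit of reference on instrument recovers
    the bias slope as its correction factor.
    """
    if element not in config.bias_slope:
        raise ConfigurationError(f"bias_slope not defined for element {element!r}")
    if n < 3:
        raise InsufficientPairsError("need at least 3 pairs for a regression fit")
    el_idx = config.element_roster.index(element)
    rng = np.random.default_rng([config.seed, _STREAM_CALIBRATION, el_idx])
    baseline = config.baseline_ppm[element]
    ref = baseline * _lognormal_noise(rng, config.reference_cv, n)
    instrument_true = ref / config.bias_slope[element]
    noise_sd = config.calibration_noise_cv * np.abs(instrument_true)
    instrument = instrument_true + rng.normal(0.0, 1.0, size=n) * noise_sd
    return PairedCalibrationSet(element=element, reference_ppm=ref, instrument_ppm=instrument)


def generate_exposure_series(
    config: GeneratorConfig,
    times_s: tuple[float, ...] | list[float],
    coeffs: dict[str, float] | None = None,
    jitter_cv: float = 0.0,
    elements: tuple[str, ...] | None = None,
) -> list[ExposureSeries]:
    """Percent-error curves ``c / sqrt(t)`` per element at the given times.

    ``coeffs`` overrides the per-element constant ``c``; by default it is
    derived from the counting-statistics model at the element baseline
    (``100 * k / sqrt(baseline)``). ``jitter_cv`` adds multiplicative
    lognormal jitter; zero gives the exact closed form for analytic tests.
    """
    t = np.asarray(times_s, dtype=float)
    if np.any(t <= 0):
        raise DomainError("exposure times must be positive")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise DomainError("exposure times must be strictly increasing")
    rng = np.random.default_rng([config.seed, _STREAM_EXPOSURE])
    out: list[ExposureSeries] = []
    for el in elements if elements is not None else config.element_roster:
        if coeffs is not None and el in coeffs:
            c = coeffs[el]
        else:
            base = config.baseline_ppm[el]
            c = 100.0 * config.error_coeff_for(el) / math.sqrt(base) if base > 0 else 0.0
        pe = c / np.sqrt(t)
        if jitter_cv > 0.0:
            pe = pe * _lognormal_noise(rng, jitter_cv, t.size)
        out.append(
            ExposureSeries(element=el, times_s=tuple(t), percent_error=tuple(pe))
        )
    return out


def generate_repeat_exposures(config: GeneratorConfig, n_rep: int) -> pd.DataFrame:
    """Tidy table of replicate readings: element, replicate, reading, error.

    Replicate scatter is generated at the instrument-error scale so the
    repeatability delta is positive with high probability when the error
    model is faithful. A zero error coefficient yields identical readings.
    """
    if n_rep < 2:
        raise InsufficientReplicatesError("need at least 2 replicate exposures")
    rng = np.random.default_rng([config.seed, _STREAM_REPEATS])
    rows = []
    for el in config.element_roster:
        true = config.baseline_ppm[el]
        err = config.error_coeff_for(el) * math.sqrt(true) / math.sqrt(config.exposure_time_s)
        readings = true + rng.normal(0.0, err if err > 0 else 0.0, size=n_rep)
        for i in range(n_rep):
            rows.append(
                {
                    "element": el,
                    "replicate": i + 1,
                    "reading_ppm": readings[i],
                    "error_ppm": err,
                }
            )
    return pd.DataFrame(rows)


def generate_moisture_pairs(
    config: GeneratorConfig,
    n_raw: int = 5,
    n_cooked: int = 10,
    treatment_effect: float | dict[str, float] = 1.0,
    all_zero_in_cooked: tuple[str, ...] = ("As",),
):
    """Paired drying-treatment readings, stratified raw/cooked.

    Treatment A is the lightly dried reading; treatment B is the same sample
    after further drying, shifted by ``treatment_effect`` and re-measured
    with fresh noise. Elements in ``all_zero_in_cooked`` are zeroed in the
    cooked stratum (both treatments) to exercise the all-zero flag.
    """
    from .moisture import PairedTreatmentTable

    rng = np.random.default_rng([config.seed, _STREAM_MOISTURE])
    strata = ["raw"] * n_raw + ["cooked"] * n_cooked
    ids = [f"m{i + 1:02d}" for i in range(len(strata))]
    cooked = np.array([s == "cooked" for s in strata])

    a_cols: dict[str, np.ndarray] = {}
    b_cols: dict[str, np.ndarray] = {}
    n = len(strata)
    for el in config.element_roster:
        base = config.baseline_ppm[el] * np.where(
            cooked, config.cooking_effects.get(el, 1.0), 1.0
        )
        cv = config.noise_cv_for(el)
        a = base * _lognormal_noise(rng, cv, n)
        shift = (
            treatment_effect.get(el, 1.0)
            if isinstance(treatment_effect, dict)
            else float(treatment_effect)
        )
        b = a * shift * _lognormal_noise(rng, cv, n)
        if el in all_zero_in_cooked:
            a = np.where(cooked, 0.0, a)
            b = np.where(cooked, 0.0, b)
        a_cols[el] = a
        b_cols[el] = b

    index = pd.Index(ids, name="sample_id")
    return PairedTreatmentTable(
        treatment_a=pd.DataFrame(a_cols, index=index),
        treatment_b=pd.DataFrame(b_cols, index=index),
        strata=pd.Series(strata, index=index, name="preparation"),
    )
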