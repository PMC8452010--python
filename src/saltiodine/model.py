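"""Salt and iodine intake assessment for iodization programmes.

Implements a point-estimate dietary exposure pipeline: household-survey
records are reduced to per-capita daily consumption of discretionary
(household) salt and of salt-containing industrially processed foods (IPF);
per-source salt intake is converted to iodine intake under a salt-iodization
standard (concentration x retention x iodized fraction); salt-reduction
scenarios rescale all sources uniformly; and totals are compared with the
EAR, RNI and UL nutrient reference values for iodine and with the WHO 5 g/day
salt maximum.

The module is laid out in the order the method runs:

1.  constants, errors, rounding policy
2.  domain types
3.  core model (per-source salt -> iodine -> scenarios -> reference comparison)
4.  survey aggregation (household records -> district -> province estimates)
5.  synthetic data (survey generator with known ground truth; the Sri Lanka
    2015/16 assessment inputs as a built-in fixture)
6.  reporting & I/O (CSV/YAML dialects, presentation tables, chart export)

All computation is carried in full floating precision; rounding (salt to one
decimal, iodine and percents to the nearest integer, half-up) happens only at
presentation time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("saltiodine")

__all__ = [
    # errors
    "SaltIodineError", "ValidationError", "ConfigurationError",
    "AggregationError", "RenderingError",
    # constants
    "HOUSEHOLD_SALT", "DEFAULT_WHO_SALT_MAX_G", "DEFAULT_DAYS_PER_MONTH",
    # types
    "FoodProduct", "HouseholdSaltSource", "RegionProfile", "IodizationParams",
    "ReferenceValues", "Scenario", "IntakeResult", "HouseholdRecord",
    "DistrictEstimate", "GeneratorConfig", "AssessmentInputs",
    "PresentationTable",
    # core model
    "salt_intake", "iodine_from_salt", "compare_to_references",
    "assess_region", "apply_reduction", "assemble_assessment", "screen_foods",
    # survey aggregation
    "per_capita_daily", "district_summary", "summarize_districts",
    "weight_to_province", "national_from_districts", "records_to_frame",
    # synthetic data
    "generate_households", "sri_lanka_fixture", "DEFAULT_SCENARIOS",
    # reporting / io
    "round_half_up", "results_to_frame", "frame_to_results",
    "write_results_csv", "read_results_csv",
    "read_foods_csv", "write_foods_csv",
    "read_regions_csv", "write_regions_csv",
    "read_params_yaml", "write_params_yaml",
    "read_households_csv", "write_households_csv",
    "read_districts_csv", "write_districts_csv",
    "render_salt_table", "render_iodine_table", "export_reference_chart",
]


# ---------------------------------------------------------------------------
# 1. Constants, errors, rounding policy
# ---------------------------------------------------------------------------

#: Reserved source name for discretionary (home-added) salt. Household salt is
#: treated as a source with salt fraction 1 and iodized fraction equal to the
#: household iodized-salt coverage, so the "a" factor is uniform across sources.
HOUSEHOLD_SALT = "household_salt"

#: WHO recommended maximum daily salt intake for adults, g/day. Display only.
DEFAULT_WHO_SALT_MAX_G = 5.0

#: Divisor converting a monthly household quantity to a daily one.
DEFAULT_DAYS_PER_MONTH = 30.0


class SaltIodineError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(SaltIodineError, ValueError):
    """A value violates a domain invariant (range, sign, NaN)."""


class ConfigurationError(SaltIodineError):
    """Inputs are individually valid but mutually inconsistent."""


class AggregationError(SaltIodineError):
    """A survey aggregation step received degenerate input."""


class RenderingError(SaltIodineError):
    """A presentation table cannot be built from the given results."""


def _check(value: float, name: str, *, lo: float = 0.0, hi: float | None = None,
           lo_strict: bool = False) -> float:
    """Validate a numeric field; NaN and out-of-range values are rejected."""
    v = float(value)
    if math.isnan(v):
        raise ValidationError(f"{name} is NaN")
    if lo_strict and v <= lo:
        raise ValidationError(f"{name} must be > {lo}, got {v}")
    if not lo_strict and v < lo:
        raise ValidationError(f"{name} must be >= {lo}, got {v}")
    if hi is not None and v > hi:
        raise ValidationError(f"{name} must be <= {hi}, got {v}")
    return v


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Python's builtin ``round`` is half-even; the printed tables this package
    reproduces follow the half-up convention (e.g. 1.5435 ug -> 2 ug). The
    value is routed through its shortest decimal repr so that quantities that
    are decimal numbers in spirit (0.45, 0.15) round as a reader expects.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _display_int(x: float) -> int:
    return int(round_half_up(x, 0))


# ---------------------------------------------------------------------------
# 2. Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoodProduct:
    """A salt-containing product.

    Parameters
    ----------
    name:
        Label, unique within an assessment.
    salt_fraction:
        Fraction of product weight that is salt (0.01 for a 1%-salt bread).
    iodized_fraction:
        Fraction of the salt used in this product that is iodized at the
        standard level ("a" in the current-intake equation); 0 for products
        exempt from iodization, 1 where industry uses iodized salt only.
    """

    name: str
    salt_fraction: float
    iodized_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("FoodProduct.name must be non-empty")
        _check(self.salt_fraction, "salt_fraction", hi=1.0)
        _check(self.iodized_fraction, "iodized_fraction", hi=1.0)


@dataclass(frozen=True)
class HouseholdSaltSource:
    """Discretionary salt intake and its iodized-salt coverage."""

    intake_g_per_day: float
    coverage: float

    def __post_init__(self) -> None:
        _check(self.intake_g_per_day, "intake_g_per_day")
        _check(self.coverage, "coverage", hi=1.0)


@dataclass(frozen=True)
class RegionProfile:
    """One region's consumption vector and household-salt coverage.

    ``consumption`` maps food name -> grams/person/day; ``population_weight``
    is a relative population used only when aggregating survey estimates.
    """

    name: str
    household_salt: HouseholdSaltSource
    consumption: Mapping[str, float]
    population_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("RegionProfile.name must be non-empty")
        _check(self.population_weight, "population_weight")
        for food, grams in self.consumption.items():
            _check(grams, f"consumption[{food!r}]")


@dataclass(frozen=True)
class IodizationParams:
    """Salt-iodization standard used for the conversion to iodine.

    ``iodine_mg_per_kg`` is the iodine concentration of iodized salt (mg
    iodine per kg salt; the modelling default is the midpoint of a legal
    range). ``retention`` is the fraction of added iodine surviving
    production-to-consumption losses (0.7 encodes the WHO 30% loss estimate).
    Note g salt x mg/kg = ug, so no further unit factor appears.
    """

    iodine_mg_per_kg: float = 22.5
    retention: float = 0.7

    def __post_init__(self) -> None:
        _check(self.iodine_mg_per_kg, "iodine_mg_per_kg")
        _check(self.retention, "retention", hi=1.0)


@dataclass(frozen=True)
class ReferenceValues:
    """Iodine nutrient reference values for non-pregnant adults, ug/day."""

    ear_ug: float = 95.0
    rni_ug: float = 150.0
    ul_ug: float = 600.0

    def __post_init__(self) -> None:
        _check(self.ear_ug, "ear_ug", lo_strict=True)
        if not (self.ear_ug <= self.rni_ug <= self.ul_ug):
            raise ValidationError(
                f"reference values must satisfy ear_ug <= rni_ug <= ul_ug, "
                f"got {self.ear_ug}, {self.rni_ug}, {self.ul_ug}")


@dataclass(frozen=True)
class Scenario:
    """A what-if condition applied to an assessment.

    ``salt_scale`` multiplies every source's salt intake (0.7 models the WHO
    30% salt-reduction target). ``mode`` selects whether iodized fractions are
    forced to 1 ("potential": all salt iodized) or taken as observed
    ("current").
    """

    label: str
    mode: str = "current"
    salt_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("potential", "current"):
            raise ValidationError(
                f"Scenario.mode must be 'potential' or 'current', got {self.mode!r}")
        _check(self.salt_scale, "salt_scale", lo_strict=True)


#: The three conditions of the published assessment: all salt iodized,
#: observed iodization, and observed iodization after a 30% salt reduction.
DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("potential", mode="potential", salt_scale=1.0),
    Scenario("current", mode="current", salt_scale=1.0),
    Scenario("current_minus30", mode="current", salt_scale=0.7),
)


@dataclass(frozen=True)
class IntakeResult:
    """Per-source and total salt and iodine intake for one region x scenario.

    Salt in g/day, iodine in ug/day, all unrounded; ``pct_*`` fields are
    percents of the reference values computed from the unrounded totals.
    """

    region: str
    scenario: str
    per_source_salt_g: Mapping[str, float]
    total_salt_g: float
    per_source_iodine_ug: Mapping[str, float]
    total_iodine_ug: float
    pct_ear: float
    pct_rni: float
    pct_ul: float
    pct_who_salt: float
    coverage: float | None = None


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household: size, monthly salt, monthly food quantities."""

    household_id: str
    district: str
    household_size: int
    monthly_salt_g: float
    food_quantities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.household_size) < 1:
            raise ValidationError(
                f"household_size must be >= 1, got {self.household_size} "
                f"(household {self.household_id!r})")
        _check(self.monthly_salt_g, "monthly_salt_g")
        for food, grams in self.food_quantities.items():
            _check(grams, f"food_quantities[{food!r}]")


@dataclass(frozen=True)
class DistrictEstimate:
    """Mean per-capita daily consumption for one district, with population."""

    district: str
    population: float
    per_capita_daily: Mapping[str, float]
    n_households: int = 0

    def __post_init__(self) -> None:
        _check(self.population, "population")
        for source, grams in self.per_capita_daily.items():
            _check(grams, f"per_capita_daily[{source!r}]")


@dataclass(frozen=True)
class AssessmentInputs:
    """A complete ready-to-run assessment: foods, regions and parameters."""

    foods: tuple[FoodProduct, ...]
    regions: tuple[RegionProfile, ...]
    params: IodizationParams
    refs: ReferenceValues
    national: str
    who_salt_max_g: float = DEFAULT_WHO_SALT_MAX_G
    scenarios: tuple[Scenario, ...] = DEFAULT_SCENARIOS


# ---------------------------------------------------------------------------
# 3. Core model
# ---------------------------------------------------------------------------

def salt_intake(consumption_g_per_day: float, salt_fraction: float) -> float:
    """Daily salt intake (g) from one product: consumption x salt fraction."""
    q = _check(consumption_g_per_day, "consumption_g_per_day")
    f = _check(salt_fraction, "salt_fraction", hi=1.0)
    return q * f


def iodine_from_salt(salt_g_per_day: float, params: IodizationParams,
                     iodized_fraction: float = 1.0) -> float:
    """Daily iodine intake (ug) delivered by ``salt_g_per_day`` grams of salt.

    salt (g) x concentration (mg iodine / kg salt) x retention x iodized
    fraction; g x mg/kg = ug exactly. ``iodized_fraction = 1`` gives the
    potential intake (all salt iodized); the observed fraction gives the
    current intake.
    """
    s = _check(salt_g_per_day, "salt_g_per_day")
    a = _check(iodized_fraction, "iodized_fraction", hi=1.0)
    return s * params.iodine_mg_per_kg * params.retention * a


def compare_to_references(total_iodine_ug: float,
                          refs: ReferenceValues) -> tuple[float, float, float]:
    """Percent of EAR, RNI and UL met by an unrounded iodine total."""
    t = _check(total_iodine_ug, "total_iodine_ug")
    for name, ref in (("ear_ug", refs.ear_ug), ("rni_ug", refs.rni_ug),
                      ("ul_ug", refs.ul_ug)):
        if ref <= 0:
            raise ValidationError(f"{name} must be positive, got {ref}")
    return (100.0 * t / refs.ear_ug,
            100.0 * t / refs.rni_ug,
            100.0 * t / refs.ul_ug)


def _iodized_fraction(scenario: Scenario, observed: float) -> float:
    return 1.0 if scenario.mode == "potential" else observed


def assess_region(profile: RegionProfile, foods: Iterable[FoodProduct],
                  params: IodizationParams, refs: ReferenceValues,
                  scenario: Scenario,
                  who_salt_max_g: float = DEFAULT_WHO_SALT_MAX_G) -> IntakeResult:
    """Assess one region under one scenario.

    Household salt enters as its own source (salt fraction implicitly 1,
    iodized fraction = household coverage); each food contributes
    consumption x salt fraction. The scenario's ``salt_scale`` multiplies
    every source, and ``mode='potential'`` forces every iodized fraction to 1.
    Totals and percent-of-reference fields are computed from unrounded sums.
    """
    foods = list(foods)
    catalog = {f.name: f for f in foods}
    if len(catalog) < len(foods):
        raise ConfigurationError("duplicate food names in catalog")
    unknown = sorted(set(profile.consumption) - set(catalog))
    if unknown:
        raise ConfigurationError(
            f"region {profile.name!r} consumes unknown foods: {', '.join(unknown)}")

    per_salt: dict[str, float] = {
        HOUSEHOLD_SALT: profile.household_salt.intake_g_per_day * scenario.salt_scale}
    per_frac: dict[str, float] = {
        HOUSEHOLD_SALT: _iodized_fraction(scenario, profile.household_salt.coverage)}
    # keep catalog order for presentation; only foods the region consumes
    for name in catalog:
        if name in profile.consumption:
            per_salt[name] = (salt_intake(profile.consumption[name],
                                          catalog[name].salt_fraction)
                              * scenario.salt_scale)
            per_frac[name] = _iodized_fraction(scenario,
                                               catalog[name].iodized_fraction)

    per_iodine = {name: iodine_from_salt(grams, params, per_frac[name])
                  for name, grams in per_salt.items()}
    total_salt = sum(per_salt.values())
    total_iodine = sum(per_iodine.values())
    pct_ear, pct_rni, pct_ul = compare_to_references(total_iodine, refs)
    return IntakeResult(
        region=profile.name,
        scenario=scenario.label,
        per_source_salt_g=per_salt,
        total_salt_g=total_salt,
        per_source_iodine_ug=per_iodine,
        total_iodine_ug=total_iodine,
        pct_ear=pct_ear, pct_rni=pct_rni, pct_ul=pct_ul,
        pct_who_salt=100.0 * total_salt / who_salt_max_g,
        coverage=profile.household_salt.coverage,
    )


def apply_reduction(profile: RegionProfile, foods: Iterable[FoodProduct],
                    params: IodizationParams, refs: ReferenceValues,
                    reduction_factor: float, mode: str = "current",
                    who_salt_max_g: float = DEFAULT_WHO_SALT_MAX_G) -> IntakeResult:
    """Assess a region with all salt intakes scaled by ``reduction_factor``.

    A factor of 0.7 models the WHO 30% salt-reduction target applied evenly
    across all sources. By linearity every salt and iodine field equals the
    unreduced field times the factor.
    """
    if not (0.0 < reduction_factor <= 1.0):
        raise ValidationError(
            f"reduction_factor must be in (0, 1], got {reduction_factor}")
    scen = Scenario(label=f"{mode}_x{reduction_factor:g}", mode=mode,
                    salt_scale=reduction_factor)
    return assess_region(profile, foods, params, refs, scen, who_salt_max_g)


def assemble_assessment(inputs: AssessmentInputs) -> list[IntakeResult]:
    """Run every region under every scenario.

    Regions keep their input order with the designated national region moved
    last; the national row is computed from the national profile's own inputs,
    never as a weighted average of the provinces. Returns one
    :class:`IntakeResult` per region x scenario (scenario-major order).
    """
    names = [p.name for p in inputs.regions]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ConfigurationError(f"duplicate region names: {', '.join(dupes)}")
    if inputs.national not in names:
        raise ConfigurationError(
            f"national region {inputs.national!r} not among regions")
    ordered = ([p for p in inputs.regions if p.name != inputs.national]
               + [p for p in inputs.regions if p.name == inputs.national])
    return [assess_region(p, inputs.foods, inputs.params, inputs.refs, scen,
                          inputs.who_salt_max_g)
            for scen in inputs.scenarios for p in ordered]


def screen_foods(consumption: Mapping[str, float],
                 foods: Iterable[FoodProduct], params: IodizationParams,
                 threshold_ug: float = 1.5) -> dict[str, float]:
    """Screen candidate foods by potential iodine contribution.

    Returns ``{name: potential ug/day}`` for foods whose fully-iodized
    contribution meets ``threshold_ug``; foods below it are dropped (logged).
    The caller supplies the candidate consumption table.
    """
    catalog = {f.name: f for f in foods}
    kept: dict[str, float] = {}
    for name, grams in consumption.items():
        if name not in catalog:
            raise ConfigurationError(f"unknown food in screening input: {name!r}")
        ug = iodine_from_salt(salt_intake(grams, catalog[name].salt_fraction),
                              params, 1.0)
        if ug >= threshold_ug:
            kept[name] = ug
        else:
            logger.info("screening: dropped %s (%.2f ug/day < %.2f)",
                        name, ug, threshold_ug)
    return kept


# ---------------------------------------------------------------------------
# 4. Survey aggregation
# ---------------------------------------------------------------------------

def per_capita_daily(monthly_quantity_g: float, household_size: int,
                     days_per_month: float = DEFAULT_DAYS_PER_MONTH) -> float:
    """Per-capita daily quantity: monthly household quantity / members / days."""
    q = _check(monthly_quantity_g, "monthly_quantity_g")
    if int(household_size) < 1:
        raise ValidationError(f"household_size must be >= 1, got {household_size}")
    d = _check(days_per_month, "days_per_month", lo_strict=True)
    return q / int(household_size) / d


def records_to_frame(records: Iterable[HouseholdRecord],
                     days_per_month: float = DEFAULT_DAYS_PER_MONTH) -> pd.DataFrame:
    """Per-capita daily values per household, tidy: one row per household,
    one column per source (household salt under :data:`HOUSEHOLD_SALT`)."""
    rows = []
    for r in records:
        row = {"household_id": r.household_id, "district": r.district,
               HOUSEHOLD_SALT: per_capita_daily(r.monthly_salt_g,
                                                r.household_size, days_per_month)}
        for food, grams in r.food_quantities.items():
            row[food] = per_capita_daily(grams, r.household_size, days_per_month)
        rows.append(row)
    if not rows:
        raise AggregationError("no household records supplied")
    return pd.DataFrame(rows)


def district_summary(records: Sequence[HouseholdRecord],
                     statistic: str = "mean",
                     days_per_month: float = DEFAULT_DAYS_PER_MONTH,
                     ) -> tuple[dict[str, float], int]:
    """Central per-capita daily estimate for one district's households.

    Returns ``(source -> g/person/day, n_households)``. The default statistic
    is the arithmetic mean; ``statistic='median'`` is available.
    """
    records = list(records)
    if not records:
        raise AggregationError("district_summary received an empty district")
    districts = {r.district for r in records}
    if len(districts) > 1:
        raise AggregationError(
            f"district_summary expects one district, got {sorted(districts)}")
    if statistic not in ("mean", "median"):
        raise ValidationError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    frame = records_to_frame(records, days_per_month)
    values = frame.drop(columns=["household_id", "district"]).fillna(0.0)
    agg = values.mean() if statistic == "mean" else values.median()
    return {k: float(v) for k, v in agg.items()}, len(records)


def summarize_districts(records: Iterable[HouseholdRecord],
                        populations: Mapping[str, float],
                        statistic: str = "mean",
                        days_per_month: float = DEFAULT_DAYS_PER_MONTH,
                        ) -> list[DistrictEstimate]:
    """Apply :func:`district_summary` to every district present in ``records``."""
    by_district: dict[str, list[HouseholdRecord]] = {}
    for r in records:
        by_district.setdefault(r.district, []).append(r)
    out = []
    for district in by_district:
        if district not in populations:
            raise ConfigurationError(f"district {district!r} has no population")
        values, n = district_summary(by_district[district], statistic,
                                     days_per_month)
        out.append(DistrictEstimate(district=district,
                                    population=populations[district],
                                    per_capita_daily=values, n_households=n))
    return out


def weight_to_province(estimates: Iterable[DistrictEstimate],
                       province_map: Mapping[str, str]) -> dict[str, dict[str, float]]:
    """Population-weighted provincial estimates from district estimates.

    province value = sum(pop_d * value_d) / sum(pop_d) per source, over the
    districts mapped to that province.
    """
    by_province: dict[str, list[DistrictEstimate]] = {}
    for est in estimates:
        if est.district not in province_map:
            raise ConfigurationError(
                f"district {est.district!r} has no province mapping")
        by_province.setdefault(province_map[est.district], []).append(est)
    out: dict[str, dict[str, float]] = {}
    for province, ests in by_province.items():
        total_pop = sum(e.population for e in ests)
        if total_pop <= 0:
            raise ConfigurationError(
                f"province {province!r} has zero total population")
        sources = sorted({s for e in ests for s in e.per_capita_daily})
        out[province] = {
            s: sum(e.population * e.per_capita_daily.get(s, 0.0) for e in ests)
               / total_pop
            for s in sources}
    return out


def national_from_districts(estimates: Iterable[DistrictEstimate],
                            supplied: Mapping[str, float] | None = None,
                            ) -> dict[str, float]:
    """National per-capita estimate: population-weighted mean over districts.

    If ``supplied`` gives a figure for a source directly (as a published
    national estimate would), it takes precedence and the derived value is
    logged for comparison.
    """
    ests = list(estimates)
    derived = weight_to_province(ests, {e.district: "national" for e in ests})
    national = derived["national"]
    if supplied:
        for source, value in supplied.items():
            if source in national:
                logger.info("national %s: supplied %.3f overrides derived %.3f",
                            source, value, national[source])
            national[source] = float(value)
    return national


# ---------------------------------------------------------------------------
# 5. Synthetic data
# ---------------------------------------------------------------------------

#: Discrete household-size distribution, mode 4 (typical South Asian sizes).
DEFAULT_SIZE_DISTRIBUTION: dict[int, float] = {
    1: 0.05, 2: 0.12, 3: 0.20, 4: 0.28, 5: 0.18, 6: 0.10, 7: 0.05, 8: 0.02}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic household-survey generator.

    The generator emulates the structure of a national nutrition /
    income-expenditure survey: households, each with a size drawn from
    ``household_size_distribution``, report a monthly salt quantity and
    monthly per-food quantities equal to
    ``true_per_capita x size x days_per_month`` times multiplicative
    gamma-distributed noise with mean 1 and coefficient of variation
    ``noise_cv`` (gamma keeps quantities non-negative). ``true_per_capita``
    maps source name -> g/person/day with household salt under
    :data:`HOUSEHOLD_SALT`; the same targets apply to every district unless
    ``district_overrides`` replaces them per district.
    """

    seed: int
    districts: tuple[tuple[str, str, float], ...]  # (name, province, population)
    households_per_district: int
    true_per_capita: Mapping[str, float]
    household_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DISTRIBUTION))
    noise_cv: float = 0.0
    days_per_month: float = DEFAULT_DAYS_PER_MONTH
    district_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        _check(self.noise_cv, "noise_cv")
        if self.households_per_district < 1:
            raise ValidationError("households_per_district must be >= 1")
        sizes = list(self.household_size_distribution)
        probs = [self.household_size_distribution[s] for s in sizes]
        if any(s < 1 or s > 10 for s in sizes) or any(p < 0 for p in probs) \
                or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError(
                "household_size_distribution must be over {1..10} and sum to 1")
        if HOUSEHOLD_SALT not in self.true_per_capita:
            raise ValidationError(
                f"true_per_capita must include {HOUSEHOLD_SALT!r}")
        for source, grams in self.true_per_capita.items():
            _check(grams, f"true_per_capita[{source!r}]")


def generate_households(config: GeneratorConfig,
                        ) -> tuple[list[HouseholdRecord], pd.DataFrame]:
    """Generate survey households and the ground truth they were drawn from.

    Returns ``(records, truth)`` where ``truth`` has columns district,
    province, population, source, g_per_day — the per-capita targets the
    aggregation pipeline should recover. Identical config (incl. seed) gives
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    sizes = np.array(sorted(config.household_size_distribution))
    probs = np.array([config.household_size_distribution[s] for s in sizes],
                     dtype=float)
    probs = probs / probs.sum()

    def noise(n: int) -> np.ndarray:
        if config.noise_cv == 0:
            return np.ones(n)
        shape = 1.0 / config.noise_cv ** 2
        return rng.gamma(shape=shape, scale=1.0 / shape, size=n)

    records: list[HouseholdRecord] = []
    truth_rows = []
    for dname, province, population in config.districts:
        targets = dict(config.true_per_capita)
        targets.update(config.district_overrides.get(dname, {}))
        n = config.households_per_district
        hh_sizes = rng.choice(sizes, size=n, p=probs)
        draws = {src: noise(n) for src in targets}
        for i in range(n):
            size = int(hh_sizes[i])
            monthly = {src: targets[src] * size * config.days_per_month
                       * draws[src][i] for src in targets}
            records.append(HouseholdRecord(
                household_id=f"{dname}-{i + 1:05d}",
                district=dname,
                household_size=size,
                monthly_salt_g=monthly[HOUSEHOLD_SALT],
                food_quantities={s: q for s, q in monthly.items()
                                 if s != HOUSEHOLD_SALT}))
        for src, target in targets.items():
            truth_rows.append({"district": dname, "province": province,
                               "population": population, "source": src,
                               "g_per_day": target})
    return records, pd.DataFrame(truth_rows)


# --- the published Sri Lanka assessment inputs -----------------------------

_SRI_LANKA_FOODS = (
    FoodProduct("bread", salt_fraction=0.01, iodized_fraction=1.0),
    FoodProduct("dried_fish", salt_fraction=0.16, iodized_fraction=0.0),
    FoodProduct("biscuits", salt_fraction=0.014, iodized_fraction=1.0),
)

# province: (household salt g/day, iodized-salt coverage, bread g/day,
#            relative population weight from the 2012 census, millions)
_SRI_LANKA_PROVINCES = {
    "Western":       (7.1, 0.78, 45, 5.85),
    "Southern":      (8.3, 0.71, 28, 2.48),
    "Central":       (7.2, 0.90, 30, 2.57),
    "Northern":      (9.3, 0.83, 43, 1.06),
    "Eastern":       (9.6, 0.91, 36, 1.55),
    "North Western": (7.7, 0.70, 24, 2.38),
    "North Central": (8.4, 0.68, 18, 1.26),
    "Uva":           (7.4, 0.80, 15, 1.27),
    "Sabaragamuwa":  (7.3, 0.82, 21, 1.93),
}
_SRI_LANKA_NATIONAL = ("Sri Lanka", 8.5, 0.78, 32)
# dried fish and biscuits: national estimates applied to every province
_SRI_LANKA_NATIONAL_ONLY = {"dried_fish": 10.0, "biscuits": 7.0}


def sri_lanka_fixture() -> AssessmentInputs:
    """The Sri Lanka 2015/16 national assessment dataset, ready to run.

    Nine provinces plus the national aggregate: household-salt intake and
    iodized-salt coverage per province, bread consumption per province, dried
    fish (10 g/day) and biscuits (7 g/day) at the national estimate
    everywhere, salt fractions {bread 1.0%, dried fish 16%, biscuits 1.4%},
    iodization at 22.5 mg/kg with 0.7 retention, and adult (non-pregnant)
    reference values EAR 95 / RNI 150 / UL 600 ug/day.
    """
    regions = []
    for name, (salt, coverage, bread, pop) in _SRI_LANKA_PROVINCES.items():
        regions.append(RegionProfile(
            name=name,
            household_salt=HouseholdSaltSource(salt, coverage),
            consumption={"bread": float(bread), **_SRI_LANKA_NATIONAL_ONLY},
            population_weight=pop))
    nat_name, nat_salt, nat_cov, nat_bread = _SRI_LANKA_NATIONAL
    regions.append(RegionProfile(
        name=nat_name,
        household_salt=HouseholdSaltSource(nat_salt, nat_cov),
        consumption={"bread": float(nat_bread), **_SRI_LANKA_NATIONAL_ONLY},
        population_weight=sum(p[3] for p in _SRI_LANKA_PROVINCES.values())))
    return AssessmentInputs(
        foods=_SRI_LANKA_FOODS,
        regions=tuple(regions),
        params=IodizationParams(iodine_mg_per_kg=22.5, retention=0.7),
        refs=ReferenceValues(ear_ug=95.0, rni_ug=150.0, ul_ug=600.0),
        national=nat_name,
        who_salt_max_g=DEFAULT_WHO_SALT_MAX_G,
        scenarios=DEFAULT_SCENARIOS)


# ---------------------------------------------------------------------------
# 6. Reporting & I/O
# ---------------------------------------------------------------------------

_SOURCE_LABELS = {HOUSEHOLD_SALT: "Household salt", "dried_fish": "Dried fish"}


def _label(source: str) -> str:
    return _SOURCE_LABELS.get(source, source.replace("_", " ").capitalize())


def results_to_frame(results: Iterable[IntakeResult]) -> pd.DataFrame:
    """Tidy results: one row per region x scenario x source plus a Total row.

    Values are stored unrounded; percent columns are populated on Total rows
    only. The frame round-trips through CSV at full precision.
    """
    rows = []
    for r in results:
        for source in r.per_source_salt_g:
            rows.append({"region": r.region, "scenario": r.scenario,
                         "source": source,
                         "salt_g_per_day": r.per_source_salt_g[source],
                         "iodine_ug_per_day": r.per_source_iodine_ug[source],
                         "coverage": r.coverage,
                         "pct_ear": np.nan, "pct_rni": np.nan,
                         "pct_ul": np.nan, "pct_who_salt": np.nan})
        rows.append({"region": r.region, "scenario": r.scenario,
                     "source": "Total",
                     "salt_g_per_day": r.total_salt_g,
                     "iodine_ug_per_day": r.total_iodine_ug,
                     "coverage": r.coverage,
                     "pct_ear": r.pct_ear, "pct_rni": r.pct_rni,
                     "pct_ul": r.pct_ul, "pct_who_salt": r.pct_who_salt})
    return pd.DataFrame(rows)


def frame_to_results(frame: pd.DataFrame) -> list[IntakeResult]:
    """Inverse of :func:`results_to_frame` (keys ordered as stored)."""
    results = []
    for (region, scenario), grp in frame.groupby(["region", "scenario"],
                                                 sort=False):
        sources = grp[grp["source"] != "Total"]
        total = grp[grp["source"] == "Total"].iloc[0]
        cov = total["coverage"]
        results.append(IntakeResult(
            region=str(region), scenario=str(scenario),
            per_source_salt_g=dict(zip(sources["source"],
                                       sources["salt_g_per_day"])),
            total_salt_g=float(total["salt_g_per_day"]),
            per_source_iodine_ug=dict(zip(sources["source"],
                                          sources["iodine_ug_per_day"])),
            total_iodine_ug=float(total["iodine_ug_per_day"]),
            pct_ear=float(total["pct_ear"]), pct_rni=float(total["pct_rni"]),
            pct_ul=float(total["pct_ul"]),
            pct_who_salt=float(total["pct_who_salt"]),
            coverage=None if pd.isna(cov) else float(cov)))
    return results


def write_results_csv(results: Iterable[IntakeResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_results_csv(path: str | Path) -> list[IntakeResult]:
    # round_trip parser: the fast default can be one ulp off, breaking the
    # write-then-read machine-precision guarantee
    return frame_to_results(pd.read_csv(path, float_precision="round_trip"))


# --- input dialects --------------------------------------------------------

def read_foods_csv(path: str | Path) -> list[FoodProduct]:
    """``foods.csv``: columns name, salt_fraction, iodized_fraction."""
    frame = pd.read_csv(path)
    required = {"name", "salt_fraction", "iodized_fraction"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(
            f"foods file missing columns: {', '.join(sorted(missing))}")
    return [FoodProduct(str(r["name"]), float(r["salt_fraction"]),
                        float(r["iodized_fraction"]))
            for _, r in frame.iterrows()]


def write_foods_csv(foods: Iterable[FoodProduct], path: str | Path) -> None:
    pd.DataFrame([{"name": f.name, "salt_fraction": f.salt_fraction,
                   "iodized_fraction": f.iodized_fraction}
                  for f in foods]).to_csv(path, index=False)


def read_regions_csv(path: str | Path, foods: Sequence[FoodProduct],
                     national: str) -> list[RegionProfile]:
    """``regions.csv``: region, population, household_salt_g,
    household_coverage, then one column per food (g/person/day).

    A blank food cell means the region lacks its own estimate; the national
    region's value is substituted and the fallback is logged.
    """
    frame = pd.read_csv(path)
    required = {"region", "population", "household_salt_g", "household_coverage"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(
            f"regions file missing columns: {', '.join(sorted(missing))}")
    food_cols = [f.name for f in foods if f.name in frame.columns]
    if national not in set(frame["region"].astype(str)):
        raise ConfigurationError(
            f"national region {national!r} not found in regions file")
    nat_row = frame[frame["region"].astype(str) == national].iloc[0]
    profiles = []
    for _, row in frame.iterrows():
        consumption = {}
        for food in food_cols:
            value = row[food]
            if pd.isna(value):
                value = nat_row[food]
                logger.info("region %s: %s consumption missing; using "
                            "national value %.3g g/day", row["region"], food,
                            float(value))
            if pd.isna(value):
                raise ConfigurationError(
                    f"no national fallback available for food {food!r}")
            consumption[food] = float(value)
        profiles.append(RegionProfile(
            name=str(row["region"]),
            household_salt=HouseholdSaltSource(float(row["household_salt_g"]),
                                               float(row["household_coverage"])),
            consumption=consumption,
            population_weight=float(row["population"])))
    return profiles


def write_regions_csv(regions: Iterable[RegionProfile], path: str | Path) -> None:
    rows = []
    for p in regions:
        rows.append({"region": p.name, "population": p.population_weight,
                     "household_salt_g": p.household_salt.intake_g_per_day,
                     "household_coverage": p.household_salt.coverage,
                     **dict(p.consumption)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_params_yaml(path: str | Path,
                     ) -> tuple[IodizationParams, ReferenceValues, float,
                                list[Scenario]]:
    """``params.yaml``: iodization constants, reference values, WHO salt
    maximum, and the scenario list. Returns (params, refs, who_max, scenarios).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        params = IodizationParams(float(raw["iodine_mg_per_kg"]),
                                  float(raw["retention"]))
        refs = ReferenceValues(float(raw["ear_ug"]), float(raw["rni_ug"]),
                               float(raw["ul_ug"]))
        who_max = float(raw.get("who_salt_max_g", DEFAULT_WHO_SALT_MAX_G))
        scenarios = [Scenario(str(s["label"]), str(s.get("mode", "current")),
                              float(s.get("salt_scale", 1.0)))
                     for s in raw.get("scenarios", [])] or list(DEFAULT_SCENARIOS)
    except KeyError as exc:
        raise ConfigurationError(f"params file missing key: {exc}") from exc
    return params, refs, who_max, scenarios


def write_params_yaml(params: IodizationParams, refs: ReferenceValues,
                      who_salt_max_g: float, scenarios: Iterable[Scenario],
                      path: str | Path) -> None:
    doc = {"iodine_mg_per_kg": params.iodine_mg_per_kg,
           "retention": params.retention,
           "ear_ug": refs.ear_ug, "rni_ug": refs.rni_ug, "ul_ug": refs.ul_ug,
           "who_salt_max_g": who_salt_max_g,
           "scenarios": [{"label": s.label, "mode": s.mode,
                          "salt_scale": s.salt_scale} for s in scenarios]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_households_csv(path: str | Path) -> list[HouseholdRecord]:
    """``households.csv``: household_id, district, household_size,
    monthly_salt_g, then one column per food (g/month).

    Households with missing or sub-1 size are excluded with a logged count,
    never imputed.
    """
    frame = pd.read_csv(path)
    required = {"household_id", "district", "household_size", "monthly_salt_g"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(
            f"households file missing columns: {', '.join(sorted(missing))}")
    food_cols = [c for c in frame.columns if c not in required]
    bad = frame["household_size"].isna() | (frame["household_size"] < 1)
    if bad.any():
        logger.warning("excluded %d household(s) with missing or invalid size",
                       int(bad.sum()))
        frame = frame[~bad]
    records = []
    for _, row in frame.iterrows():
        foods = {c: float(row[c]) for c in food_cols if not pd.isna(row[c])}
        records.append(HouseholdRecord(
            household_id=str(row["household_id"]), district=str(row["district"]),
            household_size=int(row["household_size"]),
            monthly_salt_g=float(row["monthly_salt_g"]),
            food_quantities=foods))
    return records


def write_households_csv(records: Iterable[HouseholdRecord],
                         path: str | Path) -> None:
    rows = [{"household_id": r.household_id, "district": r.district,
             "household_size": r.household_size,
             "monthly_salt_g": r.monthly_salt_g, **dict(r.food_quantities)}
            for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_districts_csv(path: str | Path) -> tuple[dict[str, str], dict[str, float]]:
    """``districts.csv``: district, province, population.
    Returns (district -> province, district -> population)."""
    frame = pd.read_csv(path)
    missing = {"district", "province", "population"} - set(frame.columns)
    if missing:
        raise ConfigurationError(
            f"districts file missing columns: {', '.join(sorted(missing))}")
    provinces = dict(zip(frame["district"].astype(str),
                         frame["province"].astype(str)))
    populations = dict(zip(frame["district"].astype(str),
                           frame["population"].astype(float)))
    return provinces, populations


def write_districts_csv(districts: Iterable[tuple[str, str, float]],
                        path: str | Path) -> None:
    pd.DataFrame(districts, columns=["district", "province", "population"]
                 ).to_csv(path, index=False)


# --- presentation tables ---------------------------------------------------

@dataclass(frozen=True)
class PresentationTable:
    """A display-rounded rectangular table with optional footer row."""

    title: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cells: tuple[tuple[str, ...], ...]
    footer: tuple[str, ...] | None = None
    footer_label: str = ""

    def __post_init__(self) -> None:
        for row in self.cells:
            if len(row) != len(self.col_labels):
                raise RenderingError("table cells are not rectangular")
        if self.footer is not None and len(self.footer) != len(self.col_labels):
            raise RenderingError("footer width does not match columns")

    def to_markdown(self) -> str:
        head = ["Region", *self.col_labels]
        lines = ["| " + " | ".join(head) + " |",
                 "| " + " | ".join("---" for _ in head) + " |"]
        for label, row in zip(self.row_labels, self.cells):
            lines.append("| " + " | ".join([label, *row]) + " |")
        if self.footer is not None:
            lines.append("| " + " | ".join([self.footer_label, *self.footer])
                         + " |")
        return "\n".join(lines)

    def to_tsv(self) -> str:
        lines = ["\t".join(["Region", *self.col_labels])]
        for label, row in zip(self.row_labels, self.cells):
            lines.append("\t".join([label, *row]))
        if self.footer is not None:
            lines.append("\t".join([self.footer_label, *self.footer]))
        return "\n".join(lines)


def _pick(results: Sequence[IntakeResult], mode_label: str) -> list[IntakeResult]:
    picked = [r for r in results if r.scenario == mode_label]
    if not picked:
        raise RenderingError(f"results contain no {mode_label!r} scenario")
    return picked


def _fmt1(x: float) -> str:
    return f"{round_half_up(x, 1):.1f}"


def render_salt_table(results: Sequence[IntakeResult],
                      scenario: str = "current", national: str | None = None,
                      who_salt_max_g: float = DEFAULT_WHO_SALT_MAX_G,
                      ) -> PresentationTable:
    """Per-source daily salt intake table (g, one decimal) with a footer of
    national percent-of-WHO-maximum values.

    Rounding happens per cell from unrounded values; the Total column is the
    rounded unrounded sum, never a sum of rounded cells. The footer percents
    come from the unrounded national values; ``national`` defaults to the last
    region in the result order.
    """
    if not results:
        raise RenderingError("no results to render")
    picked = _pick(results, scenario)
    sources = list(picked[0].per_source_salt_g)
    regions = [r.region for r in picked]
    nat = national if national is not None else regions[-1]
    nat_rows = [r for r in picked if r.region == nat]
    if not nat_rows:
        raise RenderingError(f"national region {nat!r} missing from results")
    cells = tuple(
        tuple([*(_fmt1(r.per_source_salt_g[s]) for s in sources),
               _fmt1(r.total_salt_g)])
        for r in picked)
    nat_r = nat_rows[0]
    footer = tuple(
        [*(f"{_display_int(100.0 * nat_r.per_source_salt_g[s] / who_salt_max_g)}%"
           for s in sources),
         f"{_display_int(nat_r.pct_who_salt)}%"])
    return PresentationTable(
        title="Average daily salt intake per household member (g)",
        row_labels=tuple(regions),
        col_labels=tuple([*(_label(s) for s in sources), "Total"]),
        cells=cells, footer=footer,
        footer_label=f"% WHO recommended max salt intake of "
                     f"{who_salt_max_g:g} g/day")


def render_iodine_table(results: Sequence[IntakeResult],
                        potential: str = "potential", current: str = "current",
                        ) -> PresentationTable:
    """Paired potential/current daily iodine intake table (ug, integers),
    with the household iodized-salt coverage echoed as a percent column."""
    if not results:
        raise RenderingError("no results to render")
    pot = _pick(results, potential)
    cur = _pick(results, current)
    cur_by_region = {r.region: r for r in cur}
    missing = [r.region for r in pot if r.region not in cur_by_region]
    if missing:
        raise RenderingError(
            f"regions missing from {current!r} scenario: {', '.join(missing)}")
    sources = list(pot[0].per_source_iodine_ug)
    rows = []
    for p in pot:
        c = cur_by_region[p.region]
        cov = "" if p.coverage is None else f"{_display_int(100 * p.coverage)}%"
        row = [cov]
        for s in sources:
            row.append(str(_display_int(p.per_source_iodine_ug[s])))
            row.append(str(_display_int(c.per_source_iodine_ug[s])))
        row.append(str(_display_int(p.total_iodine_ug)))
        row.append(str(_display_int(c.total_iodine_ug)))
        rows.append(tuple(row))
    cols = ["Coverage"]
    for s in sources:
        cols += [f"{_label(s)} P", f"{_label(s)} C"]
    cols += ["Total P", "Total C"]
    return PresentationTable(
        title="Estimated potential (P) and current (C) daily iodine intake (ug)",
        row_labels=tuple(p.region for p in pot),
        col_labels=tuple(cols), cells=tuple(rows))


def export_reference_chart(results: Sequence[IntakeResult], path: str | Path,
                           scenarios: Sequence[str] = ("potential", "current"),
                           ) -> None:
    """Bar chart of percent-of-EAR and percent-of-RNI by region and scenario.

    Numbers come straight from the result table; nothing is recomputed.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_scen = {s: _pick(results, s) for s in scenarios}
    regions = [r.region for r in next(iter(by_scen.values()))]
    x = np.arange(len(regions))
    width = 0.8 / (2 * len(scenarios))
    fig, ax = plt.subplots(figsize=(max(6, 1.1 * len(regions)), 4))
    for i, (scen, rows) in enumerate(by_scen.items()):
        vals = {r.region: r for r in rows}
        ax.bar(x + (2 * i) * width, [vals[r].pct_ear for r in regions],
               width, label=f"{scen}: % EAR")
        ax.bar(x + (2 * i + 1) * width, [vals[r].pct_rni for r in regions],
               width, label=f"{scen}: % RNI")
    ax.axhline(100, color="grey", linewidth=0.8, linestyle="--")
    ax.set_xticks(x + width * (len(scenarios) - 0.5))
    ax.set_xticklabels(regions, rotation=45, ha="right")
    ax.set_ylabel("% of reference value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
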