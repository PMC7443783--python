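"""Claims-record cohort pipeline: selection, death linkage, burden, strata.

Turns raw attention records (one row per medical visit), death-certificate
records and insured-population denominators into stratified incidence and
DALY tables under a grid of (methodology, disability weight) cells —
the 2 x 2 grid of Harvard-1994/GBD-2015 methods by WHO (0.165) /
MINSA (0.28) weights in the default analysis.

Cohort selection keeps first-time osteoarthritis visits (ICD-10 M15-M19) of
insured adults: age >= 15, outpatient or emergency setting (hospitalisation
excluded), no previous treatment, visit inside the analysis year; one row
per patient at the earliest eligible visit.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .engine import DisabilityWeight, MethodSpec, burden_integral
from .life_tables import remaining_life_expectancy

__all__ = [
    "AGE_BANDS",
    "OA_CODES",
    "OA_TYPES",
    "AggregationError",
    "SelectionResult",
    "classify_oa_type",
    "select_cohort",
    "link_deaths",
    "compute_burden",
    "incidence_rate",
    "daly_rate",
    "round_half_up",
    "aggregate",
    "validate_denominators",
]

OA_CODES = ("M15", "M16", "M17", "M18", "M19")

#: ICD-10 three-character category -> analysis type.  M15 (polyosteoarthritis)
#: and M19 (unspecified) are pooled, as the source tables report them.
OA_TYPES = {
    "M15": "poly_unspecified",
    "M16": "hip",
    "M17": "knee",
    "M18": "first_cmc",
    "M19": "poly_unspecified",
}

AGE_BANDS = ("15-44", "45-59", "60+")

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")
_SETTING_ORDER = {"outpatient": 0, "emergency": 1, "inpatient": 2}
# same-date, same-setting ties broken by clinical specificity
_TYPE_TIEBREAK = {"M16": 0, "M17": 1, "M18": 2, "M15": 3, "M19": 4}


class AggregationError(ValueError):
    """A stratum required by the aggregation is missing a denominator."""


def classify_oa_type(icd10: str) -> str:
    """Map an osteoarthritis ICD-10 code (subcodes allowed) to its type:
    hip (M16), knee (M17), first_cmc (M18), poly_unspecified (M15/M19)."""
    prefix = str(icd10).strip().upper()[:3]
    try:
        return OA_TYPES[prefix]
    except KeyError:
        raise ValueError(f"{icd10!r} is not an osteoarthritis code (M15-M19)") from None


def assign_age_band(age) -> pd.Series:
    """15-44 / 45-59 / 60+ bands used throughout the stratified tables."""
    return pd.cut(
        np.asarray(age, dtype=float),
        bins=[15, 45, 60, np.inf],
        labels=list(AGE_BANDS),
        right=False,
    )


@dataclass
class SelectionResult:
    """Selected cohort plus per-rule exclusion bookkeeping.

    ``exclusions`` counts rows removed, each attributed to the first rule it
    failed; the counts sum to ``input rows - len(cohort)``.
    """

    cohort: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.cohort)


def select_cohort(
    records: pd.DataFrame,
    year: int,
    min_age: int = 15,
) -> SelectionResult:
    """Apply the selection rules and deduplicate to one row per patient.

    Rules, in attribution order: well-formed ICD-10; code in M15-M19;
    age >= ``min_age``; setting not inpatient; no previous treatment;
    visit date inside ``year``.  The kept row is each patient's earliest
    eligible visit; same-day ties go to outpatient before emergency, then to
    the lexicographically first code.
    """
    df = records.copy()
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    codes = df["icd10"].astype(str).str.strip().str.upper()
    exclusions: dict[str, int] = {}

    def drop(mask: pd.Series, rule: str) -> None:
        nonlocal df, codes
        n = int(mask.sum())
        if n:
            exclusions[rule] = n
            df = df[~mask]
            codes = codes[~mask]

    malformed = ~codes.str.match(_ICD10_RE)
    if malformed.any():
        warnings.warn(
            f"{int(malformed.sum())} record(s) with malformed ICD-10 codes excluded",
            stacklevel=2,
        )
    drop(malformed, "malformed_icd10")
    drop(~codes.str[:3].isin(OA_CODES), "non_oa_code")
    drop(df["age"] < min_age, "under_age")
    drop(df["setting"] == "inpatient", "inpatient")
    drop(df["prior_treatment"].astype(bool), "prior_treatment")
    drop(df["visit_date"].dt.year != year, "outside_year")

    order = df.assign(
        _setting=df["setting"].map(_SETTING_ORDER),
        _icd=codes,
    ).sort_values(["visit_date", "_setting", "_icd"], kind="stable")
    cohort = order.groupby("patient_id", sort=True).head(1).drop(columns=["_setting", "_icd"])
    n_dupes = len(df) - len(cohort)
    if n_dupes:
        exclusions["duplicate_visit"] = n_dupes

    cohort = cohort.reset_index(drop=True)
    cohort["oa_type"] = cohort["icd10"].astype(str).str.strip().str.upper().str[:3].map(OA_TYPES)
    cohort["age_band"] = assign_age_band(cohort["age"])
    return SelectionResult(cohort=cohort, exclusions=exclusions)


def link_deaths(
    cohort: pd.DataFrame,
    deaths: pd.DataFrame,
    include_contributory: bool = False,
) -> pd.DataFrame:
    """Annotate the cohort with osteoarthritis-death information.

    A patient is flagged ``died_of_oa`` when a death certificate carries an
    M15-M19 cause with role "primary" (or also "contributory" when enabled).
    Adds ``age_at_death`` and ``years_to_death`` (time from initial
    attention to death).  A death dated before the first visit is ignored
    for YLL purposes, with a warning.
    """
    out = cohort.copy()
    out["died_of_oa"] = False
    out["age_at_death"] = np.nan
    out["years_to_death"] = np.nan
    if deaths is None or len(deaths) == 0:
        return out

    d = deaths.copy()
    d["death_date"] = pd.to_datetime(d["death_date"])
    cause_ok = d["cause_icd10"].astype(str).str.strip().str.upper().str[:3].isin(OA_CODES)
    roles = {"primary"} | ({"contributory"} if include_contributory else set())
    d = d[cause_ok & d["cause_role"].isin(roles)]
    d = d.sort_values("death_date", kind="stable").groupby("patient_id", sort=False).head(1)

    merged = out.merge(
        d[["patient_id", "death_date"]], on="patient_id", how="left"
    )
    linked = merged["death_date"].notna()
    early = linked & (merged["death_date"] < merged["visit_date"])
    if early.any():
        warnings.warn(
            f"{int(early.sum())} death record(s) predate the first attention; "
            "ignored for YLL",
            stacklevel=2,
        )
    ok = linked & ~early
    dt_years = (merged.loc[ok, "death_date"] - merged.loc[ok, "visit_date"]).dt.days / 365.25
    out.loc[ok.to_numpy(), "died_of_oa"] = True
    out.loc[ok.to_numpy(), "years_to_death"] = dt_years.to_numpy()
    out.loc[ok.to_numpy(), "age_at_death"] = (
        merged.loc[ok, "age"].to_numpy(dtype=float) + dt_years.to_numpy()
    )
    return out


def _ex_by_sex(table, ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
    ex = np.empty(len(ages), dtype=float)
    if table.sex_specific:
        for sex in ("male", "female"):
            m = sexes == sex
            if m.any():
                ex[m] = remaining_life_expectancy(table, ages[m], sex)
    else:
        ex[:] = remaining_life_expectancy(table, ages)
    return ex


def compute_burden(
    cohort: pd.DataFrame,
    specs: list[MethodSpec],
    weights: list[DisabilityWeight],
    tables,
) -> pd.DataFrame:
    """Per-person burdens for every (method, disability weight) cell.

    Returns a tidy frame with one row per patient x method x weight:
    columns ``patient_id, method, dw, yll, yld, daly``.  YLD accrues from
    the age at first attention over the remaining life expectancy at that
    age; YLL only for patients flagged as osteoarthritis deaths, from the
    age at death.  ``daly = yll + yld`` by construction.
    """
    if not specs or not weights:
        raise ValueError("at least one method and one disability weight are required")
    cols = ["patient_id", "method", "dw", "yll", "yld", "daly"]
    if len(cohort) == 0:
        return pd.DataFrame(columns=cols)

    ages = cohort["age"].to_numpy(dtype=float)
    sexes = cohort["sex"].to_numpy()
    died = (
        cohort["died_of_oa"].to_numpy(dtype=bool)
        if "died_of_oa" in cohort
        else np.zeros(len(cohort), dtype=bool)
    )

    frames = []
    for spec in specs:
        if isinstance(tables, dict):
            table = tables[spec.life_table_ref]
        else:
            table = tables
        ex_onset = _ex_by_sex(table, ages, sexes)
        yll_vec = np.zeros(len(cohort))
        if died.any():
            ad = cohort.loc[died, "age_at_death"].to_numpy(dtype=float)
            ex_death = _ex_by_sex(table, ad, sexes[died])
            yll_vec[died] = burden_integral(ad, ex_death, 1.0, spec)
        yld_spec = spec if spec.age_weight_on_yld else replace(spec, K=0.0)
        for w in weights:
            yld_vec = burden_integral(ages, ex_onset, w.value, yld_spec)
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": cohort["patient_id"].to_numpy(),
                        "method": spec.name,
                        "dw": w.label,
                        "yll": yll_vec,
                        "yld": yld_vec,
                        "daly": yll_vec + yld_vec,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[cols]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 dp rounds to 0.1), as the source
    tables round their rates."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _per_1000(numerator, insured: int, what: str) -> float:
    if insured is None or insured <= 0:
        raise ZeroDivisionError(f"{what} per 1000 undefined: insured count must be > 0")
    return round_half_up(
        float(Decimal(repr(float(numerator))) * 1000 / Decimal(int(insured)))
    )


def incidence_rate(new_cases: int, insured: int) -> float:
    """New cases per 1000 insured, rounded half-up to one decimal."""
    return _per_1000(new_cases, insured, "incidence")


def daly_rate(total_dalys: float, insured: int) -> float:
    """DALYs per 1000 insured, rounded half-up to one decimal."""
    return _per_1000(total_dalys, insured, "DALY rate")


def validate_denominators(denominators: pd.DataFrame) -> pd.DataFrame:
    """Check internal consistency of the insured-population table.

    Sex and network counts must sum to the total; age-band counts must not
    exceed the total (bands cover insured aged 15+ only).
    """
    d = denominators.copy()
    if (d["insured_count"] < 0).any():
        raise ValueError("insured counts must be non-negative")
    lut = {(r.dimension, r.level): int(r.insured_count) for r in d.itertuples()}
    total = lut.get(("total", "total"))
    if total is None:
        raise ValueError("denominators must include a (total, total) row")
    for dim in ("sex", "network"):
        levels = [v for (dm, _), v in lut.items() if dm == dim]
        if levels and sum(levels) != total:
            raise ValueError(f"{dim} denominators sum to {sum(levels)}, not {total}")
    bands = [v for (dm, _), v in lut.items() if dm == "age_band"]
    if bands and sum(bands) > total:
        raise ValueError("age-band denominators exceed the total insured count")
    return d


# dimensions whose strata share the full insured population as denominator
_TOTAL_DENOM_DIMS = {"oa_type"}
# dimensions reported without population denominators (no rates)
_NO_DENOM_DIMS = {"setting"}


def aggregate(
    burdens: pd.DataFrame,
    cohort: pd.DataFrame,
    denominators: pd.DataFrame,
    dimensions: tuple[str, ...] = ("sex", "age_band", "oa_type", "network"),
) -> pd.DataFrame:
    """Stratified counts, percentages, incidence and DALY rates.

    One output row per (dimension, level) plus a leading total row.  Per
    (method, weight) cell: ``dalys_<method>_<dw>`` (unrounded sum of years)
    and ``dalys_per_1000_<method>_<dw>`` (rounded to 1 decimal).  Incidence
    uses stratum denominators, except for dimensions whose levels share the
    whole-population denominator (osteoarthritis type) or have none
    (care setting).
    """
    denominators = validate_denominators(denominators)
    lut = {(r.dimension, r.level): int(r.insured_count) for r in denominators.itertuples()}
    total_insured = lut[("total", "total")]
    n_total = len(cohort)

    cells = burdens
    cell_keys = (
        burdens[["method", "dw"]].drop_duplicates().itertuples(index=False)
        if len(burdens)
        else []
    )
    cell_keys = [(m, w) for m, w in cell_keys]

    def daly_columns(mask_cells: pd.DataFrame, insured: int | None) -> dict:
        out = {}
        for m, w in cell_keys:
            sub = mask_cells[(mask_cells["method"] == m) & (mask_cells["dw"] == w)]
            tot = float(sub["daly"].sum())
            out[f"dalys_{m}_{w}"] = tot
            out[f"dalys_per_1000_{m}_{w}"] = (
                daly_rate(tot, insured) if insured else np.nan
            )
        return out

    rows = []
    rows.append(
        {
            "dimension": "total",
            "level": "total",
            "new_cases": n_total,
            "pct_col": 100.0,
            "insured": total_insured,
            "incidence_per_1000": incidence_rate(n_total, total_insured),
            **daly_columns(cells, total_insured),
        }
    )

    for dim in dimensions:
        levels = _dimension_levels(dim, cohort)
        for level in levels:
            in_level = cohort[dim].astype(str) == str(level)
            n = int(in_level.sum())
            if dim in _NO_DENOM_DIMS:
                insured = None
            elif dim in _TOTAL_DENOM_DIMS:
                insured = total_insured
            else:
                insured = lut.get((dim, str(level)))
                if insured is None:
                    raise AggregationError(
                        f"no insured denominator for stratum ({dim}, {level})"
                    )
            ids = set(cohort.loc[in_level, "patient_id"])
            level_cells = cells[cells["patient_id"].isin(ids)] if len(cells) else cells
            rows.append(
                {
                    "dimension": dim,
                    "level": str(level),
                    "new_cases": n,
                    "pct_col": round_half_up(100.0 * n / n_total) if n_total else np.nan,
                    "insured": insured if insured is not None else np.nan,
                    "incidence_per_1000": (
                        incidence_rate(n, insured) if insured else np.nan
                    ),
                    **daly_columns(level_cells, insured),
                }
            )
    return pd.DataFrame(rows)


def _dimension_levels(dim: str, cohort: pd.DataFrame) -> list[str]:
    fixed = {
        "sex": ["male", "female"],
        "age_band": list(AGE_BANDS),
        "oa_type": ["poly_unspecified", "knee", "hip", "first_cmc"],
        "setting": ["emergency", "outpatient"],
    }
    if dim in fixed:
        return fixed[dim]
    if dim not in cohort.columns:
        raise AggregationError(f"cohort has no column {dim!r}")
    return sorted(cohort[dim].dropna().astype(str).unique())
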