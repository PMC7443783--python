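"""Remaining-life-expectancy tables for burden-of-disease calculations.

Two families of reference tables are needed: the sex-specific tables of the
1994 Harvard framework, anchored at a life expectancy at birth of 80.0 years
for men and 82.5 years for women (the Coale-Demeny "West level 26" anchors),
and the sex-invariant aspirational standard of the 2015 GBD revision,
anchored at 91.9 years (lowest-observed-mortality projection to 2050).

The authentic tabulations are not bundled; instead :func:`make_reference_tables`
builds smooth Gompertz-survivorship stand-ins calibrated to those anchors.
Authentic tables can be supplied as CSV files via :func:`load_life_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

__all__ = [
    "LifeTable",
    "LifeTableSchemaError",
    "LifeTableValidationError",
    "ReferenceConfig",
    "ReferenceTables",
    "load_life_table",
    "write_life_table",
    "remaining_life_expectancy",
    "make_reference_tables",
    "default_life_tables",
]

_SEX_ALIASES = {
    "m": "male", "male": "male",
    "f": "female", "female": "female",
    "both": "both", "b": "both",
}


class LifeTableSchemaError(ValueError):
    """Input file does not have the required columns or parseable values."""


class LifeTableValidationError(ValueError):
    """Table entries violate a life-table invariant."""


@dataclass(frozen=True)
class LifeTable:
    """Tabulated remaining life expectancy e(a), by sex stratum.

    ``strata`` maps a sex key (``"male"``, ``"female"`` or ``"both"``) to a
    pair of parallel arrays ``(ages, ex)``.  Invariants enforced on
    construction: ages strictly increasing, e(a) >= 0, expected age at death
    ``a + e(a)`` non-decreasing, and e at the terminal tabulated age > 0.
    """

    source_label: str
    strata: Mapping[str, tuple[np.ndarray, np.ndarray]] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.strata:
            raise LifeTableValidationError("life table has no entries")
        if "both" in self.strata and len(self.strata) > 1:
            raise LifeTableValidationError(
                "life table mixes sex-specific and sex-invariant strata"
            )
        for sex, (ages, ex) in self.strata.items():
            if sex not in ("male", "female", "both"):
                raise LifeTableValidationError(f"unknown sex stratum {sex!r}")
            ages = np.asarray(ages, dtype=float)
            ex = np.asarray(ex, dtype=float)
            if ages.shape != ex.shape or ages.ndim != 1 or ages.size == 0:
                raise LifeTableValidationError(
                    f"stratum {sex!r}: ages and ex must be equal-length 1-d arrays"
                )
            if np.any(ages < 0):
                raise LifeTableValidationError(f"stratum {sex!r}: negative age")
            if np.any(np.diff(ages) <= 0):
                raise LifeTableValidationError(
                    f"stratum {sex!r}: ages must be strictly increasing"
                )
            if np.any(ex < 0):
                bad = ages[ex < 0][0]
                raise LifeTableValidationError(
                    f"stratum {sex!r}: negative life expectancy at age {bad:g}"
                )
            death_age = ages + ex
            drops = np.diff(death_age) < -1e-9
            if np.any(drops):
                bad = ages[1:][drops][0]
                raise LifeTableValidationError(
                    f"stratum {sex!r}: expected age at death a + e(a) decreases "
                    f"at age {bad:g}"
                )
            if ex[-1] <= 0:
                raise LifeTableValidationError(
                    f"stratum {sex!r}: terminal life expectancy must be > 0"
                )

    @property
    def sex_specific(self) -> bool:
        return "both" not in self.strata

    def entries(self, sex: str = "both") -> list[tuple[float, float]]:
        ages, ex = self.strata[self._resolve(sex)]
        return list(zip(ages.tolist(), ex.tolist()))

    def _resolve(self, sex: str | None) -> str:
        if not self.sex_specific:
            return "both"
        if sex is None:
            raise ValueError(
                f"table {self.source_label!r} is sex-specific; a sex is required"
            )
        key = _SEX_ALIASES.get(str(sex).lower())
        if key is None or key not in self.strata:
            raise ValueError(f"no stratum for sex {sex!r} in {self.source_label!r}")
        return key


def remaining_life_expectancy(
    table: LifeTable, age, sex: str | None = None
):
    """Interpolated remaining life expectancy e(age) in years.

    Linear interpolation between bracketing tabulated ages; clamped to the
    first/last tabulated value outside the table.  ``age`` may be a scalar or
    an array.  Negative ages are rejected.
    """
    ages, ex = table.strata[table._resolve(sex)]
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    out = np.interp(a, ages, ex)
    return float(out) if np.isscalar(age) or a.ndim == 0 else out


def load_life_table(
    path, schema: Mapping[str, str] | None = None, source_label: str | None = None
) -> LifeTable:
    """Read a life table from delimited text.

    Expected columns ``age,sex,ex`` (renameable through ``schema``, a mapping
    of required name -> file column name); sex values M/F/both.
    """
    colmap = {"age": "age", "sex": "sex", "ex": "ex"}
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise LifeTableSchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    try:
        ages_raw = df[colmap["age"]].astype(int)
    except (TypeError, ValueError) as err:
        raise LifeTableSchemaError(f"{path}: ages must parse as integers") from err
    if (ages_raw < 0).any():
        raise LifeTableSchemaError(f"{path}: ages must be non-negative")
    sexes = df[colmap["sex"]].astype(str).str.lower().map(_SEX_ALIASES)
    if sexes.isna().any():
        bad = df[colmap["sex"]][sexes.isna()].iloc[0]
        raise LifeTableSchemaError(f"{path}: unrecognised sex value {bad!r}")
    strata = {}
    for sex, grp in df.assign(_sex=sexes).groupby("_sex", sort=True):
        grp = grp.sort_values(colmap["age"])
        strata[sex] = (
            grp[colmap["age"]].to_numpy(dtype=float),
            grp[colmap["ex"]].to_numpy(dtype=float),
        )
    return LifeTable(source_label=source_label or str(path), strata=strata)


def write_life_table(table: LifeTable, path) -> None:
    """Write a table as ``age,sex,ex`` CSV (round-trips with the loader)."""
    frames = []
    code = {"male": "M", "female": "F", "both": "both"}
    for sex in sorted(table.strata):
        ages, ex = table.strata[sex]
        frames.append(pd.DataFrame({"age": ages.astype(int), "sex": code[sex], "ex": ex}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parametric reference tables
# ---------------------------------------------------------------------------

class ReferenceTables(NamedTuple):
    harvard_male: LifeTable
    harvard_female: LifeTable
    gbd: LifeTable


@dataclass(frozen=True)
class ReferenceConfig:
    """Calibration targets and shape parameters for the stand-in tables.

    ``gompertz_slope`` is the exponential rate of adult mortality increase
    (per year of age); 0.1/yr is typical of modern low-mortality schedules.
    The level parameter of each Gompertz hazard is solved so that life
    expectancy at birth matches the target within ``e0_tol`` years.
    """

    e0_harvard_male: float = 80.0
    e0_harvard_female: float = 82.5
    e0_gbd: float = 91.9
    gompertz_slope: float = 0.1
    max_age: int = 110
    e0_tol: float = 0.05

    def __post_init__(self) -> None:
        for name in ("e0_harvard_male", "e0_harvard_female", "e0_gbd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gompertz_slope <= 0:
            raise ValueError("gompertz_slope must be positive")


def _gompertz_ex(level: float, slope: float, max_age: int) -> tuple[np.ndarray, np.ndarray]:
    """e(a) at integer ages 0..max_age under survivorship
    S(x) = exp(-(B/theta) (e^{theta x} - 1))."""
    step = 0.05
    grid = np.arange(0.0, max_age + 30.0 + step, step)
    surv = np.exp(-(level / slope) * np.expm1(slope * grid))
    # person-years remaining above x: T(x) = int_x^inf S
    cum = cumulative_trapezoid(surv, grid, initial=0.0)
    person_years = cum[-1] - cum
    ex_grid = person_years / np.where(surv > 1e-12, surv, np.nan)
    # truncate the tabulation where survivorship numerically vanishes
    usable = grid[surv > 1e-12][-1]
    top = int(min(max_age, np.floor(usable)))
    ages = np.arange(0, top + 1, dtype=float)
    return ages, np.interp(ages, grid, ex_grid)


def _calibrate_gompertz(e0_target: float, slope: float, max_age: int, tol: float):
    def gap(log_level: float) -> float:
        _, ex = _gompertz_ex(10.0 ** log_level, slope, max_age)
        return ex[0] - e0_target

    try:
        log_level = brentq(gap, -12.0, -2.0, xtol=1e-10)
    except ValueError as err:
        raise ArithmeticError(
            f"Gompertz calibration failed for e0={e0_target} with "
            f"slope={slope}: target not bracketed in level range 1e-12..1e-2"
        ) from err
    level = 10.0 ** log_level
    ages, ex = _gompertz_ex(level, slope, max_age)
    if abs(ex[0] - e0_target) > tol:
        raise ArithmeticError(
            f"Gompertz calibration for e0={e0_target} converged to "
            f"{ex[0]:.4f}, outside tolerance {tol}"
        )
    return ages, ex


def make_reference_tables(config: ReferenceConfig | None = None) -> ReferenceTables:
    """Build the three calibrated stand-in tables.

    Returns single-stratum tables for Harvard male (e0 = 80.0), Harvard
    female (e0 = 82.5) and the sex-invariant GBD standard (e0 = 91.9), at
    integer ages 0..max_age.
    """
    cfg = config or ReferenceConfig()
    out = {}
    targets = {
        "harvard_male": ("male", cfg.e0_harvard_male),
        "harvard_female": ("female", cfg.e0_harvard_female),
        "gbd": ("both", cfg.e0_gbd),
    }
    for name, (sex, e0) in targets.items():
        ages, ex = _calibrate_gompertz(e0, cfg.gompertz_slope, cfg.max_age, cfg.e0_tol)
        out[name] = LifeTable(
            source_label=f"gompertz stand-in (e0={e0})", strata={sex: (ages, ex)}
        )
    return ReferenceTables(out["harvard_male"], out["harvard_female"], out["gbd"])


@lru_cache(maxsize=1)
def default_life_tables() -> dict[str, LifeTable]:
    """Bundled tables keyed by the references used in method presets:
    ``"west26"`` (sex-specific Harvard stand-in) and ``"gbd2050"``."""
    ref = make_reference_tables()
    west26 = LifeTable(
        source_label="gompertz stand-in for West level 26 (e0 80.0 M / 82.5 F)",
        strata={
            "male": ref.harvard_male.strata["male"],
            "female": ref.harvard_female.strata["female"],
        },
    )
    return {"west26": west26, "gbd2050": ref.gbd}
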