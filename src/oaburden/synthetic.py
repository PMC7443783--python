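"""Seeded synthetic cohort generator emulating the 2016 EsSalud records.

Produces the three pipeline inputs — attention records, death certificates
and insured-population denominators — with the marginal structure of the
real cohort: 65.5% female; age bands 15-44 / 45-59 / >=60 at
15.4% / 30.0% / 54.6% with ages drawn truncated-normal(60.9, 15.1) within
each band; osteoarthritis type mix 62.6% poly/unspecified, 31.0% knee,
5.9% hip, 0.5% first carpometacarpal; four health networks; 95% outpatient;
and roughly 3 osteoarthritis deaths per 196,003 cases.  Denominators are
the 2016 insured counts scaled to ``insured_total``.

The joint distribution across sex, age, type and network is independent:
only the published marginals constrain it.  Everything derives from one
:class:`numpy.random.Generator` stream, so a seed fixes the output bytes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ESSALUD_2016_INSURED",
    "SyntheticConfig",
    "CorruptionSpec",
    "SyntheticCohort",
    "generate",
    "generate_noise_variants",
]

#: Insured population of the Peruvian social insurance system in 2016, by
#: stratum; the scaling basis for synthetic denominators.
ESSALUD_2016_INSURED = {
    ("total", "total"): 10_937_079,
    ("sex", "male"): 5_521_152,
    ("sex", "female"): 5_415_927,
    ("age_band", "15-44"): 5_083_446,
    ("age_band", "45-59"): 1_747_647,
    ("age_band", "60+"): 1_474_919,
    ("network", "Metropolitan Lima"): 5_222_771,
    ("network", "Northern Coast/Highlands"): 2_612_164,
    ("network", "Southern Coast/Highlands"): 2_481_640,
    ("network", "Amazon Rainforest"): 620_504,
}

_STUDY_CASES = 196_003
NETWORKS = (
    "Metropolitan Lima",
    "Northern Coast/Highlands",
    "Southern Coast/Highlands",
    "Amazon Rainforest",
)
_BAND_RANGES = {"15-44": (15, 45), "45-59": (45, 60), "60+": (60, 100)}
# type order matches the probability vector: poly/unspec, knee, hip, first CMC
_TYPE_ORDER = ("poly_unspecified", "knee", "hip", "first_cmc")
_TYPE_CODES = {"knee": ["M17"], "hip": ["M16"], "first_cmc": ["M18"],
               "poly_unspecified": ["M15", "M19"]}

RECORD_COLUMNS = ["patient_id", "sex", "age", "visit_date", "icd10",
                  "setting", "network", "prior_treatment"]
DEATH_COLUMNS = ["patient_id", "death_date", "cause_icd10", "cause_role"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters; defaults are the 2016 study marginals."""

    n_cases: int = _STUDY_CASES
    seed: int = 0
    year: int = 2016
    p_female: float = 0.655
    age_band_probs: tuple[float, float, float] = (0.154, 0.300, 0.546)
    age_mean: float = 60.9
    age_sd: float = 15.1
    type_probs: tuple[float, float, float, float] = (0.626, 0.310, 0.059, 0.005)
    network_probs: tuple[float, float, float, float] = (0.453, 0.270, 0.235, 0.042)
    p_emergency: float = 0.050
    p_oa_death: float = 3 / _STUDY_CASES
    insured_total: int | None = None  # default: scaled by n_cases / 196,003

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        for name in ("p_female", "p_emergency", "p_oa_death"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for name in ("age_band_probs", "type_probs", "network_probs"):
            v = getattr(self, name)
            if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.resolved_insured_total() < self.n_cases:
            raise ValueError(
                "insured_total must be at least n_cases (cases are drawn from "
                "the insured population)"
            )

    def resolved_insured_total(self) -> int:
        if self.insured_total is not None:
            return int(self.insured_total)
        base = ESSALUD_2016_INSURED[("total", "total")]
        return int(round(base * self.n_cases / _STUDY_CASES))


@dataclass(frozen=True)
class CorruptionSpec:
    """Rates of ineligible rows to inject, each relative to n_cases."""

    inpatient: float = 0.0
    prior_treatment: float = 0.0
    under_15: float = 0.0
    non_oa_code: float = 0.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated inputs plus a manifest of the true generating parameters."""

    records: pd.DataFrame
    deaths: pd.DataFrame
    denominators: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, Path]:
        """Write records.csv, deaths.csv, denominators.csv, manifest.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": out / "records.csv",
            "deaths": out / "deaths.csv",
            "denominators": out / "denominators.csv",
            "manifest": out / "manifest.json",
        }
        self.records.to_csv(paths["records"], index=False)
        self.deaths.to_csv(paths["deaths"], index=False)
        self.denominators.to_csv(paths["denominators"], index=False)
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return paths


def _truncnorm_ages(rng, bands, mean, sd, n):
    ages = np.empty(n, dtype=float)
    for band, (lo, hi) in _BAND_RANGES.items():
        m = bands == band
        if m.any():
            a, b = (lo - mean) / sd, (hi - mean) / sd
            ages[m] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                          size=int(m.sum()), random_state=rng)
    return np.floor(ages).astype(int)


def _scaled_denominators(insured_total: int) -> pd.DataFrame:
    base_total = ESSALUD_2016_INSURED[("total", "total")]
    f = insured_total / base_total
    rows = [{"dimension": "total", "level": "total", "insured_count": insured_total}]
    # sexes: round one, set the other by difference so they sum to the total
    male = int(round(ESSALUD_2016_INSURED[("sex", "male")] * f))
    rows.append({"dimension": "sex", "level": "male", "insured_count": male})
    rows.append({"dimension": "sex", "level": "female", "insured_count": insured_total - male})
    for band in _BAND_RANGES:  # bands cover ages 15+ only; no sum constraint
        rows.append({
            "dimension": "age_band", "level": band,
            "insured_count": int(round(ESSALUD_2016_INSURED[("age_band", band)] * f)),
        })
    nets = [int(round(ESSALUD_2016_INSURED[("network", n)] * f)) for n in NETWORKS[:-1]]
    nets.append(insured_total - sum(nets))
    for name, count in zip(NETWORKS, nets):
        rows.append({"dimension": "network", "level": name, "insured_count": count})
    return pd.DataFrame(rows)


def generate(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw a synthetic cohort; fully reproducible from ``config.seed``."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases

    patient_id = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < cfg.p_female, "female", "male")
    bands = rng.choice(list(_BAND_RANGES), size=n, p=cfg.age_band_probs)
    age = _truncnorm_ages(rng, bands, cfg.age_mean, cfg.age_sd, n)
    oa_type = rng.choice(_TYPE_ORDER, size=n, p=cfg.type_probs)
    icd10 = np.array([_TYPE_CODES[t][0] for t in oa_type]) if n else np.array([], dtype=str)
    poly = oa_type == "poly_unspecified"  # M15/M19 split evenly
    if poly.any():
        icd10[poly] = np.where(rng.random(int(poly.sum())) < 0.5, "M15", "M19")
    setting = np.where(rng.random(n) < cfg.p_emergency, "emergency", "outpatient")
    network = rng.choice(NETWORKS, size=n, p=cfg.network_probs)
    year_start = np.datetime64(f"{cfg.year}-01-01")
    n_days = (np.datetime64(f"{cfg.year + 1}-01-01") - year_start).astype(int)
    visit_offset = rng.integers(0, n_days, size=n)
    visit_date = year_start + visit_offset.astype("timedelta64[D]")

    records = pd.DataFrame({
        "patient_id": patient_id,
        "sex": sex,
        "age": age,
        "visit_date": pd.to_datetime(visit_date).strftime("%Y-%m-%d") if n else [],
        "icd10": icd10,
        "setting": setting,
        "network": network,
        "prior_treatment": np.zeros(n, dtype=bool),
    }, columns=RECORD_COLUMNS)

    died = rng.random(n) < cfg.p_oa_death
    death_rows = []
    for i in np.flatnonzero(died):
        remaining = int(n_days - visit_offset[i])
        delay = int(rng.integers(0, max(remaining, 1)))
        d_date = visit_date[i] + np.timedelta64(delay, "D")
        death_rows.append({
            "patient_id": patient_id[i],
            "death_date": str(d_date),
            "cause_icd10": icd10[i],
            "cause_role": "primary",
        })
    deaths = pd.DataFrame(death_rows, columns=DEATH_COLUMNS)

    denominators = _scaled_denominators(cfg.resolved_insured_total())
    manifest = {
        "generator": "oaburden.synthetic",
        "config": {**asdict(cfg), "insured_total": cfg.resolved_insured_total()},
        "n_records": int(n),
        "n_deaths": int(died.sum()),
        "independence_note": (
            "sex, age band, osteoarthritis type and network are sampled "
            "independently; only the marginal shares are calibrated"
        ),
    }
    return SyntheticCohort(records, deaths, denominators, manifest)


def generate_noise_variants(
    config: SyntheticConfig, corruption: CorruptionSpec
) -> SyntheticCohort:
    """Clean cohort plus ineligible rows injected at the given rates.

    Injected rows use fresh patient ids and are tagged in
    ``manifest["injected"]`` so selection tests can assert exact exclusion
    counts per rule (inpatient setting, previous treatment, age under 15,
    non-osteoarthritis code).
    """
    cohort = generate(config)
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)  # separate stream for noise
    counts = {
        "inpatient": int(round(corruption.inpatient * cfg.n_cases)),
        "prior_treatment": int(round(corruption.prior_treatment * cfg.n_cases)),
        "under_15": int(round(corruption.under_15 * cfg.n_cases)),
        "non_oa_code": int(round(corruption.non_oa_code * cfg.n_cases)),
    }
    rows = []
    next_id = cfg.n_cases
    year_start = np.datetime64(f"{cfg.year}-01-01")
    n_days = (np.datetime64(f"{cfg.year + 1}-01-01") - year_start).astype(int)

    def base_row():
        nonlocal next_id
        row = {
            "patient_id": f"N{next_id:07d}",
            "sex": "female" if rng.random() < cfg.p_female else "male",
            "age": int(rng.integers(15, 90)),
            "visit_date": str(year_start + np.timedelta64(int(rng.integers(0, n_days)), "D")),
            "icd10": str(rng.choice(["M15", "M16", "M17", "M18", "M19"])),
            "setting": "outpatient",
            "network": str(rng.choice(NETWORKS)),
            "prior_treatment": False,
        }
        next_id += 1
        return row

    for _ in range(counts["inpatient"]):
        rows.append({**base_row(), "setting": "inpatient"})
    for _ in range(counts["prior_treatment"]):
        rows.append({**base_row(), "prior_treatment": True})
    for _ in range(counts["under_15"]):
        rows.append({**base_row(), "age": int(rng.integers(0, 15))})
    for _ in range(counts["non_oa_code"]):
        rows.append({**base_row(), "icd10": str(rng.choice(["M05", "M20", "J45"]))})

    noisy = pd.concat(
        [cohort.records, pd.DataFrame(rows, columns=RECORD_COLUMNS)],
        ignore_index=True,
    )
    cohort.records = noisy
    cohort.manifest["injected"] = counts
    return cohort
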