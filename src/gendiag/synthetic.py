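"""Synthetic TBI cohorts and life tables.

Emulates the statistical structure of linked emergency-department / acute-care
administrative records for first traumatic-brain-injury (TBI) events: per-code
sex-differential prevalences of ICD-style diagnostic codes, a 30-day mortality
process among severe cases driven by a population (life-table) baseline hazard
multiplied by exp(covariate effects), and a six-category discharge-location
process with known log-odds coefficients.  Every downstream stage of the
analysis is testable against the known generating parameters.

Coding conventions: sex is 0 = male, 1 = female throughout; the life table
uses labels "M"/"F".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

SEVERITIES = ("unknown", "mild", "moderate", "severe")
DISCHARGE_CATEGORIES = ("home", "home_support", "LTC", "CCC", "rehab", "other")
OTHER_SUBLOCATIONS = ("acute_transfer", "palliative", "ama", "died_in_facility")
MECHANISMS = ("falls", "struck", "motor_vehicle", "cyclist", "other")

#: columns of a cohort table, in serialization order
COHORT_COLUMNS = [
    "patient_id", "sex", "age", "event_year", "codes", "source", "severity",
    "death_day", "survival_known", "discharge_location", "other_sublocation",
    "los", "adg_score", "rural", "income_quintile", "mechanism", "latent_score",
]

_CODE_SEP = ";"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``code_catalog`` lists ``(label, prevalence_in_females,
    prevalence_in_males)`` triples.  ``mortality_betas`` are log rate ratios
    applied on top of the matched population daily death rate; covariate
    effects are applied to centred covariates (age - 40, ADG - 2,
    income - 3) so that slopes are directly comparable with fits on the raw
    scale.  ``discharge_betas`` maps ``(category, covariate)`` to a log odds
    coefficient of the baseline-category logit with "home" as reference
    (centred covariates: age - 40, LOS - 5, ADG - 2, income - 3).
    """

    n_patients: int = 20_000
    prop_female: float = 0.445
    age_range: tuple[int, int] = (16, 64)
    year_range: tuple[int, int] = (2002, 2019)
    code_catalog: tuple[tuple[str, float, float], ...] = ()
    severity_probs: tuple[float, float, float, float] = (0.486, 0.415, 0.028, 0.071)
    mortality_betas: dict = field(default_factory=dict)
    discharge_betas: dict = field(default_factory=dict)
    seed: int = 0
    # auxiliary structure, kept out of the headline signature
    prop_acute: float = 0.127
    prop_rural: float = 0.155
    income_probs: tuple[float, ...] = (0.215, 0.199, 0.197, 0.197, 0.192)
    mechanism_probs: tuple[float, ...] = (0.45, 0.20, 0.15, 0.05, 0.15)
    day0_half_interval: bool = True
    prob_unknown_survival: float = 0.02
    missing_los_rate: float = 0.106
    missing_adg_rate: float = 0.101
    max_codes_per_patient: int | None = None
    other_sublocation_probs: tuple[float, ...] = (0.6, 0.2, 0.1, 0.1)

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for p in (self.prop_female, self.prop_acute, self.prop_rural):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if abs(sum(self.severity_probs) - 1.0) > 1e-9:
            raise ValueError("severity_probs must sum to 1")
        for _, pf, pm in self.code_catalog:
            if not (0.0 <= pf <= 1.0 and 0.0 <= pm <= 1.0):
                raise ValueError("code prevalences must lie in [0, 1]")
        labels = [c[0] for c in self.code_catalog]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate code labels in catalog")


def default_code_catalog() -> tuple[tuple[str, float, float], ...]:
    """A catalog with male-enriched, female-enriched, sex-neutral,
    sex-exclusive and near-singleton codes, mirroring the mix the code
    filters and the sex-association screen must cope with."""
    male = [
        ("W12", 0.0010, 0.0100), ("V274", 0.0020, 0.0140),
        ("V685", 0.0008, 0.0060), ("S02410", 0.0030, 0.0120),
        ("Z21", 0.0006, 0.0030), ("W27", 0.0020, 0.0090),
        ("V8608", 0.0010, 0.0070), ("V280", 0.0012, 0.0080),
        # moderately male-enriched, common enough to spread the score
        ("W10", 0.0200, 0.0700), ("V43", 0.0150, 0.0600),
        ("W22", 0.0200, 0.0650), ("X59", 0.0300, 0.0800),
    ]
    female = [
        ("Y070", 0.0100, 0.0008), ("T741", 0.0060, 0.0006),
        ("V800", 0.0120, 0.0015), ("W04", 0.0080, 0.0010),
        ("W54", 0.0090, 0.0020), ("U99037", 0.0050, 0.0006),
        ("Z630", 0.0060, 0.0012), ("V809", 0.0040, 0.0010),
        # moderately female-enriched
        ("R296", 0.0700, 0.0200), ("S934", 0.0600, 0.0150),
        ("M545", 0.0550, 0.0200), ("F432", 0.0500, 0.0180),
    ]
    neutral = [
        ("S060", 0.050, 0.050), ("S010", 0.080, 0.080), ("R51", 0.060, 0.060),
        ("S008", 0.100, 0.100), ("W01", 0.070, 0.070), ("W18", 0.050, 0.050),
        ("S020", 0.030, 0.030), ("R55", 0.040, 0.040), ("Z514", 0.020, 0.020),
        ("S098", 0.090, 0.090), ("T140", 0.030, 0.030), ("W19", 0.080, 0.080),
        ("S014", 0.025, 0.030), ("R42", 0.035, 0.030),
    ]
    exclusive = [("N40", 0.0, 0.004), ("O80", 0.005, 0.0)]
    rare = [("Q999", 1e-5, 1e-5), ("U071", 2e-5, 1e-5)]
    return tuple(male + female + neutral + exclusive + rare)


def default_mortality_betas() -> dict:
    """Log rate ratios of the 30-day excess-mortality process among severe
    cases.  Sex carries the signal (rate ratio 1.5 for female); the latent
    gender score is null; the intercept calibrates 30-day case fatality to
    roughly 9% on top of the matched population rate."""
    return {
        "intercept": 5.7,
        "sex": float(np.log(1.5)),
        "gender_score": 0.0,
        "age": 0.010,
        "adg_score": 0.05,
        "rural": 0.10,
        "income_quintile": -0.05,
        "mechanism_struck": -0.10,
        "mechanism_motor_vehicle": 0.30,
        "mechanism_cyclist": -0.20,
        "mechanism_other": 0.10,
    }


def default_discharge_betas() -> dict:
    """Log odds of each non-reference discharge category versus "home".

    The gender score carries most of the signal — odds ratios ~0.34 for
    "other" and ~0.45 for rehab, >1 for the care facilities — while sex
    conditional on the score matters only for long-term care.  Intercepts
    put marginal category frequencies near home 55%, home-with-support 15%,
    other 17%, rehab 12%, with complex continuing care and long-term care a
    few percent each.
    """
    b = {
        ("home_support", "intercept"): -1.30,
        ("LTC", "intercept"): -3.90,
        ("CCC", "intercept"): -3.20,
        ("rehab", "intercept"): -1.45,
        ("other", "intercept"): -1.10,
        ("LTC", "sex"): float(np.log(1.98)),
        ("home_support", "gender_score"): float(np.log(1.07)),
        ("LTC", "gender_score"): float(np.log(2.14)),
        ("CCC", "gender_score"): float(np.log(1.63)),
        ("other", "gender_score"): float(np.log(0.34)),
        ("rehab", "gender_score"): float(np.log(0.45)),
        ("LTC", "age"): 0.05,
        ("CCC", "age"): 0.03,
        ("rehab", "age"): 0.02,
        ("rehab", "los"): 0.03,
        ("LTC", "los"): 0.02,
        ("home_support", "adg_score"): 0.10,
        ("CCC", "adg_score"): 0.10,
        ("other", "rural"): 0.20,
        ("home_support", "income_quintile"): 0.03,
    }
    return b


def default_config(n_patients: int = 20_000, seed: int = 0) -> SimulationConfig:
    """The study conditions used throughout: Table-1-style demographics,
    the default code catalog and the default outcome processes."""
    return SimulationConfig(
        n_patients=n_patients,
        code_catalog=default_code_catalog(),
        mortality_betas=default_mortality_betas(),
        discharge_betas=default_discharge_betas(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# life tables
# ---------------------------------------------------------------------------

def default_base_rate_curve(age: np.ndarray) -> np.ndarray:
    """Gompertz-like adult annual death rate: 4e-4 at age 20, doubling
    roughly every 10 years."""
    return 4e-4 * np.exp(0.07 * (np.asarray(age, dtype=float) - 20.0))


def generate_life_table(age_range, year_range, base_rate_curve=None,
                        sex_multiplier: float = 1.5, seed: int | None = None,
                        ) -> pd.DataFrame:
    """Build a complete (age, sex, year) grid of annual death rates.

    ``base_rate_curve`` maps age to the female annual rate (callable or dict);
    the male rate is the female rate times ``sex_multiplier``.  Rates are
    clipped into the open interval (0, 1).  ``seed`` is accepted for API
    symmetry; the default table is deterministic.
    """
    a0, a1 = int(age_range[0]), int(age_range[1])
    y0, y1 = int(year_range[0]), int(year_range[1])
    if a1 < a0 or y1 < y0:
        raise ValueError("empty age or year range")
    if sex_multiplier <= 0:
        raise ValueError("sex_multiplier must be positive")
    ages = np.arange(a0, a1 + 1)
    if base_rate_curve is None:
        base = default_base_rate_curve(ages)
    elif callable(base_rate_curve):
        base = np.asarray([base_rate_curve(a) for a in ages], dtype=float)
    else:
        base = np.asarray([base_rate_curve[a] for a in ages], dtype=float)
    if np.any(base <= 0) or np.any(base >= 1):
        raise ValueError("base rates must lie in (0, 1)")
    years = np.arange(y0, y1 + 1)
    rows = []
    for sex_label, mult in (("F", 1.0), ("M", sex_multiplier)):
        rate = np.clip(base * mult, 1e-12, 1 - 1e-12)
        for year in years:
            rows.append(pd.DataFrame({"age": ages, "sex": sex_label,
                                      "year": year, "annual_rate": rate}))
    out = pd.concat(rows, ignore_index=True)
    return out[["age", "sex", "year", "annual_rate"]]


def life_table_lookup(life_table: pd.DataFrame, age, sex, year) -> np.ndarray:
    """Vectorized annual-rate lookup; ``sex`` is 0/1 (M/F) or "M"/"F".

    Raises ``KeyError`` naming the first unmatched (age, sex, year) key.
    """
    age = np.asarray(age)
    year = np.asarray(year)
    sex = np.asarray(sex)
    if sex.dtype.kind in "iufb":
        sex = np.where(sex.astype(int) == 1, "F", "M")
    keys = pd.DataFrame({"age": age, "sex": sex, "year": year})
    merged = keys.merge(life_table, on=["age", "sex", "year"], how="left")
    missing = merged["annual_rate"].isna()
    if missing.any():
        i = int(np.flatnonzero(missing)[0])
        k = (int(age[i]) if age.ndim else int(age),
             str(sex[i]) if sex.ndim else str(sex),
             int(year[i]) if year.ndim else int(year))
        raise KeyError(f"no life-table entry for (age, sex, year) = {k}")
    return merged["annual_rate"].to_numpy()


def write_life_table(path, life_table: pd.DataFrame) -> None:
    life_table.to_csv(path, index=False)


def read_life_table(path) -> pd.DataFrame:
    lt = pd.read_csv(path)
    expected = ["age", "sex", "year", "annual_rate"]
    if list(lt.columns) != expected:
        raise ValueError(f"life table must have columns {expected}")
    if ((lt["annual_rate"] <= 0) | (lt["annual_rate"] >= 1)).any():
        bad = int(np.flatnonzero((lt["annual_rate"] <= 0) | (lt["annual_rate"] >= 1))[0])
        raise ValueError(f"row {bad}: field 'annual_rate': rate must lie in (0, 1)")
    return lt


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _latent_gender_score(carriage: np.ndarray, catalog, prop_female: float) -> np.ndarray:
    """Posterior probability of being female given code carriage under the
    generating model (codes independent given sex) — the quantity the fitted
    gender score estimates."""
    eps = 1e-12
    llr = np.full(carriage.shape[0], logit(prop_female))
    for j, (_, pf, pm) in enumerate(catalog):
        pf_, pm_ = max(pf, eps), max(pm, eps)
        qf_, qm_ = max(1 - pf, eps), max(1 - pm, eps)
        x = carriage[:, j]
        llr += np.where(x == 1, np.log(pf_ / pm_), np.log(qf_ / qm_))
    return expit(llr)


def _centred(cohort: pd.DataFrame, score: np.ndarray) -> dict:
    """Covariate values (centred) addressable by beta name."""
    vals = {
        "sex": cohort["sex"].to_numpy(float),
        "gender_score": score,
        "age": cohort["age"].to_numpy(float) - 40.0,
        "adg_score": cohort["adg_score"].to_numpy(float) - 2.0,
        "rural": cohort["rural"].to_numpy(float),
        "income_quintile": cohort["income_quintile"].to_numpy(float) - 3.0,
        "los": np.nan_to_num(cohort["los"].to_numpy(float) - 5.0),
    }
    for m in MECHANISMS[1:]:
        vals[f"mechanism_{m}"] = (cohort["mechanism"] == m).to_numpy(float)
    return vals


def generate_cohort(config: SimulationConfig, life_table: pd.DataFrame) -> pd.DataFrame:
    """Draw a synthetic first-TBI-event cohort.

    Sex is Bernoulli(prop_female); each catalog code is assigned
    independently at its sex-specific prevalence; 30-day deaths are simulated
    for severe patients only, from the daily hazard
    ``annual_rate/365 × exp(Xβ)`` (a half-length day-0 interval first, then
    days 1..30); discharge location for acute-care patients alive at
    discharge follows the baseline-category logit implied by
    ``discharge_betas``.  Missingness in LOS/ADG is injected completely at
    random after outcomes are drawn.  Fully reproducible from ``config.seed``.
    """
    cfg = config
    n = cfg.n_patients
    labels = [c[0] for c in cfg.code_catalog]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate code labels in catalog")

    ss = np.random.SeedSequence(cfg.seed)
    r_demo, r_codes, r_mort, r_disc, r_miss = (
        np.random.default_rng(s) for s in ss.spawn(5))

    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    sex = (r_demo.random(n) < cfg.prop_female).astype(int)
    age = r_demo.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n)
    year = r_demo.integers(cfg.year_range[0], cfg.year_range[1] + 1, size=n)
    source = np.where(r_demo.random(n) < cfg.prop_acute, "acute", "emergency")
    severity = r_demo.choice(SEVERITIES, size=n, p=cfg.severity_probs)
    mechanism = r_demo.choice(MECHANISMS, size=n, p=cfg.mechanism_probs)
    rural = (r_demo.random(n) < cfg.prop_rural).astype(int)
    income = r_demo.choice(np.arange(1, 6), size=n, p=cfg.income_probs)
    adg = r_demo.poisson(2.2, size=n).astype(float)
    los = np.where(source == "acute",
                   np.round(r_demo.lognormal(np.log(3.5), 0.8, size=n), 1), np.nan)

    # diagnostic codes: independent Bernoulli per catalog entry, sex-specific
    ncodes = len(cfg.code_catalog)
    carriage = np.zeros((n, ncodes), dtype=np.int8)
    for j, (_, pf, pm) in enumerate(cfg.code_catalog):
        prev = np.where(sex == 1, pf, pm)
        carriage[:, j] = r_codes.random(n) < prev
    if cfg.max_codes_per_patient is not None:
        cap = cfg.max_codes_per_patient
        for i in np.flatnonzero(carriage.sum(axis=1) > cap):
            on = np.flatnonzero(carriage[i])
            drop = r_codes.choice(on, size=len(on) - cap, replace=False)
            carriage[i, drop] = 0
    codes = [sorted(labels[j] for j in np.flatnonzero(carriage[i]))
             for i in range(n)]
    latent = (_latent_gender_score(carriage, cfg.code_catalog, cfg.prop_female)
              if ncodes else np.full(n, cfg.prop_female))

    cohort = pd.DataFrame({
        "patient_id": [f"P{i:07d}" for i in range(n)],
        "sex": sex, "age": age, "event_year": year, "codes": codes,
        "source": source, "severity": severity,
        "death_day": np.nan, "survival_known": True,
        "discharge_location": pd.Series([pd.NA] * n, dtype="object"),
        "other_sublocation": pd.Series([pd.NA] * n, dtype="object"),
        "los": los, "adg_score": adg, "rural": rural,
        "income_quintile": income, "mechanism": mechanism,
        "latent_score": latent,
    })

    # --- 30-day mortality among severe cases -------------------------------
    vals = _centred(cohort, latent)
    xb = np.full(n, float(cfg.mortality_betas.get("intercept", 0.0)))
    for name, beta in cfg.mortality_betas.items():
        if name == "intercept" or beta == 0.0:
            continue
        xb += beta * vals[name]
    daily = life_table_lookup(life_table, age, sex, year) / 365.0
    lam = daily * np.exp(xb)
    severe = cohort["severity"].to_numpy() == "severe"
    death_day = np.full(n, np.nan)
    if severe.any():
        lam_s = lam[severe]
        idx = np.flatnonzero(severe)
        if cfg.day0_half_interval:
            die0 = r_mort.random(idx.size) < -np.expm1(-0.5 * lam_s)
        else:
            die0 = np.zeros(idx.size, dtype=bool)
        p_day = -np.expm1(-lam_s)
        first = r_mort.geometric(np.clip(p_day, 1e-300, 1.0))
        dd = np.where(die0, 0, np.where(first <= 30, first, np.nan))
        death_day[idx] = dd
    cohort["death_day"] = death_day

    unknown = r_mort.random(n) < cfg.prob_unknown_survival
    cohort.loc[unknown, "death_day"] = np.nan
    cohort["survival_known"] = ~unknown

    # --- discharge location for acute patients alive at discharge ----------
    dvals = _centred(cohort, latent)
    alive = cohort["death_day"].isna() | (cohort["death_day"] > np.nan_to_num(los, nan=-1.0))
    eligible = (cohort["source"] == "acute") & alive & cohort["survival_known"]
    if eligible.any():
        idx = np.flatnonzero(eligible.to_numpy())
        noncats = [c for c in DISCHARGE_CATEGORIES if c != "home"]
        eta = np.zeros((idx.size, len(noncats)))
        for k, cat in enumerate(noncats):
            for (c, cov), beta in cfg.discharge_betas.items():
                if c != cat or beta == 0.0:
                    continue
                eta[:, k] += beta * (1.0 if cov == "intercept" else dvals[cov][idx])
        full = np.column_stack([np.zeros(idx.size), eta])  # home first
        p = np.exp(full - full.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        u = r_disc.random(idx.size)
        choice = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        cats = ["home"] + noncats
        loc = [cats[c] for c in choice]
        cohort.loc[cohort.index[idx], "discharge_location"] = loc
        is_other = cohort["discharge_location"] == "other"
        if is_other.any():
            subs = r_disc.choice(OTHER_SUBLOCATIONS, size=int(is_other.sum()),
                                 p=cfg.other_sublocation_probs)
            cohort.loc[is_other, "other_sublocation"] = subs

    # --- missingness (MCAR) -------------------------------------------------
    has_los = cohort["los"].notna().to_numpy()
    mask_los = (r_miss.random(n) < cfg.missing_los_rate) & has_los
    cohort.loc[mask_los, "los"] = np.nan
    mask_adg = r_miss.random(n) < cfg.missing_adg_rate
    cohort.loc[mask_adg, "adg_score"] = np.nan

    logger.info("generated cohort: n=%d, severe=%d, deaths=%d, discharged=%d",
                n, int(severe.sum()), int(cohort["death_day"].notna().sum()),
                int(cohort["discharge_location"].notna().sum()))
    return cohort


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(path, cohort: pd.DataFrame) -> None:
    """Write a cohort as UTF-8 CSV; the codes field joins labels with ';'."""
    out = cohort.copy()
    out["codes"] = [_CODE_SEP.join(c) if isinstance(c, (list, tuple, set, frozenset))
                    else ("" if pd.isna(c) else str(c))
                    for c in out["codes"]]
    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


def _fail(row: int, fieldname: str, msg: str):
    raise ValueError(f"row {row}: field '{fieldname}': {msg}")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Empty fields come back as missing (``NaN``/``pd.NA``), never as zero.
    Malformed rows raise ``ValueError`` naming the row number and field.
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=True)
    required = [c for c in COHORT_COLUMNS if c != "latent_score"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file missing columns: {missing_cols}")

    codes = []
    for i, c in enumerate(df["codes"]):
        if pd.isna(c) or str(c) == "":
            codes.append([])
        else:
            codes.append([tok for tok in str(c).split(_CODE_SEP) if tok])
    df["codes"] = codes

    for i, v in enumerate(df["sex"]):
        if int(v) not in (0, 1):
            _fail(i, "sex", f"must be 0 or 1, got {v!r}")
    for i, v in enumerate(df["severity"]):
        if v not in SEVERITIES:
            _fail(i, "severity", f"must be one of {SEVERITIES}, got {v!r}")
    for i, v in enumerate(df["death_day"]):
        if pd.notna(v) and not (0 <= float(v) <= 30):
            _fail(i, "death_day", f"must lie in [0, 30], got {v!r}")
    for i, v in enumerate(df["income_quintile"]):
        if int(v) not in (1, 2, 3, 4, 5):
            _fail(i, "income_quintile", f"must lie in 1..5, got {v!r}")
    for i, v in enumerate(df["discharge_location"]):
        if pd.notna(v) and v not in DISCHARGE_CATEGORIES:
            _fail(i, "discharge_location",
                  f"must be one of {DISCHARGE_CATEGORIES}, got {v!r}")
    df["survival_known"] = df["survival_known"].astype(bool)
    return df
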