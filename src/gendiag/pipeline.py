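"""End-to-end orchestration: simulate (or load) → split → filter codes →
screen → gender score → outcome models → sex-vs-gender comparison →
reports."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codes as codes_mod
from . import compare as compare_mod
from . import discharge as discharge_mod
from . import mortality as mortality_mod
from . import score as score_mod
from . import synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run; YAML-serializable."""

    seed: int = 0
    n_patients: int = 20_000
    cohort_path: str | None = None       # load instead of simulating
    life_table_path: str | None = None
    output_dir: str = "gendiag_output"
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    alpha: float = 0.05
    adjust_method: str = "bh"            # or "bonferroni"
    filter_rule: str = "either"
    baseline: str = "intercept"          # or "day-factor"
    ci_method: str = "profile"           # or "wald"
    write_cohort: bool = False
    report_formats: tuple[str, ...] = ("csv", "json")

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("split_fractions", "report_formats"):
            if k in raw and isinstance(raw[k], list):
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(d["split_fractions"])
        d["report_formats"] = list(d["report_formats"])
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def derive_gender_scores(train, validation, test, alpha=0.05,
                         adjust_method="bh", filter_rule="either") -> dict:
    """Screen, select and fit the gender-score model; score the test set.

    Returns screening tables, the filter report, the fitted model and the
    test-set scores (aligned to ``test``).
    """
    m_train = codes_mod.build_indicator_matrix(train)
    m_valid = codes_mod.build_indicator_matrix(validation)
    m_train, m_valid, filter_report = codes_mod.filter_codes(
        m_train, m_valid, rule=filter_rule)
    scr_train = score_mod.univariate_screen(m_train)
    scr_valid = score_mod.univariate_screen(m_valid)
    selected = score_mod.select_codes(scr_train, scr_valid, alpha=alpha,
                                      method=adjust_method)
    model = score_mod.fit_score_model(m_train, selected)
    m_test = codes_mod.build_indicator_matrix(test)
    scores = score_mod.compute_scores(model, m_test)
    scr_train["significant_train"] = score_mod.adjust_pvalues(
        scr_train["p_value"], alpha, adjust_method)
    scr_valid["significant_validation"] = score_mod.adjust_pvalues(
        scr_valid["p_value"], alpha, adjust_method)
    return {"screen_train": scr_train, "screen_validation": scr_valid,
            "filter_report": filter_report, "selected_codes": selected,
            "model": model, "test_scores": scores}


def make_table1(cohorts: dict) -> pd.DataFrame:
    """Characteristics summary: percentages for categorical fields,
    median/Q1/Q3 for continuous ones (LOS and ADG over non-missing records
    only)."""
    rows = {}
    for name, df in cohorts.items():
        col = {}
        col["N"] = len(df)
        if len(df) == 0:
            rows[name] = col
            continue
        col["female_pct"] = round(100.0 * (df["sex"] == 1).mean(), 1)
        col["acute_pct"] = round(100.0 * (df["source"] == "acute").mean(), 1)
        for stat, qv in (("median", 0.5), ("q1", 0.25), ("q3", 0.75)):
            col[f"age_{stat}"] = float(df["age"].quantile(qv))
        col["rural_pct"] = round(100.0 * (df["rural"] == 1).mean(), 1)
        for q in range(1, 6):
            col[f"income_q{q}_pct"] = round(
                100.0 * (df["income_quintile"] == q).mean(), 1)
        for v, lab in (("los", "los"), ("adg_score", "adg")):
            nm = df[v].dropna()   # based on non-missing records
            for stat, qv in (("median", 0.5), ("q1", 0.25), ("q3", 0.75)):
                col[f"{lab}_{stat}"] = float(nm.quantile(qv)) if len(nm) else np.nan
        for s in synthetic.SEVERITIES:
            col[f"severity_{s}_pct"] = round(
                100.0 * (df["severity"] == s).mean(), 1)
        rows[name] = col
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write reports under
    ``config.output_dir``.  Returns the in-memory results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- data ---------------------------------------------------------------
    if config.life_table_path is not None:
        lt_path = Path(config.life_table_path)
        if not lt_path.exists():
            raise FileNotFoundError(f"life table not found: {lt_path}")
        life_table = synthetic.read_life_table(lt_path)
    else:
        life_table = synthetic.generate_life_table((16, 64), (2002, 2019))
    if config.cohort_path is not None:
        c_path = Path(config.cohort_path)
        if not c_path.exists():
            raise FileNotFoundError(f"cohort not found: {c_path}")
        cohort = synthetic.read_cohort(c_path)
    else:
        sim = synthetic.default_config(n_patients=config.n_patients,
                                       seed=config.seed)
        cohort = synthetic.generate_cohort(sim, life_table)
    logger.info("stage data: cohort n=%d", len(cohort))

    # --- split and gender score --------------------------------------------
    train, validation, test = codes_mod.split_dataset(
        cohort, config.split_fractions, seed=config.seed)
    logger.info("stage split: train=%d validation=%d test=%d",
                len(train), len(validation), len(test))
    gs = derive_gender_scores(train, validation, test, alpha=config.alpha,
                              adjust_method=config.adjust_method,
                              filter_rule=config.filter_rule)
    test = test.copy()
    test["gender_score"] = gs["test_scores"]
    score_summary = score_mod.summarize_scores(
        test["gender_score"], test["sex"], test["age"])

    # --- outcome models ------------------------------------------------------
    mort_fits = mortality_mod.mortality_model_suite(
        test, life_table, baseline=config.baseline, ci_method=config.ci_method)
    mort_cohort, _ = mortality_mod.restrict_mortality_cohort(test)
    mort_cmp = compare_mod.compare_sex_vs_gender(
        mort_fits["sex_only"], mort_fits["gender_only"], mort_fits["both"],
        n=len(mort_cohort))

    disc_fits = discharge_mod.discharge_model_suite(
        test, ci_method=config.ci_method)
    disc_cohort, _ = discharge_mod.restrict_discharge_cohort(test)
    disc_cmp = compare_mod.compare_sex_vs_gender(
        disc_fits["sex_only"], disc_fits["gender_only"], disc_fits["both"],
        n=len(disc_cohort))
    subgroups = discharge_mod.other_subgroup_logits(
        disc_cohort, ci_method=config.ci_method)

    table1 = make_table1({"all": cohort, "mortality_test": mort_cohort,
                          "discharge_test": disc_cohort})

    # --- reports -------------------------------------------------------------
    results = {
        "screen_train": gs["screen_train"],
        "screen_validation": gs["screen_validation"],
        "selected_codes": gs["selected_codes"],
        "score_model": gs["model"],
        "score_summary": score_summary,
        "mortality_fits": mort_fits,
        "mortality_summary": mortality_mod.mortality_summary(mort_cohort),
        "mortality_comparison": mort_cmp,
        "discharge_fits": disc_fits,
        "discharge_comparison": disc_cmp,
        "other_subgroups": subgroups,
        "table1": table1,
        "test_cohort": test,
    }
    _write_reports(results, config, out)
    if config.write_cohort:
        synthetic.write_cohort(out / "cohort.csv", cohort)
        synthetic.write_life_table(out / "life_table.csv", life_table)
    return results


def _write_reports(results: dict, config: RunConfig, out: Path) -> None:
    results["screen_train"].to_csv(out / "screening_train.csv", index=False)
    results["screen_validation"].to_csv(out / "screening_validation.csv",
                                        index=False)
    (out / "selected_codes.txt").write_text(
        "\n".join(results["selected_codes"]) + "\n"
        if results["selected_codes"] else "")
    results["score_summary"]["by_sex"].to_csv(out / "score_summary_by_sex.csv")
    results["score_summary"]["by_age_decade"].to_csv(
        out / "score_summary_by_age_decade.csv")
    mortality_mod.mortality_report(results["mortality_fits"]).to_csv(
        out / "mortality_models.csv", index=False)
    discharge_mod.discharge_report(results["discharge_fits"]).to_csv(
        out / "discharge_models.csv", index=False)
    results["table1"].to_csv(out / "table1.csv")
    comparison = {
        "mortality": results["mortality_comparison"].as_dict(),
        "discharge": results["discharge_comparison"].as_dict(),
        "mortality_summary": results["mortality_summary"],
    }
    (out / "comparison.json").write_text(json.dumps(comparison, indent=2,
                                                    default=float) + "\n")
    manifest = {"config": config.to_dict(), "config_hash": _config_hash(config),
                "n_selected_codes": len(results["selected_codes"])}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
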