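"""Cohort CSV input/output, pipeline configuration, and the study driver.

The cohort CSV schema carries one row per eye:

    patient_id, eye_role, al_pre_phakic, al_post_aphakic,
    al_post_pseudophakic, al_post_repeat, km_pre, km_post, iol_model,
    iol_a_constant, iol_power, postop_se, has_stable_refraction

UTF-8, header row mandatory, decimal point ".", missing optional values
empty.  ``run_study`` wires the stages into the full retrospective
calibration: descriptive tables, the formula x AL-option prediction-error
comparison with lens-constant zeroing, the AL-correction regression and
Bland-Altman agreement summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .biometry import ALOption, BiometryRecord, LensConstants
from .calibration import (
    OptionEvaluation,
    evaluate_options,
    fit_al_correction,
)
from .formulas import FormulaId, required_constant_field
from .stats_protocol import bland_altman, one_sample_t, paired_t

__all__ = ["COHORT_COLUMNS", "PipelineConfig", "StudyReport", "read_cohort", "write_cohort", "run_study"]

logger = logging.getLogger("iolcalib")

COHORT_COLUMNS = [
    "patient_id",
    "eye_role",
    "al_pre_phakic",
    "al_post_aphakic",
    "al_post_pseudophakic",
    "al_post_repeat",
    "km_pre",
    "km_post",
    "iol_model",
    "iol_a_constant",
    "iol_power",
    "postop_se",
    "has_stable_refraction",
]

_FLOAT_COLUMNS = [
    "al_pre_phakic", "al_post_aphakic", "al_post_pseudophakic", "al_post_repeat",
    "km_pre", "km_post", "iol_a_constant", "iol_power", "postop_se",
]


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end study run."""

    input_path: Path
    formulas: Sequence[FormulaId] = (
        FormulaId.SRKT, FormulaId.HOFFERQ, FormulaId.HOLLADAY1, FormulaId.COMBO,
    )
    options: Sequence[ALOption] = (
        ALOption.PHAKIC, ALOption.PSEUDOPHAKIC_ACRYLATE, ALOption.APHAKIC,
    )
    constants: Dict[str, LensConstants] = field(default_factory=dict)
    optimize: bool = True
    out_dir: Path = Path("study_out")
    seed: Optional[int] = None
    verbosity: int = 0

    def validate(self) -> None:
        for f in self.formulas:
            cs = self.constants_for(f)
            fieldname = required_constant_field(f)
            if getattr(cs, fieldname) is None:
                raise ValueError(f"formula {f.value} requires the {fieldname} constant")
            if f is FormulaId.COMBO and cs.pacd is None:
                raise ValueError("combo requires both an A-constant and a pACD")

    def constants_for(self, formula: FormulaId) -> LensConstants:
        key = formula.value
        if key in self.constants:
            return self.constants[key]
        if "default" in self.constants:
            return self.constants["default"]
        raise ValueError(f"no lens constants configured for formula {formula.value}")


@dataclass
class StudyReport:
    """In-memory bundle of the study outputs."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    alc: dict
    bland_altman: pd.DataFrame
    evaluations: List[OptionEvaluation]


def _parse_row(idx: int, row: pd.Series) -> BiometryRecord:
    kwargs = {}
    for col in COHORT_COLUMNS:
        v = row[col]
        if col in _FLOAT_COLUMNS:
            if pd.isna(v) or v == "":
                kwargs[col] = None
            else:
                try:
                    kwargs[col] = float(v)
                except (TypeError, ValueError):
                    raise ValueError(f"row {idx}: malformed number in column {col!r}: {v!r}") from None
        elif col == "has_stable_refraction":
            if pd.isna(v) or v == "":
                kwargs[col] = False
            elif str(v).strip().lower() in ("true", "1", "yes"):
                kwargs[col] = True
            elif str(v).strip().lower() in ("false", "0", "no"):
                kwargs[col] = False
            else:
                raise ValueError(f"row {idx}: malformed boolean in has_stable_refraction: {v!r}")
        else:
            kwargs[col] = None if pd.isna(v) else str(v)
    try:
        return BiometryRecord(**kwargs)
    except ValueError as exc:
        raise ValueError(f"row {idx}: {exc}") from None


def read_cohort(path) -> List[BiometryRecord]:
    """Read and validate a cohort CSV; errors carry the offending row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "eye_role": str, "iol_model": str})
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown column(s) in cohort CSV: {sorted(unknown)}")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks column(s): {sorted(missing)}")
    # row numbers are 1-based data rows (header = row 0)
    return [_parse_row(i + 1, row) for i, row in df.iterrows()]


def write_cohort(records: Sequence[BiometryRecord], path) -> None:
    """Serialize records to the cohort CSV schema (deterministic layout)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["has_stable_refraction"] = "true" if r.has_stable_refraction else "false"
        rows.append({c: d[c] for c in COHORT_COLUMNS})
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def _describe(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "n": int(values.size),
    }


def _table1(records: Sequence[BiometryRecord]) -> pd.DataFrame:
    """Descriptive Km/AL table with paired before-vs-after p-values."""
    ops = [r for r in records if r.eye_role == "operated"]
    fes = [r for r in records if r.eye_role == "fellow"]
    rows = []

    def add(parameter, pre, post, unit):
        pre, post = np.asarray(pre, float), np.asarray(post, float)
        entry = {"parameter": parameter, "unit": unit}
        entry.update({f"pre_{k}": v for k, v in _describe(pre).items()})
        entry.update({f"post_{k}": v for k, v in _describe(post).items()})
        entry["p_paired_t"] = paired_t(post, pre).p_value
        rows.append(entry)

    if ops:
        add("km_operated", [r.km_pre for r in ops], [r.km_post for r in ops], "D")
        add(
            "al_operated_pseudophakic",
            [r.al_pre_phakic for r in ops],
            [r.al_post_pseudophakic for r in ops],
            "mm",
        )
        add(
            "al_operated_aphakic",
            [r.al_pre_phakic for r in ops],
            [r.al_post_aphakic for r in ops],
            "mm",
        )
    if fes:
        add("km_fellow", [r.km_pre for r in fes], [r.km_post for r in fes], "D")
        add("al_fellow", [r.al_pre_phakic for r in fes], [r.al_post_repeat for r in fes], "mm")
    return pd.DataFrame(rows)


def _table2(evaluations: List[OptionEvaluation]) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        row = {
            "formula": ev.formula.value,
            "option": ev.al_option.value,
            "n": ev.supplied.n,
            "me_supplied": ev.supplied.me,
            "sd_supplied": ev.supplied.sd,
            "p_me_vs_zero": one_sample_t(ev.supplied.pe, 0.0).p_value,
        }
        if ev.optimized is not None:
            row.update(
                me_optimized=ev.optimized.me,
                sd_optimized=ev.optimized.sd,
                medae_optimized=ev.optimized.medae,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _table3(evaluations: List[OptionEvaluation]) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        if ev.optimized_constants is None:
            continue
        cfield = required_constant_field(ev.formula)
        rows.append(
            {
                "formula": ev.formula.value,
                "option": ev.al_option.value,
                "constant": cfield,
                "value": getattr(ev.optimized_constants, cfield),
                "pacd_tied": ev.optimized_constants.pacd if ev.formula is FormulaId.COMBO else None,
            }
        )
    return pd.DataFrame(rows)


def _bland_altman_table(records: Sequence[BiometryRecord]) -> pd.DataFrame:
    ops = [r for r in records if r.eye_role == "operated"]
    rows = []
    pairs = [
        ("ps_minus_ph", [r.al_post_pseudophakic for r in ops], [r.al_pre_phakic for r in ops]),
        ("ap_minus_ph", [r.al_post_aphakic for r in ops], [r.al_pre_phakic for r in ops]),
    ]
    for name, x, y in pairs:
        ba = bland_altman(x, y)
        rows.append(
            {
                "comparison": name,
                "bias": ba.bias,
                "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "n": ba.n,
            }
        )
    return pd.DataFrame(rows)


def run_study(config: PipelineConfig, records: Optional[List[BiometryRecord]] = None) -> StudyReport:
    """Run the retrospective calibration study end to end.

    Reads the cohort (unless records are passed in), produces the
    descriptive table, the formula x option PE comparison with optional
    lens-constant zeroing, the optimized-constant table, the AL-correction
    regression and Bland-Altman summaries, and writes them under
    ``config.out_dir`` along with a JSON run log.  Deterministic given
    input and configuration; input records are never mutated.
    """
    config.validate()
    if records is None:
        records = read_cohort(config.input_path)
    ops = [r for r in records if r.eye_role == "operated"]
    if not ops:
        raise ValueError("cohort has no operated eyes")

    constants_map = {f: config.constants_for(f) for f in config.formulas}
    evaluations = evaluate_options(
        records, config.formulas, constants_map, config.options, optimize=config.optimize
    )

    corr = fit_al_correction(
        [r.al_pre_phakic for r in ops], [r.al_post_pseudophakic for r in ops]
    )
    report = StudyReport(
        table1=_table1(records),
        table2=_table2(evaluations),
        table3=_table3(evaluations),
        alc={"intercept": corr.intercept, "slope": corr.slope, "r_squared": corr.r_squared},
        bland_altman=_bland_altman_table(records),
        evaluations=evaluations,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # rounding happens only here, at serialization
    report.table1.to_csv(out / "table1.csv", index=False, float_format="%.6f", lineterminator="\n")
    t2 = report.table2.copy()
    for c in t2.columns:
        if c.startswith(("me_", "sd_", "medae_")):
            t2[c] = t2[c].round(2) + 0.0  # avoid "-0.0"
        if c.startswith("p_"):
            t2[c] = t2[c].round(3)
    t2.to_csv(out / "table2.csv", index=False, lineterminator="\n")
    t3 = report.table3.copy()
    t3["value"] = t3["value"].round(2)
    if "pacd_tied" in t3.columns:
        t3["pacd_tied"] = t3["pacd_tied"].round(2)
    t3.to_csv(out / "table3.csv", index=False, lineterminator="\n")
    report.bland_altman.to_csv(out / "bland_altman.csv", index=False, float_format="%.6f", lineterminator="\n")
    (out / "alc.json").write_text(json.dumps(report.alc, indent=2, sort_keys=True) + "\n")
    log = {
        "package_version": __version__,
        "input": str(config.input_path),
        "formulas": [f.value for f in config.formulas],
        "options": [o.value for o in config.options],
        "optimize": config.optimize,
        "seed": config.seed,
        "constants": {
            k: {f.name: getattr(v, f.name) for f in dataclasses.fields(v)}
            for k, v in config.constants.items()
        },
        "n_records": len(records),
        "n_operated": len(ops),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    logger.info("study outputs written to %s", out)
    return report
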