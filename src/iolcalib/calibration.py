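"""Prediction-error analysis, lens-constant zeroing and AL correction.

The refractive prediction error (PE) of an eye is the achieved postoperative
spherical-equivalent refraction minus the refraction a formula predicts for
the implanted IOL — always from the preoperative keratometry, with the AL
reading taken from a chosen biometer display option.  A systematic component
of the mean error (ME) can be removed either by optimizing the formula's
lens constant until ME = 0 (the classical route) or, as studied here, by
regressing the postoperative pseudophakic AL on the preoperative phakic AL
and feeding the corrected AL to the unchanged formula.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .biometry import ALOption, BiometryRecord, LensConstants
from .formulas import (
    FormulaId,
    convert_a_constant,
    predicted_refraction,
    required_constant_field,
)

__all__ = [
    "PESummary",
    "ALCorrection",
    "OptionEvaluation",
    "prediction_error",
    "prediction_errors",
    "summarize",
    "zero_me_constant",
    "fit_al_correction",
    "apply_al_correction",
    "evaluate_options",
]

#: |mean PE| tolerance of the zeroing root-finder (D)
ME_TOLERANCE = 1e-4
#: constant tolerance of the zeroing root-finder
CONSTANT_XTOL = 1e-6
#: default half-width of the zeroing bracket per constant kind
DEFAULT_BRACKET_HALFWIDTH = {"a_constant": 3.0, "pacd": 1.5, "sf": 1.5}


@dataclass
class PESummary:
    """Per formula x AL-option summary of refractive prediction errors."""

    formula: FormulaId
    al_option: ALOption
    pe: np.ndarray
    me: float
    sd: float
    medae: float
    n: int


@dataclass
class ALCorrection:
    """Linear AL correction ALc = intercept + slope * AL."""

    intercept: float
    slope: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"R^2 {self.r_squared} outside [0, 1]")


@dataclass
class OptionEvaluation:
    """One row bundle of the formula-comparison table."""

    formula: FormulaId
    al_option: ALOption
    supplied: PESummary
    optimized: Optional[PESummary] = None
    optimized_constants: Optional[LensConstants] = None


def _eligible(records: Sequence[BiometryRecord]) -> List[BiometryRecord]:
    return [
        r for r in records
        if r.eye_role == "operated" and r.has_stable_refraction and r.postop_se is not None
    ]


def _arrays(records: Sequence[BiometryRecord], al_option: ALOption):
    al = np.array([r.al_reading(al_option) for r in records])
    km = np.array([r.km_pre for r in records])
    power = np.array([r.iol_power for r in records], dtype=float)
    se = np.array([r.postop_se for r in records], dtype=float)
    return al, km, power, se


def prediction_error(
    record: BiometryRecord,
    formula: FormulaId,
    constants: LensConstants,
    al_option: ALOption,
) -> float:
    """PE (D) of one eye: achieved minus predicted refraction.

    Uses the preoperative keratometry and the AL reading selected by
    ``al_option``; requires a stable postoperative refraction.
    """
    if not record.has_stable_refraction or record.postop_se is None:
        raise ValueError(
            f"record {record.patient_id}/{record.eye_role} has no stable postoperative refraction"
        )
    al = record.al_reading(al_option)
    pred = predicted_refraction(formula, al, record.km_pre, constants, record.iol_power)
    return float(record.postop_se - pred)


def prediction_errors(
    records: Sequence[BiometryRecord],
    formula: FormulaId,
    constants: LensConstants,
    al_option: ALOption,
) -> np.ndarray:
    """Vectorized PEs over all eligible (operated, stable-refraction) eyes."""
    eligible = _eligible(records)
    if not eligible:
        raise ValueError("no eligible records with stable postoperative refraction")
    al, km, power, se = _arrays(eligible, al_option)
    return se - predicted_refraction(formula, al, km, constants, power)


def summarize(pe, formula: FormulaId = None, al_option: ALOption = None) -> PESummary:
    """ME, sample SD and median absolute error of a PE list."""
    pe = np.asarray(pe, dtype=float)
    if pe.size < 2:
        raise ValueError("PE summary requires at least 2 values")
    return PESummary(
        formula=formula,
        al_option=al_option,
        pe=pe,
        me=float(pe.mean()),
        sd=float(pe.std(ddof=1)),
        medae=float(np.median(np.abs(pe))),
        n=int(pe.size),
    )


def _with_constant(
    formula: FormulaId, base: LensConstants, value: float
) -> LensConstants:
    """Lens constants with the formula's optimization variable set to ``value``.

    For Combo the single A-constant drives both branch constants through
    the standard conversion relations.
    """
    if formula is FormulaId.COMBO:
        out = convert_a_constant(value)
        out.source = "optimized"
        return out
    field = required_constant_field(formula)
    out = dataclasses.replace(base, **{field: value})
    out.source = "optimized"
    return out


def zero_me_constant(
    records: Sequence[BiometryRecord],
    formula: FormulaId,
    al_option: ALOption,
    constants: LensConstants,
    bracket: Optional[Tuple[float, float]] = None,
) -> LensConstants:
    """Lens constants zeroing the mean prediction error for one formula/option.

    Mean PE is strictly monotone in the lens constant, so a bracketed root
    search (Brent) drives |ME| below ``ME_TOLERANCE``.  The optimization
    variable is the A-constant for SRK/T and Combo (Combo's pACD tied via
    the conversion relations), the pACD for Hoffer Q, and the surgeon
    factor for Holladay 1.
    """
    eligible = _eligible(records)
    if len(eligible) < 2:
        raise ValueError("zeroing requires at least 2 eligible records")
    field = required_constant_field(formula)
    start = getattr(constants, field)
    if start is None:
        raise ValueError(f"constants lack the {field} required by {formula.value}")

    al, km, power, se = _arrays(eligible, al_option)

    def mean_error(c: float) -> float:
        cs = _with_constant(formula, constants, c)
        return float(np.mean(se - predicted_refraction(formula, al, km, cs, power)))

    if bracket is None:
        hw = DEFAULT_BRACKET_HALFWIDTH[field]
        bracket = (start - hw, start + hw)
    lo, hi = bracket
    me_lo, me_hi = mean_error(lo), mean_error(hi)
    if me_lo * me_hi > 0:
        raise ValueError(
            f"mean error does not change sign over bracket [{lo}, {hi}]: "
            f"ME({lo})={me_lo:.4f} D, ME({hi})={me_hi:.4f} D"
        )
    root = brentq(mean_error, lo, hi, xtol=CONSTANT_XTOL)
    if abs(mean_error(root)) >= ME_TOLERANCE:
        raise ArithmeticError("zeroing failed to reach the ME tolerance")
    return _with_constant(formula, constants, root)


def fit_al_correction(al_pre, al_post_ps) -> ALCorrection:
    """OLS regression of the pseudophakic postoperative AL on the phakic AL.

    Returns the correction ALc = intercept + slope * AL with its R^2.
    """
    x = np.asarray(al_pre, dtype=float)
    y = np.asarray(al_post_ps, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired AL lists must have equal length")
    if x.size < 3:
        raise ValueError("AL correction fit requires at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in preoperative AL")
    res = stats.linregress(x, y)
    return ALCorrection(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(min(res.rvalue**2, 1.0)),
    )


def apply_al_correction(al, corr: ALCorrection):
    """Corrected axial length ALc = intercept + slope * AL (mm)."""
    out = corr.intercept + corr.slope * np.asarray(al, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def evaluate_options(
    records: Sequence[BiometryRecord],
    formulas: Sequence[FormulaId],
    constants_map: Dict[FormulaId, LensConstants],
    options: Sequence[ALOption] = (
        ALOption.PHAKIC,
        ALOption.PSEUDOPHAKIC_ACRYLATE,
        ALOption.APHAKIC,
    ),
    optimize: bool = True,
) -> List[OptionEvaluation]:
    """PE summaries for every formula x AL option, before and after zeroing.

    Ordering is deterministic: formulas in the given order, options in the
    given order within each formula.
    """
    out: List[OptionEvaluation] = []
    for formula in formulas:
        constants = constants_map[formula]
        for option in options:
            pe = prediction_errors(records, formula, constants, option)
            row = OptionEvaluation(
                formula=formula,
                al_option=option,
                supplied=summarize(pe, formula, option),
            )
            if optimize:
                opt_c = zero_me_constant(records, formula, option, constants)
                pe_opt = prediction_errors(records, formula, opt_c, option)
                row.optimized = summarize(pe_opt, formula, option)
                row.optimized_constants = opt_c
            out.append(row)
    return out
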