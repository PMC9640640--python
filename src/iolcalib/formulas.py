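"""Vergence-based IOL power formulas: SRK/T, Hoffer Q, Holladay 1, Combo.

Each formula predicts the postoperative spherical-equivalent refraction at
the spectacle plane for a given axial length (AL, mm), mean keratometry
(K, D), implanted IOL power (D) and its lens constant.  All three leaves are
thin-lens vergence models differing in how they estimate the effective lens
position (ELP), which corneal index they assume, and what optical axial
length they focus on:

* SRK/T: corneal-height ELP from the A-constant, retinal-thickness-corrected
  optical AL, corneal index 1.333.
* Hoffer Q: personalized-ACD (pACD) tangent model, corneal power used
  directly (keratometric), solved at the corneal plane then vertex-converted.
* Holladay 1: anatomical ACD from corneal height plus the surgeon factor
  (SF), corneal index 4/3, optical AL = AL + 0.2 mm.

The Combo method dispatches on the AL used for prediction: Hoffer Q for
AL < 23.00 mm and SRK/T for AL >= 23.00 mm.

Functions are NumPy-vectorized: scalars in, scalar out; arrays in, arrays
out.  Wang-Koch long-eye AL adjustments are intentionally not applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .biometry import (
    DEFAULT_VERTEX_MM,
    IOL_POWER_RANGE,
    LensConstants,
    corneal_radius_from_k,
    vertex_convert,
)

__all__ = [
    "FormulaId",
    "FormulaIntermediates",
    "PredictionInput",
    "srkt_predicted_refraction",
    "srkt_emmetropia_power",
    "hofferq_predicted_refraction",
    "hofferq_emmetropia_power",
    "holladay1_predicted_refraction",
    "holladay1_emmetropia_power",
    "combo_predicted_refraction",
    "predicted_refraction",
    "emmetropia_power",
    "power_for_target_refraction",
    "convert_a_constant",
    "required_constant_field",
]

NA = 1.336  # aqueous/vitreous index shared by the vergence forms
COMBO_AL_THRESHOLD = 23.00


class FormulaId(Enum):
    SRKT = "srkt"
    HOFFERQ = "hofferq"
    HOLLADAY1 = "holladay1"
    COMBO = "combo"

    @classmethod
    def from_label(cls, label: str) -> "FormulaId":
        try:
            return cls(label.lower())
        except ValueError:
            raise ValueError(f"unknown formula {label!r}") from None


#: which LensConstants field each formula's ELP estimate consumes
_CONSTANT_FIELD = {
    FormulaId.SRKT: "a_constant",
    FormulaId.HOFFERQ: "pacd",
    FormulaId.HOLLADAY1: "sf",
    FormulaId.COMBO: "a_constant",
}


def required_constant_field(formula: FormulaId) -> str:
    return _CONSTANT_FIELD[formula]


@dataclass
class FormulaIntermediates:
    """Internal quantities of one formula evaluation (scalar inputs only)."""

    formula: FormulaId
    r: float
    na: float = NA
    v: float = DEFAULT_VERTEX_MM
    nc_minus_1: Optional[float] = None
    # SRK/T
    lcor: Optional[float] = None
    cw: Optional[float] = None
    h: Optional[float] = None
    acd_const: Optional[float] = None
    acd_est: Optional[float] = None
    rethick: Optional[float] = None
    lopt: Optional[float] = None
    # Hoffer Q
    acd_pred: Optional[float] = None
    m: Optional[float] = None
    g: Optional[float] = None
    # Holladay 1
    rag: Optional[float] = None
    ag: Optional[float] = None
    acd_anat: Optional[float] = None
    alm: Optional[float] = None


@dataclass
class PredictionInput:
    """One formula evaluation request (AL reading already selected)."""

    al: float
    km: float
    constants: LensConstants
    iol_power: float


def convert_a_constant(a: float) -> LensConstants:
    """Standard conversions from an A-constant to pACD and surgeon factor.

    SF = 0.5663*A - 65.60;  pACD = 0.58357*A - 63.896.
    """
    return LensConstants(
        a_constant=a,
        sf=0.5663 * a - 65.60,
        pacd=0.58357 * a - 63.896,
        source="converted",
    )


def _generalized_vergence_refraction(r, lopt, elp, power, nc_minus_1, na=NA, v=DEFAULT_VERTEX_MM):
    """Back-calculated spectacle refraction of the shared vergence form."""
    num = 1000.0 * na * (na * r - nc_minus_1 * lopt) - power * (lopt - elp) * (na * r - nc_minus_1 * elp)
    den = na * (v * (na * r - nc_minus_1 * lopt) + lopt * r) - 0.001 * power * (lopt - elp) * (
        v * (na * r - nc_minus_1 * elp) + elp * r
    )
    if np.any(np.abs(den) < 1e-12):
        raise ZeroDivisionError("vergence denominator vanished")
    return num / den


def _generalized_emmetropia_power(r, lopt, elp, nc_minus_1, na=NA):
    den = (lopt - elp) * (na * r - nc_minus_1 * elp)
    if np.any(np.abs(den) < 1e-12):
        raise ZeroDivisionError("emmetropia power denominator vanished")
    return 1000.0 * na * (na * r - nc_minus_1 * lopt) / den


# --------------------------------------------------------------------------
# SRK/T
# --------------------------------------------------------------------------

def _srkt_geometry(al, km, a_constant):
    """r, ELP estimate and optical AL of the SRK/T chain."""
    al = np.asarray(al, dtype=float)
    km = np.asarray(km, dtype=float)
    r = corneal_radius_from_k(km)
    lcor = np.where(al <= 24.2, al, -3.446 + 1.716 * al - 0.0237 * al * al)
    cw = -5.41 + 0.58412 * lcor + 0.098 * km
    disc = r * r - cw * cw / 4.0
    if np.any(disc < 0):
        warnings.warn("SRK/T corneal height discriminant negative; clamped to 0 (steep cornea)")
    h = r - np.sqrt(np.maximum(disc, 0.0))
    acd_const = 0.62467 * a_constant - 68.747
    acd_est = h + (acd_const - 3.336)
    rethick = 0.65696 - 0.02029 * al
    lopt = al + rethick
    return r, lcor, cw, h, acd_const, acd_est, rethick, lopt


def srkt_predicted_refraction(al, km, constants: LensConstants, iol_power):
    """SRK/T back-calculated refraction at the spectacle plane (D)."""
    if constants.a_constant is None:
        raise ValueError("SRK/T requires an A-constant")
    r, *_, acd_est, _, lopt = _srkt_geometry(al, km, constants.a_constant)
    out = _generalized_vergence_refraction(r, lopt, acd_est, np.asarray(iol_power, float), 0.333)
    return float(out) if np.ndim(out) == 0 else out


def srkt_emmetropia_power(al, km, constants: LensConstants):
    """IOL power giving 0 D spectacle refraction under SRK/T."""
    if constants.a_constant is None:
        raise ValueError("SRK/T requires an A-constant")
    r, *_, acd_est, _, lopt = _srkt_geometry(al, km, constants.a_constant)
    out = _generalized_emmetropia_power(r, lopt, acd_est, 0.333)
    return float(out) if np.ndim(out) == 0 else out


def srkt_intermediates(al: float, km: float, constants: LensConstants) -> FormulaIntermediates:
    r, lcor, cw, h, acd_const, acd_est, rethick, lopt = _srkt_geometry(al, km, constants.a_constant)
    return FormulaIntermediates(
        formula=FormulaId.SRKT, r=float(r), nc_minus_1=0.333, lcor=float(lcor), cw=float(cw),
        h=float(h), acd_const=float(acd_const), acd_est=float(acd_est),
        rethick=float(rethick), lopt=float(lopt),
    )


# --------------------------------------------------------------------------
# Hoffer Q
# --------------------------------------------------------------------------

HOFFERQ_AL_CLAMP = (18.5, 31.0)


def _hofferq_acd(al, km, pacd):
    """Hoffer Q predicted ACD (mm); trigonometric arguments in degrees."""
    al = np.asarray(al, dtype=float)
    km = np.asarray(km, dtype=float)
    alm = np.clip(al, *HOFFERQ_AL_CLAMP)
    m = np.where(alm <= 23.0, 1.0, -1.0)
    g = np.where(alm <= 23.0, 28.0, 23.5)
    tan_k = np.tan(np.radians(km))
    acd = (
        pacd
        + 0.3 * (alm - 23.5)
        + tan_k * tan_k
        + 0.1 * m * (23.5 - alm) ** 2 * np.tan(np.radians(0.1 * (g - alm) ** 2))
        - 0.99166
    )
    return acd, m, g, alm


def hofferq_predicted_refraction(al, km, constants: LensConstants, iol_power):
    """Hoffer Q back-calculated refraction at the spectacle plane (D).

    The closed form solves the refraction at the corneal plane, then
    converts to the spectacle plane over the 12 mm vertex distance.
    """
    if constants.pacd is None:
        raise ValueError("Hoffer Q requires a pACD constant")
    al = np.asarray(al, dtype=float)
    km = np.asarray(km, dtype=float)
    p = np.asarray(iol_power, dtype=float)
    acd, *_ = _hofferq_acd(al, km, constants.pacd)
    vitreous = al - acd - 0.05
    if np.any(vitreous <= 0):
        raise ValueError("Hoffer Q: AL - ACD - 0.05 must be positive")
    denom = 1336.0 / vitreous - p
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("Hoffer Q: singular intermediate vergence")
    inner = 1.336 / denom + (acd + 0.05) / 1000.0
    if np.any(np.abs(inner) < 1e-12):
        raise ZeroDivisionError("Hoffer Q: singular corneal-plane vergence")
    r_cornea = 1.336 / inner - km
    out = vertex_convert(r_cornea, direction="cornea_to_spectacle")
    return float(out) if np.ndim(out) == 0 else out


def hofferq_emmetropia_power(al, km, constants: LensConstants):
    """IOL power giving 0 D refraction under Hoffer Q (closed form)."""
    if constants.pacd is None:
        raise ValueError("Hoffer Q requires a pACD constant")
    al = np.asarray(al, dtype=float)
    km = np.asarray(km, dtype=float)
    acd, *_ = _hofferq_acd(al, km, constants.pacd)
    vitreous = al - acd - 0.05
    if np.any(vitreous <= 0):
        raise ValueError("Hoffer Q: AL - ACD - 0.05 must be positive")
    out = 1336.0 / vitreous - 1.336 / (1.336 / km - (acd + 0.05) / 1000.0)
    return float(out) if np.ndim(out) == 0 else out


def hofferq_intermediates(al: float, km: float, constants: LensConstants) -> FormulaIntermediates:
    acd, m, g, alm = _hofferq_acd(al, km, constants.pacd)
    return FormulaIntermediates(
        formula=FormulaId.HOFFERQ, r=float(corneal_radius_from_k(km)),
        acd_pred=float(acd), m=float(m), g=float(g), alm=float(alm),
    )


# --------------------------------------------------------------------------
# Holladay 1
# --------------------------------------------------------------------------

def _holladay_geometry(al, km, sf):
    al = np.asarray(al, dtype=float)
    km = np.asarray(km, dtype=float)
    r = corneal_radius_from_k(km)
    rag = np.maximum(r, 7.0)
    ag = np.minimum(12.5 * al / 23.45, 13.5)
    disc = rag * rag - ag * ag / 4.0
    if np.any(disc < 0):
        raise ValueError("Holladay 1: corneal dome discriminant negative")
    acd_anat = 0.56 + rag - np.sqrt(disc)
    elp = acd_anat + sf
    alm = al + 0.2
    return r, rag, ag, acd_anat, elp, alm


def holladay1_predicted_refraction(al, km, constants: LensConstants, iol_power):
    """Holladay 1 back-calculated refraction at the spectacle plane (D)."""
    if constants.sf is None:
        raise ValueError("Holladay 1 requires a surgeon factor")
    r, *_, elp, alm = _holladay_geometry(al, km, constants.sf)
    out = _generalized_vergence_refraction(r, alm, elp, np.asarray(iol_power, float), 1.0 / 3.0)
    return float(out) if np.ndim(out) == 0 else out


def holladay1_emmetropia_power(al, km, constants: LensConstants):
    if constants.sf is None:
        raise ValueError("Holladay 1 requires a surgeon factor")
    r, *_, elp, alm = _holladay_geometry(al, km, constants.sf)
    out = _generalized_emmetropia_power(r, alm, elp, 1.0 / 3.0)
    return float(out) if np.ndim(out) == 0 else out


def holladay1_intermediates(al: float, km: float, constants: LensConstants) -> FormulaIntermediates:
    r, rag, ag, acd_anat, elp, alm = _holladay_geometry(al, km, constants.sf)
    return FormulaIntermediates(
        formula=FormulaId.HOLLADAY1, r=float(r), nc_minus_1=1.0 / 3.0, rag=float(rag),
        ag=float(ag), acd_anat=float(acd_anat), acd_est=float(elp), alm=float(alm),
    )


# --------------------------------------------------------------------------
# Combo and dispatchers
# --------------------------------------------------------------------------

def combo_predicted_refraction(al, km, constants: LensConstants, iol_power):
    """AL-switched method: Hoffer Q below 23.00 mm, SRK/T at or above."""
    if constants.a_constant is None or constants.pacd is None:
        raise ValueError("Combo requires both an A-constant and a pACD")
    al = np.asarray(al, dtype=float)
    srkt = srkt_predicted_refraction(al, km, constants, iol_power)
    hq = hofferq_predicted_refraction(al, km, constants, iol_power)
    out = np.where(al >= COMBO_AL_THRESHOLD, srkt, hq)
    return float(out) if np.ndim(out) == 0 else out


def combo_emmetropia_power(al, km, constants: LensConstants):
    if constants.a_constant is None or constants.pacd is None:
        raise ValueError("Combo requires both an A-constant and a pACD")
    al = np.asarray(al, dtype=float)
    out = np.where(
        al >= COMBO_AL_THRESHOLD,
        srkt_emmetropia_power(al, km, constants),
        hofferq_emmetropia_power(al, km, constants),
    )
    return float(out) if np.ndim(out) == 0 else out


_PREDICTORS = {
    FormulaId.SRKT: srkt_predicted_refraction,
    FormulaId.HOFFERQ: hofferq_predicted_refraction,
    FormulaId.HOLLADAY1: holladay1_predicted_refraction,
    FormulaId.COMBO: combo_predicted_refraction,
}
_EMMETROPIA = {
    FormulaId.SRKT: srkt_emmetropia_power,
    FormulaId.HOFFERQ: hofferq_emmetropia_power,
    FormulaId.HOLLADAY1: holladay1_emmetropia_power,
    FormulaId.COMBO: combo_emmetropia_power,
}
_INTERMEDIATES = {
    FormulaId.SRKT: srkt_intermediates,
    FormulaId.HOFFERQ: hofferq_intermediates,
    FormulaId.HOLLADAY1: holladay1_intermediates,
}


def predicted_refraction(formula: FormulaId, al, km, constants: LensConstants, iol_power):
    """Dispatch to one formula's back-calculated spectacle refraction."""
    return _PREDICTORS[formula](al, km, constants, iol_power)


def emmetropia_power(formula: FormulaId, al, km, constants: LensConstants):
    """IOL power giving zero predicted refraction under ``formula``."""
    return _EMMETROPIA[formula](al, km, constants)


def intermediates(formula: FormulaId, al: float, km: float, constants: LensConstants) -> FormulaIntermediates:
    if formula is FormulaId.COMBO:
        leaf = FormulaId.SRKT if al >= COMBO_AL_THRESHOLD else FormulaId.HOFFERQ
        return _INTERMEDIATES[leaf](al, km, constants)
    return _INTERMEDIATES[formula](al, km, constants)


def power_for_target_refraction(
    formula: FormulaId, al: float, km: float, constants: LensConstants, target_se: float,
    bracket=IOL_POWER_RANGE,
) -> float:
    """IOL power whose predicted refraction equals ``target_se`` (D).

    Predicted refraction is strictly decreasing in power, so a bracketed
    root search over the labelled power range is exact.
    """
    fn = _PREDICTORS[formula]

    def resid(p: float) -> float:
        return fn(al, km, constants, p) - target_se

    lo, hi = bracket
    if resid(lo) * resid(hi) > 0:
        raise ValueError(
            f"target refraction {target_se} D unreachable with powers in {bracket}"
        )
    return brentq(resid, lo, hi, xtol=1e-10)
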