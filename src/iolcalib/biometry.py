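"""Core domain types, unit conversions, and the biometer measurement-mode model.

Optical biometers report the axial length (AL) of an eye under different
display modes depending on its lens status: phakic (natural lens in place),
aphakic (no lens) and pseudophakic (intraocular lens implanted).  The modes
share the group refractive index but differ in the AL computation, which in
practice behaves like a mode-dependent additive offset on the displayed
reading.  This module models that instrument behaviour and provides the two
unit conversions every IOL power formula needs: the keratometric
radius/power relation and the vertex conversion of a refraction between the
spectacle and corneal planes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "ALOption",
    "BiometryRecord",
    "LensConstants",
    "ModeOffsets",
    "AL_RANGE",
    "KM_RANGE",
    "IOL_POWER_RANGE",
    "KERATOMETRIC_INDEX_FACTOR",
    "DEFAULT_VERTEX_MM",
    "corneal_radius_from_k",
    "k_from_corneal_radius",
    "vertex_convert",
    "display_al",
]

#: plausible axial length range (mm); out of range is an error, never a clamp
AL_RANGE = (15.0, 40.0)
#: plausible mean keratometry range (D)
KM_RANGE = (30.0, 60.0)
#: plausible IOL labelled power range (D)
IOL_POWER_RANGE = (-10.0, 40.0)
#: keratometric convention n_k = 1.3375, i.e. r [mm] = 337.5 / K [D]
KERATOMETRIC_INDEX_FACTOR = 337.5
#: conventional spectacle vertex distance (mm)
DEFAULT_VERTEX_MM = 12.0


class ALOption(Enum):
    """Axial-length display mode of the optical biometer."""

    PHAKIC = "Ph"
    APHAKIC = "Ap"
    PSEUDOPHAKIC_ACRYLATE = "Ps"

    @classmethod
    def from_label(cls, label: str) -> "ALOption":
        for opt in cls:
            if opt.value == label or opt.name == label.upper():
                return opt
        raise ValueError(f"unknown AL option {label!r}; expected one of Ph, Ap, Ps")


@dataclass(frozen=True)
class ModeOffsets:
    """Additive instrument-mode model for displayed AL readings.

    Offsets are expressed relative to the pseudophakic display.  The
    acrylate correction is the constant the biometer adds to the raw
    optical reading when the pseudophakic-acrylate mode is selected.
    """

    phakic: float = 0.11
    aphakic: float = 0.11
    pseudophakic: float = 0.0
    acrylate_correction: float = 0.1

    def relative(self, mode: ALOption) -> float:
        """Offset of ``mode`` relative to the pseudophakic display."""
        return {
            ALOption.PHAKIC: self.phakic,
            ALOption.APHAKIC: self.aphakic,
            ALOption.PSEUDOPHAKIC_ACRYLATE: self.pseudophakic,
        }[mode]


@dataclass
class LensConstants:
    """Lens constants for one IOL model.

    ``a_constant`` is the SRK-family A-constant; ``pacd`` the Hoffer Q
    personalized ACD (mm); ``sf`` the Holladay surgeon factor (mm).
    ``source`` records provenance: catalog, converted or optimized.
    """

    a_constant: Optional[float] = None
    pacd: Optional[float] = None
    sf: Optional[float] = None
    source: str = "catalog"

    def __post_init__(self) -> None:
        if self.a_constant is not None and not 110.0 <= self.a_constant <= 125.0:
            raise ValueError(f"A-constant {self.a_constant} outside [110, 125]")
        if self.pacd is not None and not 1.0 <= self.pacd <= 9.0:
            raise ValueError(f"pACD {self.pacd} outside [1, 9] mm")
        if self.sf is not None and not -2.0 <= self.sf <= 6.0:
            raise ValueError(f"surgeon factor {self.sf} outside [-2, 6] mm")
        if self.source not in ("catalog", "converted", "optimized"):
            raise ValueError(f"unknown constants source {self.source!r}")


@dataclass
class BiometryRecord:
    """Biometry of one eye before and after first-eye cataract surgery.

    Operated eyes carry the two postoperative AL re-measurements (aphakic
    and pseudophakic-acrylate options) plus the implanted IOL and, once
    refraction is stable, the postoperative spherical equivalent at the
    spectacle plane.  Fellow (unoperated) eyes carry a repeat phakic
    reading instead, serving as the repeatability control.
    """

    patient_id: str
    eye_role: str  # "operated" | "fellow"
    al_pre_phakic: float
    km_pre: float
    km_post: Optional[float] = None
    al_post_aphakic: Optional[float] = None
    al_post_pseudophakic: Optional[float] = None
    al_post_repeat: Optional[float] = None
    iol_model: Optional[str] = None
    iol_a_constant: Optional[float] = None
    iol_power: Optional[float] = None
    postop_se: Optional[float] = None
    has_stable_refraction: bool = False

    def __post_init__(self) -> None:
        if self.eye_role not in ("operated", "fellow"):
            raise ValueError(f"eye_role must be operated|fellow, got {self.eye_role!r}")
        for name in ("al_pre_phakic", "al_post_aphakic", "al_post_pseudophakic", "al_post_repeat"):
            v = getattr(self, name)
            if v is not None and not AL_RANGE[0] <= v <= AL_RANGE[1]:
                raise ValueError(f"{name}={v} mm outside plausible range {AL_RANGE}")
        for name in ("km_pre", "km_post"):
            v = getattr(self, name)
            if v is not None and not KM_RANGE[0] <= v <= KM_RANGE[1]:
                raise ValueError(f"{name}={v} D outside plausible range {KM_RANGE}")
        if self.iol_power is not None and not IOL_POWER_RANGE[0] <= self.iol_power <= IOL_POWER_RANGE[1]:
            raise ValueError(f"iol_power={self.iol_power} D outside {IOL_POWER_RANGE}")
        if self.postop_se is not None and not self.has_stable_refraction:
            raise ValueError("postop_se present but has_stable_refraction is False")

    def al_reading(self, option: ALOption) -> float:
        """The AL reading this record holds for ``option`` (errors if absent)."""
        value = {
            ALOption.PHAKIC: self.al_pre_phakic,
            ALOption.APHAKIC: self.al_post_aphakic,
            ALOption.PSEUDOPHAKIC_ACRYLATE: self.al_post_pseudophakic,
        }[option]
        if value is None:
            raise ValueError(
                f"record {self.patient_id}/{self.eye_role} has no AL reading "
                f"for option {option.value}"
            )
        return value


def corneal_radius_from_k(km):
    """Mean corneal radius of curvature (mm) from mean keratometry (D).

    Uses the keratometric convention r = 337.5 / K.
    """
    km = np.asarray(km, dtype=float)
    if np.any(km <= 0):
        raise ValueError("keratometry must be positive")
    out = KERATOMETRIC_INDEX_FACTOR / km
    return float(out) if out.ndim == 0 else out


def k_from_corneal_radius(r):
    """Inverse of :func:`corneal_radius_from_k`."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("corneal radius must be positive")
    out = KERATOMETRIC_INDEX_FACTOR / r
    return float(out) if out.ndim == 0 else out


def vertex_convert(refraction, vertex_mm: float = DEFAULT_VERTEX_MM, direction: str = "spectacle_to_cornea"):
    """Convert a refraction (D) between the spectacle and corneal planes.

    ``spectacle_to_cornea``: R / (1 - 0.001 * vertex * R);
    ``cornea_to_spectacle``: R / (1 + 0.001 * vertex * R).
    The two directions are mutual inverses.
    """
    r = np.asarray(refraction, dtype=float)
    if direction == "spectacle_to_cornea":
        den = 1.0 - 0.001 * vertex_mm * r
    elif direction == "cornea_to_spectacle":
        den = 1.0 + 0.001 * vertex_mm * r
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if np.any(np.abs(den) < 1e-12):
        raise ZeroDivisionError("vertex conversion denominator is singular")
    out = r / den
    return float(out) if out.ndim == 0 else out


def display_al(raw_optical_al, mode: ALOption, offsets: ModeOffsets = ModeOffsets()):
    """Displayed AL reading for a raw optical AL under a display mode.

    The pseudophakic-acrylate display adds the acrylate correction to the
    raw reading; the other modes add their configured offset relative to
    the pseudophakic display on top of that, so pairwise displayed
    differences equal the configured relative offsets regardless of the
    raw value.
    """
    raw = np.asarray(raw_optical_al, dtype=float)
    if np.any(raw < AL_RANGE[0]) or np.any(raw > AL_RANGE[1]):
        raise ValueError(f"raw optical AL outside plausible range {AL_RANGE}")
    shift = offsets.acrylate_correction + offsets.relative(mode) - offsets.pseudophakic
    out = raw + shift
    return float(out) if out.ndim == 0 else out
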