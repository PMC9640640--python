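"""Synthetic biometry cohorts with the structure the analysis assumes.

Each synthetic patient contributes an operated eye and a fellow control eye.
The operated eye carries a preoperative phakic AL reading, postoperative
aphakic- and pseudophakic-option re-measurements, preoperative and
postoperative keratometry, the implanted IOL power chosen by a generating
formula for a slightly myopic target, and (for a configurable fraction) a
stable postoperative spherical-equivalent refraction.  The instrument-mode
structure is additive: the pseudophakic reading is anchored to the true AL
and the phakic/aphakic readings sit a configurable systematic offset above
it plus paired measurement noise.  A constant refraction bias emulates
un-optimized catalog lens constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List

import numpy as np
from scipy import stats

from .biometry import (
    AL_RANGE,
    BiometryRecord,
    KM_RANGE,
    LensConstants,
    ModeOffsets,
)
from .formulas import (
    FormulaId,
    convert_a_constant,
    power_for_target_refraction,
    predicted_refraction,
)

__all__ = ["GeneratorParams", "generate_cohort", "regenerate_expected_summaries"]

#: truncation bounds for the true AL draw (mm), matching observed clinical range
AL_TRUNCATION = (20.3, 32.2)


def _default_constants() -> LensConstants:
    return convert_a_constant(119.30)


@dataclass
class GeneratorParams:
    """Population, instrument and noise parameters of the synthetic cohort."""

    n_patients: int = 201
    stable_refraction_fraction: float = 133.0 / 201.0
    al_mean: float = 23.59
    al_sd: float = 1.35
    km_mean: float = 43.98
    km_sd: float = 1.56
    mode_offsets: ModeOffsets = field(default_factory=ModeOffsets)
    paired_noise_sd: float = 0.07
    fellow_noise_sd: float = 0.05
    km_noise_sd_operated: float = 0.39
    km_noise_sd_fellow: float = 0.36
    true_formula: FormulaId = FormulaId.SRKT
    true_constants: LensConstants = field(default_factory=_default_constants)
    target_refraction: float = -0.25
    power_step: float = 0.5
    refraction_noise_sd: float = 0.35
    constant_bias_d: float = 0.25
    iol_model: str = "synthetic-monofocal"
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "paired_noise_sd", "fellow_noise_sd", "km_noise_sd_operated",
            "km_noise_sd_fellow", "refraction_noise_sd", "al_sd", "km_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.stable_refraction_fraction <= 1.0:
            raise ValueError("stable_refraction_fraction must lie in [0, 1]")
        if not AL_RANGE[0] <= self.al_mean <= AL_RANGE[1]:
            raise ValueError("al_mean outside plausible AL range")
        if not KM_RANGE[0] <= self.km_mean <= KM_RANGE[1]:
            raise ValueError("km_mean outside plausible Km range")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.power_step <= 0:
            raise ValueError("power_step must be positive")


def _truncated_normal(rng, mean, sd, bounds, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(params: GeneratorParams) -> List[BiometryRecord]:
    """Draw a fully reproducible cohort of operated + fellow eyes.

    The pseudophakic-option reading is the reference (true AL); the phakic
    and aphakic readings add their configured mode offsets and paired
    measurement noise.  The achieved refraction is the generating formula's
    prediction from the pseudophakic AL plus the constant bias and
    refraction noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    off = params.mode_offsets

    # one block of draws per quantity, fixed order, so the cohort is
    # byte-reproducible from the seed
    true_al_op = _truncated_normal(rng, params.al_mean, params.al_sd, AL_TRUNCATION, n)
    km_op = _truncated_normal(rng, params.km_mean, params.km_sd, KM_RANGE, n)
    true_al_fe = _truncated_normal(rng, params.al_mean, params.al_sd, AL_TRUNCATION, n)
    km_fe = _truncated_normal(rng, params.km_mean, params.km_sd, KM_RANGE, n)
    noise_ph = rng.normal(0.0, params.paired_noise_sd, n) if params.paired_noise_sd else np.zeros(n)
    noise_ap = rng.normal(0.0, params.paired_noise_sd, n) if params.paired_noise_sd else np.zeros(n)
    noise_fe = rng.normal(0.0, params.fellow_noise_sd, n) if params.fellow_noise_sd else np.zeros(n)
    km_shift_op = rng.normal(0.0, params.km_noise_sd_operated, n) if params.km_noise_sd_operated else np.zeros(n)
    km_shift_fe = rng.normal(0.0, params.km_noise_sd_fellow, n) if params.km_noise_sd_fellow else np.zeros(n)
    se_noise = rng.normal(0.0, params.refraction_noise_sd, n) if params.refraction_noise_sd else np.zeros(n)
    stable = rng.random(n) < params.stable_refraction_fraction

    al_ps = true_al_op
    al_ph = al_ps + off.phakic + noise_ph
    al_ap = al_ph + noise_ap - (off.phakic - off.aphakic)
    al_fe_pre = true_al_fe + off.phakic
    al_fe_post = al_fe_pre + noise_fe

    records: List[BiometryRecord] = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        power = power_for_target_refraction(
            params.true_formula, float(al_ph[i]), float(km_op[i]),
            params.true_constants, params.target_refraction,
        )
        power = float(np.round(power / params.power_step) * params.power_step)
        se = None
        if stable[i]:
            se = float(
                predicted_refraction(
                    params.true_formula, float(al_ps[i]), float(km_op[i]),
                    params.true_constants, power,
                )
                + params.constant_bias_d
                + se_noise[i]
            )
        records.append(
            BiometryRecord(
                patient_id=pid,
                eye_role="operated",
                al_pre_phakic=float(al_ph[i]),
                al_post_aphakic=float(al_ap[i]),
                al_post_pseudophakic=float(al_ps[i]),
                km_pre=float(km_op[i]),
                km_post=float(km_op[i] + km_shift_op[i]),
                iol_model=params.iol_model,
                iol_a_constant=params.true_constants.a_constant,
                iol_power=power,
                postop_se=se,
                has_stable_refraction=bool(stable[i]),
            )
        )
        records.append(
            BiometryRecord(
                patient_id=pid,
                eye_role="fellow",
                al_pre_phakic=float(al_fe_pre[i]),
                al_post_repeat=float(al_fe_post[i]),
                km_pre=float(km_fe[i]),
                km_post=float(km_fe[i] + km_shift_fe[i]),
            )
        )
    return records


def regenerate_expected_summaries(params: GeneratorParams) -> Dict[str, float]:
    """Population-level expectations implied by the generator parameters.

    Useful for documentation and as closed-form fixtures: the expected
    paired mode differences equal the configured relative offsets and the
    expected noise SDs equal the configured SDs.
    """
    params.validate()
    off = params.mode_offsets
    return {
        "al_mean": params.al_mean,
        "al_sd": params.al_sd,
        "km_mean": params.km_mean,
        "km_sd": params.km_sd,
        "mean_diff_ph_minus_ps": off.phakic - off.pseudophakic,
        "mean_diff_ap_minus_ph": off.aphakic - off.phakic,
        "mean_diff_fellow_repeat": 0.0,
        "sd_diff_ph_minus_ps": params.paired_noise_sd,
        "sd_diff_ap_minus_ph": params.paired_noise_sd,
        "sd_diff_fellow_repeat": params.fellow_noise_sd,
        "expected_me_bias_ps": params.constant_bias_d,
        "n_operated": float(params.n_patients),
        "n_eligible_expected": params.n_patients * params.stable_refraction_fraction,
    }
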