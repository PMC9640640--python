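import dataclasses

import numpy as np
import pytest

from _oracles import ols_normal_equations
from iolcalib import (
    ALCorrection,
    ALOption,
    FormulaId,
    GeneratorParams,
    apply_al_correction,
    convert_a_constant,
    evaluate_options,
    fit_al_correction,
    generate_cohort,
    one_sample_t,
    prediction_error,
    prediction_errors,
    summarize,
    zero_me_constant,
)

ALL_FORMULAS = [FormulaId.SRKT, FormulaId.HOFFERQ, FormulaId.HOLLADAY1, FormulaId.COMBO]
ALL_OPTIONS = [ALOption.PHAKIC, ALOption.PSEUDOPHAKIC_ACRYLATE, ALOption.APHAKIC]
PAPER_ALC = ALCorrection(intercept=-0.017, slope=0.996, r_squared=1.0)


# ---------------------------------------------------------------- prediction error

def test_prediction_error_round_trip_on_noisefree_cohort(noisefree_cohort, ulib_constants):
    """Noise-free eyes generated from SRK/T have zero PE under SRK/T + Ps AL."""
    pe = prediction_errors(
        noisefree_cohort, FormulaId.SRKT, ulib_constants, ALOption.PSEUDOPHAKIC_ACRYLATE
    )
    assert np.abs(pe).max() < 1e-9


def test_prediction_error_additive(noisefree_cohort, ulib_constants):
    rec = next(r for r in noisefree_cohort if r.has_stable_refraction)
    base = prediction_error(rec, FormulaId.SRKT, ulib_constants, ALOption.PSEUDOPHAKIC_ACRYLATE)
    shifted = dataclasses.replace(rec, postop_se=rec.postop_se + 0.25)
    assert prediction_error(
        shifted, FormulaId.SRKT, ulib_constants, ALOption.PSEUDOPHAKIC_ACRYLATE
    ) == pytest.approx(base + 0.25, abs=1e-12)


def test_prediction_error_requires_stable_refraction(noisefree_cohort, ulib_constants):
    fellow = next(r for r in noisefree_cohort if r.eye_role == "fellow")
    with pytest.raises(ValueError, match="stable"):
        prediction_error(fellow, FormulaId.SRKT, ulib_constants, ALOption.PHAKIC)


# ---------------------------------------------------------------- summaries

@pytest.mark.parametrize(
    "pe, me, medae",
    [([0.2, -0.2], 0.0, 0.2), ([0.1, 0.3, -0.4], 0.0, 0.3), ([0.0, 0.0, 0.0], 0.0, 0.0)],
)
def test_summarize_examples(pe, me, medae):
    s = summarize(pe)
    assert s.me == pytest.approx(me, abs=1e-12)
    assert s.medae == pytest.approx(medae, abs=1e-12)
    assert s.n == len(pe)


def test_summarize_rejects_single_value():
    with pytest.raises(ValueError):
        summarize([0.1])


# ---------------------------------------------------------------- zeroing

def test_zeroing_recovers_generating_constant(noisefree_cohort, ulib_constants):
    opt = zero_me_constant(
        noisefree_cohort, FormulaId.SRKT, ALOption.PSEUDOPHAKIC_ACRYLATE, ulib_constants
    )
    assert opt.a_constant == pytest.approx(119.30, abs=1e-3)


def test_zeroing_makes_me_indistinguishable_from_zero(default_cohort, ulib_constants):
    opt = zero_me_constant(
        default_cohort, FormulaId.SRKT, ALOption.PSEUDOPHAKIC_ACRYLATE, ulib_constants
    )
    pe = prediction_errors(default_cohort, FormulaId.SRKT, opt, ALOption.PSEUDOPHAKIC_ACRYLATE)
    assert one_sample_t(pe, 0.0).p_value > 0.999


def test_zeroing_moves_constant_against_hyperopic_bias(default_cohort, ulib_constants):
    """The generator's +0.25 D bias demands a larger optimized A-constant."""
    opt = zero_me_constant(
        default_cohort, FormulaId.SRKT, ALOption.PSEUDOPHAKIC_ACRYLATE, ulib_constants
    )
    assert opt.a_constant > 119.30


def test_zeroing_idempotent(default_cohort, ulib_constants):
    once = zero_me_constant(default_cohort, FormulaId.HOLLADAY1, ALOption.PHAKIC, ulib_constants)
    twice = zero_me_constant(default_cohort, FormulaId.HOLLADAY1, ALOption.PHAKIC, once)
    assert abs(twice.sf - once.sf) < 1e-6


def test_zeroing_reports_bracket_failure(default_cohort, ulib_constants):
    with pytest.raises(ValueError, match="sign"):
        zero_me_constant(
            default_cohort, FormulaId.SRKT, ALOption.PSEUDOPHAKIC_ACRYLATE, ulib_constants,
            bracket=(112.0, 113.0),
        )


@pytest.mark.parametrize("formula", ALL_FORMULAS)
def test_mean_error_monotone_in_constant(default_cohort, ulib_constants, formula):
    """Grid check: ME decreases strictly as the lens constant grows."""
    from iolcalib.calibration import _with_constant, required_constant_field

    field = required_constant_field(formula)
    start = getattr(ulib_constants, field)
    hw = 3.0 if field == "a_constant" else 1.5
    mes = []
    for c in np.linspace(start - hw, start + hw, 7):
        cs = _with_constant(formula, ulib_constants, c)
        mes.append(prediction_errors(default_cohort, formula, cs, ALOption.PHAKIC).mean())
    assert np.all(np.diff(mes) < 0)


# ---------------------------------------------------------------- AL correction

def test_fit_al_correction_identity_and_shift():
    al = np.linspace(21, 27, 25)
    corr = fit_al_correction(al, al)
    assert (corr.intercept, corr.slope, corr.r_squared) == pytest.approx((0.0, 1.0, 1.0), abs=1e-12)
    corr = fit_al_correction(al, al - 0.11)
    assert corr.intercept == pytest.approx(-0.11, abs=1e-12)
    assert corr.slope == pytest.approx(1.0, abs=1e-12)


def test_fit_al_correction_matches_normal_equations(default_cohort):
    ops = [r for r in default_cohort if r.eye_role == "operated"]
    x = [r.al_pre_phakic for r in ops]
    y = [r.al_post_pseudophakic for r in ops]
    corr = fit_al_correction(x, y)
    slope, intercept, r2 = ols_normal_equations(x, y)
    assert corr.slope == pytest.approx(slope, abs=1e-10)
    assert corr.intercept == pytest.approx(intercept, abs=1e-10)
    assert corr.r_squared == pytest.approx(r2, abs=1e-10)
    assert 0.99 <= corr.slope <= 1.00
    assert apply_al_correction(23.59, corr) == pytest.approx(23.48, abs=0.02)


def test_fit_al_correction_zero_variance_rejected():
    with pytest.raises(ValueError):
        fit_al_correction([23.0, 23.0, 23.0], [22.9, 23.0, 23.1])


def test_apply_al_correction_paper_coefficients():
    assert round(apply_al_correction(23.59, PAPER_ALC), 2) == 23.48
    assert apply_al_correction(26.00, PAPER_ALC) == pytest.approx(25.879, abs=1e-9)
    assert apply_al_correction(24.3, ALCorrection(0.0, 1.0, 1.0)) == 24.3


# ---------------------------------------------------------------- option evaluation

@pytest.fixture(scope="module")
def evaluations(default_cohort, ulib_constants):
    cmap = {f: ulib_constants for f in ALL_FORMULAS}
    return evaluate_options(default_cohort, ALL_FORMULAS, cmap, ALL_OPTIONS, optimize=True)


def test_every_optimized_me_is_zero(evaluations):
    for ev in evaluations:
        assert abs(ev.optimized.me) < 1e-4
        assert round(ev.optimized.me, 2) == 0.0


def test_phakic_me_exceeds_pseudophakic_me(evaluations):
    """Longer phakic AL readings make the PE more positive for every formula."""
    by_key = {(ev.formula, ev.al_option): ev for ev in evaluations}
    for f in ALL_FORMULAS:
        me_ph = by_key[(f, ALOption.PHAKIC)].supplied.me
        me_ps = by_key[(f, ALOption.PSEUDOPHAKIC_ACRYLATE)].supplied.me
        assert me_ph - me_ps > 0


def test_medae_stable_across_options_after_zeroing(evaluations):
    by_formula = {}
    for ev in evaluations:
        by_formula.setdefault(ev.formula, []).append(ev.optimized.medae)
    for f, medaes in by_formula.items():
        assert max(medaes) - min(medaes) < 0.05


def test_noisefree_evaluation_degenerate(noisefree_cohort, ulib_constants):
    evs = evaluate_options(
        noisefree_cohort, [FormulaId.SRKT], {FormulaId.SRKT: ulib_constants},
        [ALOption.PSEUDOPHAKIC_ACRYLATE], optimize=True,
    )
    assert evs[0].supplied.medae == pytest.approx(0.0, abs=1e-9)


def test_alc_chain_reproduces_pseudophakic_calibration(default_cohort, ulib_constants):
    """Corrected phakic ALs give the same ME as the pseudophakic option."""
    from iolcalib.formulas import predicted_refraction

    ops = [r for r in default_cohort if r.eye_role == "operated"]
    corr = fit_al_correction(
        [r.al_pre_phakic for r in ops], [r.al_post_pseudophakic for r in ops]
    )
    eligible = [r for r in ops if r.has_stable_refraction]
    km = np.array([r.km_pre for r in eligible])
    power = np.array([r.iol_power for r in eligible])
    se = np.array([r.postop_se for r in eligible])
    alc = apply_al_correction(np.array([r.al_pre_phakic for r in eligible]), corr)
    for f in ALL_FORMULAS:
        pe_corr = se - predicted_refraction(f, alc, km, ulib_constants, power)
        pe_ps = prediction_errors(default_cohort, f, ulib_constants, ALOption.PSEUDOPHAKIC_ACRYLATE)
        se_me = pe_ps.std(ddof=1) / np.sqrt(pe_ps.size)
        assert abs(pe_corr.mean() - pe_ps.mean()) < 2 * se_me
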