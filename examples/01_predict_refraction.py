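"""Predict postoperative refraction with the three vergence formulas.

For an average eye (AL 23.59 mm, Km 43.98 D) and a 21.5 D IOL with
A-constant 119.30 (pACD and surgeon factor derived by the standard
conversions), each formula back-calculates the spectacle-plane refraction
the patient should end up with.
"""

from iolcalib import FormulaId, convert_a_constant, emmetropia_power, predicted_refraction

constants = convert_a_constant(119.30)
al, km, power = 23.59, 43.98, 21.5

for formula in (FormulaId.SRKT, FormulaId.HOFFERQ, FormulaId.HOLLADAY1, FormulaId.COMBO):
    ref = predicted_refraction(formula, al, km, constants, power)
    p_emme = emmetropia_power(formula, al, km, constants)
    print(f"{formula.value:10s} predicted refraction {ref:+.3f} D, emmetropia power {p_emme:.2f} D")

# A negative refraction means the implanted power leaves the eye slightly
# myopic; the emmetropia power is the power that would land exactly at 0 D.
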