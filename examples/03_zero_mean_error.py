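"""Lens-constant optimization: zero the mean prediction error per AL option.

With un-optimized catalog constants the mean error (ME) of the refractive
prediction error is positive; zeroing it per formula and AL option yields the
optimized constants.  Using the pseudophakic AL needs the smallest constant
shift — and the corrected phakic AL behaves like the pseudophakic reading.
"""

from iolcalib import (
    ALOption,
    FormulaId,
    convert_a_constant,
    generate_cohort,
    GeneratorParams,
    prediction_errors,
    zero_me_constant,
)
from iolcalib.calibration import required_constant_field

cohort = generate_cohort(GeneratorParams(seed=1))
ulib = convert_a_constant(119.30)

for formula in (FormulaId.SRKT, FormulaId.HOFFERQ, FormulaId.HOLLADAY1, FormulaId.COMBO):
    field = required_constant_field(formula)
    for option in (ALOption.PHAKIC, ALOption.PSEUDOPHAKIC_ACRYLATE, ALOption.APHAKIC):
        me = prediction_errors(cohort, formula, ulib, option).mean()
        opt = zero_me_constant(cohort, formula, option, ulib)
        print(f"{formula.value:10s} {option.value}: ME {me:+.2f} D -> "
              f"optimized {field} {getattr(opt, field):.2f} (catalog {getattr(ulib, field):.2f})")

# Larger MEs demand larger constant shifts; the pseudophakic option's
# constants stay closest to the catalog values because that AL reading
# carries no systematic instrument offset in the generator.
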