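# Methods

## Optical model and formula implementations

All three leaf formulas are thin-lens Gaussian vergence models. A spectacle
refraction R at vertex distance V = 12 mm is propagated to the cornea
(R_c = R/(1 − 0.001·V·R)), through a corneal thin lens, translated through
aqueous of index n_a = 1.336 to the IOL plane (the formula's effective lens
position, ELP), through the IOL thin lens, and required to focus at the
formula's optical axial length. The closed forms implemented here are
algebraically equivalent to that trace; the test suite verifies the
equivalence against an independent step-by-step vergence propagation with
bisection (1,000 random inputs, agreement to 1e−6 D; observed ~1e−13 D).

Formula-specific choices:

* **SRK/T** — corneal index 1.333; long-eye AL correction polynomial above
  24.2 mm; corneal height from corneal width with the discriminant clamped
  at zero (a warning is emitted — this is the published guard for very steep
  corneas); ELP from the A-constant via ACD_const = 0.62467·A − 68.747;
  optical AL = AL + retinal thickness (0.65696 − 0.02029·AL). The published
  long-eye polynomial does not join the identity exactly at 24.2 mm; the
  jump (+0.0015 mm) is recorded by a test rather than smoothed away.
* **Hoffer Q** — personalized ACD with tangent terms whose arguments are in
  **degrees** (the most common implementation bug); AL clamped to
  [18.5, 31] mm inside the ACD model only; no additional ACD clamp (some
  third-party implementations clamp ACD to [2.5, 6.5]; not adopted). The
  closed form solves the refraction at the corneal plane and converts to the
  spectacle plane over 12 mm.
* **Holladay 1** — anatomical ACD from corneal height (radius floored at
  7 mm, corneal width capped at 13.5 mm) plus the surgeon factor; corneal
  index 4/3; optical AL = AL + 0.2 mm.
* **Combo** — dispatch on the AL reading used for the prediction: Hoffer Q
  strictly below 23.00 mm, SRK/T at or above.

Lens constants interconvert by the standard affine relations
(SF = 0.5663·A − 65.60; pACD = 0.58357·A − 63.896). Vertex distance and the
keratometric index factor (337.5) are module constants; the formulas'
internal corneal indices are separate per formula. Barrett Universal II is
out of scope (unpublished); Haigis is out of scope (requires anterior
chamber depth, which the pipeline deliberately does not model); Wang–Koch
long-eye adjustments are deliberately not applied.

## Instrument-mode model

The biometer's phakic/aphakic/pseudophakic AL computations are undisclosed;
the package models them as purely additive offsets relative to the
pseudophakic display (defaults: phakic +0.11 mm, aphakic +0.11 mm), plus the
0.1 mm acrylate correction the instrument adds to the raw optical reading in
pseudophakic-acrylate mode. Displayed mode differences are therefore
independent of the raw AL. This is an explicit simplification: the true
difference between the modes need not be additive, and the offsets are
configuration, not physics.

## Calibration chain

The prediction error of an eligible eye (operated, stable refraction) is
PE = postoperative spherical equivalent − predicted refraction, with the
preoperative keratometry always used. Mean error (ME), sample SD and median
absolute error (MedAE; mean of the central pair for even n) summarize each
formula × AL-option cell.

Constant zeroing solves ME(c) = 0 for the formula's own constant
(A-constant for SRK/T; pACD for Hoffer Q; SF for Holladay 1) by Brent's
method on a bracket of ±3 A-units (±1.5 mm for pACD/SF) around the starting
constant, with constant tolerance 1e−6 and |ME| tolerance 1e−4 D. ME is
strictly monotone (decreasing) in the constant over that bracket — verified
by a grid test — so the root is unique. For Combo a single A-constant is the
optimization variable with the Hoffer branch's pACD tied through the
conversion relations; whether a joint two-constant optimization would differ
materially is an open question, but the tied parametrization produces one
coherent optimized pair.

The AL correction is ordinary least squares of the postoperative
pseudophakic AL on the preoperative phakic AL over **all** operated eyes
(PE analyses use only eyes with stable refraction). Applying the fitted
ALc = a + b·AL to the phakic reading and re-running any formula with
unchanged constants reproduces the pseudophakic-option ME within sampling
error (tested as |ΔME| < 2·SE(ME)).

## Statistical protocol

* Normality: one-sample Kolmogorov–Smirnov against a normal with the sample
  mean and SD, exact small-sample p-value. Because the parameters are
  estimated from the same data this p-value is conservative (the Lilliefors
  effect); `ks_normality(..., lilliefors=True)` provides the corrected
  variant, and the power-against-alternatives test uses it. The default
  mirrors the nominal protocol.
* Paired and one-sample t-tests are two-sided with df = n − 1; constant
  nonzero differences (sd = 0) raise instead of returning an infinite
  statistic.
* Friedman's test uses within-row average ranks and the tie-corrected
  chi-square; fully tied data return statistic 0, p = 1. Post-hoc pairwise
  comparisons use the normal approximation of the mean-rank difference with
  Bonferroni multiplication by the number of pairs (capped at 1). The
  post-hoc scheme is a documented choice — rank-difference z rather than
  pairwise Wilcoxon — and is swappable.
* Bland–Altman limits of agreement use 1.96·SD verbatim (not a t quantile),
  the conventional practice.
* The paired-design sample size searches upward from the normal-
  approximation lower bound ceil(((z_{1−α/2} + z_{power})·σ/δ)²),
  evaluating the exact noncentral-t power at each integer n; this guarantees
  the minimal n. For δ = 0.02 D, σ = 0.08 D, α = 0.05, power 0.80 the bound
  is 126 and the minimal n is 128.

## Synthetic cohort generator

The generator emulates the study conditions: 201 patients, one operated and
one fellow eye each; true AL from a truncated normal (mean 23.59, SD
1.35 mm, truncated to the observed clinical range [20.3, 32.2] mm) and Km
from a normal (43.98 ± 1.56 D, truncated only to plausibility). The
pseudophakic reading is anchored to the true AL (the study's conclusion is
that the systematic error sits in the phakic computation); the phakic
reading adds +0.11 mm plus N(0, 0.07 mm) paired noise; the aphakic reading
adds further paired noise but no offset relative to phakic; the fellow eye's
repeat reading adds N(0, 0.05 mm). Keratometry changes by N(0, 0.39 D)
(operated) / N(0, 0.36 D) (fellow). The IOL power targets −0.25 D with the
generating formula (default SRK/T, A = 119.30) from the phakic AL, rounded
to 0.5 D steps. The achieved refraction is the generating formula's
prediction from the pseudophakic AL plus a +0.25 D constant bias (emulating
un-optimized catalog constants; chosen to reproduce the order of magnitude
of typical un-optimized MEs, 0.2–0.4 D) plus N(0, 0.35 D) refraction noise.
A stable refraction is available for a Bernoulli(133/201) fraction of
operated eyes. Target refraction, refraction noise and the bias are typical
clinical values, fully configurable; all draws derive from one seed and the
cohort (and its CSV serialization) is byte-reproducible.

What the generator does **not** emulate: cataract-density-dependent
refractive-index error (the hypothesized physical mechanism), measurement
failures, exclusion criteria, axial-length-dependent bias (the planted
offset is constant in AL, hence the fitted correction's slope is ~1 by
construction), or between-formula disagreement in the achieved refraction
(one formula generates the outcomes). Passing tests therefore demonstrate
the pipeline's correctness and internal consistency under the planted
mechanism — not clinical accuracy of any formula on real eyes.

## Problem sizes and numerics

Tests and the acceptance script run the default cohort (201 patients), a
1,000-input formula-equivalence sweep and 1,000 null t-test simulations;
the full suite completes in a few seconds on one CPU. Rounding happens only
at serialization (2 dp for diopters/mm, 3 dp for p-values). Root finding
uses `scipy.optimize.brentq` throughout (power selection xtol 1e−10;
constant zeroing xtol 1e−6). Out-of-range biometry is an error, never a
clamp, except where a published formula itself clamps (Hoffer Q AL window,
Holladay corneal-width cap, SRK/T height guard).

## Known limitations

* The additive instrument-mode model is a simplification of undisclosed
  device internals; only the relative offsets are identifiable from data.
* The Hoffer Q reference plane (corneal vs spectacle) is ambiguous in the
  literature; this implementation solves at the corneal plane and converts,
  and the choice is localized in one function.
* Fellow-eye records carry no IOL or refraction fields; pipelines that
  assume every record is operated must filter on `eye_role`.
* The exact-KS default has low power against non-normal alternatives at
  moderate n; use the Lilliefors variant when screening matters.
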