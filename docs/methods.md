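# Methods

## The binding model

`titrafit` analyses equilibrium titrations of a protein that binds up to
three ligand molecules in consecutive steps,

    P + L ⇌ PL (K_d1),  PL + L ⇌ PLL (K_d2),  PLL + L ⇌ PLLL (K_d3),

with *stepwise macroscopic* dissociation constants `K_di` (µM).  The
motivating system is the homohexameric bacterial purine nucleoside
phosphorylase, whose crystal structures show open and closed active-site
conformations distributed asymmetrically over the hexamer; in solution
this shows up as up to three distinguishable binding-site classes for
phosphate and for the inhibitor formycin A.  The partition function over
ligation states (the binding polynomial) is

    Q(L) = 1 + Σᵢ βᵢ Lⁱ,   βᵢ = Π_{j≤i} 1/K_dj,

and species fractions are its terms divided by `Q`.  Because the protein
(≈0.5–2 µM monomer in fluorimetry, up to 1.3 mM in calorimetry) is
comparable to or above `K_d1`, free ligand is never approximated by
total ligand: every evaluation solves the ligand mass balance
`L + p·BM(L)/Q(L) = l_tot` exactly.  The residual is strictly increasing
in `L` with a sign change on `[0, l_tot]`, so the solver is a vectorised
bisection on that bracket, iterated far below 1e−12 relative tolerance;
non-convergence raises with diagnostics rather than returning silently.
The exhaustive alternative — enumerating all real roots of the
degree-(n+1) polynomial form of the same balance — is kept in the test
suite as an independent oracle.

### Binding-unit basis

The schemes count one site per step on a *binding unit*.  How many
monomers make up one unit is a modelling choice (one site per dimer is
the natural bookkeeping both for the 2-site dimer model and the 3-site
hexamer-of-three-dimers model), so the conversion is an explicit,
configurable divisor (`binding_units`, default 2).  Changing it rescales
fitted responses, never the dissociation constants.

### Statistical (no-cooperativity) reference

For n identical independent sites, site counting alone fixes
`K_di = k · i/(n−i+1)`: ratios 1:4 for two sites and 1:3:9 for three.
Fitted constants that violate these ratios are the operational evidence
for non-equivalent site classes; `statistical_scheme` generates the
reference and the tests verify it against the expanded partition
function `(1 + L/k)ⁿ`.

## Observation models

* **Fluorescence / CD** — signal = offset + Σ rₛ·[species s], with molar
  response coefficients per curve.  Mixed-sign responses produce curves
  with several extrema; that shape information is what lets a single
  titration constrain three constants.
* **MST** — the labelled-protein concentration is constant, so
  normalised thermophoresis responds to species *fractions*; each
  heating-laser power carries its own response set while sharing the
  constants.
* **ITC** — per-injection heats with perfusion-displacement bookkeeping:
  a fraction `1 − v/V₀` of cell contents is retained per injection, and
  `qₙ = V₀ Σᵢ ΔHᵢ ([B_i]ₙ − fₙ[B_i]ₙ₋₁) + q_dil` with `[B_i]` the
  concentration of ligand bound at step i.  Disabling the displacement
  correction makes the heats telescope exactly to the total binding
  enthalpy — a tested identity.

An additive offset is not separately identifiable from a uniform shift
of all responses when protein is constant (the species concentrations
sum to `p_total`); fits therefore absorb the offset into the free-protein
response.

## Pre-fit corrections

Applied in a fixed order — additive before multiplicative — because the
two do not commute (a tested property):

1. **Time drift**: per-point linear slopes from repeated readings,
   accumulated as `Fₙ ± Σ_{m≤n} aₘ`.  The formula is implemented exactly
   in its additive form with a documented `sign` flag; for data whose
   slopes are recorded as raw (negative) decay rates the self-consistent
   restoring choice is `sign = −1`, pinned per dataset by the generator
   round trip.
2. **Ionic-strength quench**: the titration signal is divided by a
   NaCl-reference curve `F(I)` interpolated with a monotone piecewise
   cubic and normalised to 1 at the first titration point's ionic
   strength, so that point is correction-neutral.  Extrapolation outside
   the measured reference range is an error, never silent.  Phosphate's
   contribution to `I` uses the single-pKa Henderson–Hasselbalch
   partition (`I = c(1 + 2f₂)` plus a constant buffer background).
3. **CD spectra**: Savitzky–Golay smoothing (4th-degree, 11-point
   window — exact for polynomials up to the window order), difference
   spectra versus the apo protein, and cross-section titration curves at
   the k wavelengths of largest |change| with a minimum spacing of one
   smoothing window.
4. **MST stitching**: two concentration ranges sharing 3–4 points are
   merged by least-squares *affine* alignment (scale + offset, because
   capillary batches shift baselines), with a reported RMS mismatch.

## Global fitting

All curves of a series share the log₁₀ K_d's; each curve has its own
responses.  Because the responses enter linearly, they are profiled out
exactly at every objective evaluation (variable projection): the
optimiser only ever sees 1–3 shared nonlinear parameters.  Ordering
`K_d1 ≤ K_d2 ≤ K_d3` is enforced by an increment parameterisation,
removing label switching.  Ten seeded starts spanning the tested ligand
range guard against basin misses, with an early stop once two starts
agree; a short Nelder–Mead polish follows, because Gauss–Newton steps
crawl in the curved K_d valleys these objectives have (the polish is
what makes zero-noise recovery exact to ~1e−15 relative).  ITC residuals
are internally rescaled (heats are O(1e−7) kcal) so optimiser tolerances
act on O(1) numbers; enthalpies and per-experiment dilution heats are
projected out the same way.

Standard deviations come from the Gauss–Newton covariance at the
optimum, with Jacobian columns normalised before an eigenvalue screen so
that parameters of wildly different natural scales do not masquerade as
degeneracies; genuinely dead directions (e.g. the gauge degeneracy of an
all-flat curve) set `identifiable = False` and infinite SDs instead of a
silent answer.

## Model discrimination

The forward ladder starts from the one-site model and escalates only
when the pooled-residual Wald–Wolfowitz runs test shows significantly
*fewer* sign runs than expected (two-sided p < 0.05 with the count below
expectation) — the signature of systematic misfit.  Complex fits are
warm-started from the simpler fit (a new weakest site one decade above
the previous one), which enforces nested-SSR monotonicity.  AICc weights
(least-squares form, `n·ln(SSR/n) + 2K` with the small-sample
correction; K counts the error variance) are computed across all fitted
models as a second criterion; when the two disagree both verdicts are
reported with the ladder call as the headline.

**Runs-test conventions.**  Exact enumeration of the runs distribution
for n ≤ 20, normal approximation above.  One-sided tail probabilities
carry the continuity correction (conservative, right for directional
calls); the reported two-sided p uses the *mid-p* convention (observed
value counted half).  The distinction matters: the runs statistic is
discrete, and its atom structure puts a hard floor under how uniform any
deterministic p-value can be under the null.  At 30 residuals that floor
is ≈0.06 in Kolmogorov–Smirnov distance for mid-p (worse for every
doubled-tail variant); at the pooled-residual lengths the ladder
actually operates on (≈150–170 points for a seven-curve series) the
floor drops to ≈0.02 and mid-p is uniform to KS ≈ 0.04.  The calibration
test therefore checks uniformity at n = 150.  Exact zeros are dropped
before counting.

## Confidence intervals

3σ intervals (α = 0.0027) come from profile likelihood: the target
log₁₀ K_d is stepped on a log grid, all other parameters re-optimised
(projection makes the inner problem cheap), and the boundary is where
SSR crosses `SSR_min·(1 + F(α; 1, n−k)/(n−k))`.  A crossing outside the
tested ligand range is reported *open*, censored at the nearest tested
concentration and rendered with the `(< lo–hi)` convention — an honest
statement that the data place only a one-sided constraint.  In
well-conditioned (near-Gaussian) regimes the profile interval matches
the Wald interval `estimate ± 3·SE` within 1%, a tested identity; the
fast Wald form is what the Monte-Carlo recovery suite uses.

## Kinetics

Three initial-rate laws: Michaelis–Menten; a two-site allosteric law in
which occupancy of one site of a dimer rescales its neighbour's
constants (`K_M2 = a·K_M1`, `V_max2 = b·V_max1`); and competitive
inhibition.  The allosteric law is implemented exactly in its quoted
form, whose numerator quadratic term uses `K_M2²` while the denominator
uses `K_M1·K_M2`; the two only agree at a = 1, so an `eq2_variant`
switch provides the algebraically self-consistent alternative, and both
reduce to Michaelis–Menten with doubled V_max at a = b = 1 (tested to
1e−10).  Fits are weighted nonlinear least squares in log-parameter
space with multi-start (including a deterministic grid over the
cooperativity magnitude `a`) plus a simplex polish; nested models are
compared with the extra-sum-of-squares F test at 95% confidence.

**Identifiability of b.**  Under the default study conditions (substrate
to 50 mM, 2% relative noise, single pass) the only signature of `b` is
the high-substrate asymptote `2bV₁/a` — a ≈1σ effect at the top of the
grid.  Roughly half of seeded fits therefore collapse `b` to its zero
boundary with a genuinely lower SSR than the truth; the package flags
this through the boundary estimate rather than reporting a confident
interior value, and a triplicate design (the tested alternative)
restores recoverability.  `V_max1`, `K_M1` and `a` are well identified
throughout.

## Synthetic data: what it emulates and what it does not

Generators are seeded and bit-reproducible.  Defaults are the regimes of
the motivating study: phosphate binding at K_d = 4.4 µM / 84 µM /
1.77 mM and formycin-A calorimetry at 6.75 / 148.9 / 655 µM; seven
fluorescence response sets of mixed sign (several non-monotone curves);
MST over 3.5 nM–750 mM in two affine-offset ranges at four laser powers;
ITC series over 300–1300 µM monomer with 8–12× syringe excess and small
initial injections; near-UV CD spectra (230–300 nm, 0.25 nm step) built
from per-species Gaussian band templates.  Noise is Gaussian — relative
to curve amplitude for optical/MST signals and rates (2% default),
absolute for ITC heats (0.25 µcal default); drift slopes decay with
ligand concentration (the ligand stabilises the fluorophore); the quench
has a knee near 100 mM ionic strength.  The NaCl reference is emitted
noise-free and sampled at the titration points' ionic strengths, as the
correction protocol prescribes.

The `opposite_sign` MST fixture encodes the designed failure mode:
response sets in which the first and third binding steps move the signal
in opposite directions while the second step's responses cancel.  The
ladder then correctly — from the data's point of view — returns two
sites: a middle constant whose formation produces no signal change is
undetectable in principle, not an estimator defect.

Not emulated: instrument-level physics (shot noise, capillary
adsorption, syringe backlash, photobleaching kinetics), buffer
speciation beyond the single-pKa phosphate model, and inter-day protein
activity drift.  Passing tests therefore demonstrate correctness of the
analysis given the stated statistical structure, not robustness to every
artefact of real instruments.

## Monte-Carlo problem sizes

The recovery and discrimination suites use 100 seeds per scenario
(7 curves × 24 points each), the runs-test null 1000 draws of 150
residuals, and the F-test null 1000 datasets of 12 points; the
speciation oracle comparison uses 10⁴ random instances.  These sizes
give binomial standard errors of ≤5 percentage points on the reported
rates while keeping the full suite in the minutes range on one CPU.

## Known limitations

* Wald SDs at a parameter boundary (the `b` collapse, K_d increments at
  zero) are not trustworthy; the profile machinery and the
  `identifiable` flag are the honest alternatives.
* The ladder's runs test is applied to residuals pooled across curves;
  sign runs that straddle curve boundaries are counted as if the curves
  were contiguous.  With ≥16 points per curve the boundary effect is
  negligible.
* AICc counts all response coefficients as free parameters; for heavily
  weighted curves with near-degenerate responses this slightly penalises
  complex models.
* Per-curve σ is taken as supplied (or unit); no empirical variance
  shrinkage across curves is attempted.
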