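# Methods

## Migration model

The migration stage models an additive, initially uniform at loading
C₀ in a polymer film of thickness L, diffusing with a constant coefficient
D (Fick's second law, ∂C/∂t = D ∂²C/∂x²) into a finite, well-stirred food
phase. Assumptions: no film swelling, no concentration dependence of D, no
evaporation losses, instantaneous partition equilibrium at the film–food
interface, and a single-sided exposure with a zero-flux back face — so L
is the full film thickness (for a sheet wetted on both faces the same
solution applies with L equal to the half-thickness).

The food phase's capacity relative to the film is the dimensionless
α = V_F/(K_P/F·V_P), where K_P/F = C_P,∞/C_F,∞ is the polymer/food
partition coefficient. At equilibrium a fraction α/(1+α) of the additive
resides in the food, and the approach to equilibrium is the classical
limited-volume sorption series with eigenvalues qₙ solving tan q = −α·q.

**Direction of the α–K relation.** With K defined polymer-over-food, a
*large* K (additive prefers the polymer) must give a *small* food capacity
α; the package therefore uses α = V_F/(K·V_P) throughout. The packaged
fitted-parameter table is internally consistent with exactly this
convention: α×K is one constant (mean 249.9, CV 0.62 %) across all 45
compound × food rows. Note that this empirical constant (≈ 250) differs
from the purely geometric V_F/V_P = 15 mL / (9 cm² × 80 µm) = 208.3; the
origin of the difference is not documented in the source tables, so
consistency checks test the product-constancy property that the numbers
actually satisfy, and K values derived from a fitted α with the default
geometry will differ from the tabulated ones by the same ≈ 1.2 factor.

## Numerics

**Roots.** The n-th root of tan q = −α·q lies strictly inside
((n−½)π, nπ). The solver brackets each interval with the pole-free form
sin q + α·q·cos q (which provably changes sign there), applies Brent's
method at xtol = 1e-14, and polishes with Newton steps on tan q + α·q.
Convergence is judged on the Newton correction (the root-coordinate
error), not the raw residual |tan q + α·q|: at the root, that residual is
amplified by f′(q) = 1 + (αq)² + α, so its double-precision floor
≈ f′(q)·q·ε exceeds 1e-10 once αq is large (higher-order roots at α ≈ 10,
or any root at α ≫ 10³) even when q itself is accurate to machine
precision. Tests verify roots against an independent 1e-12 bisection
oracle and assert the 1e-10 residual bound for the leading roots, which
dominate the series.

**Series.** Truncation is adaptive: since the weights are < 1 and
qₙ ≈ nπ, retaining n* = ceil(√(ln(1/tol)/τ_min)/π) + 2 terms bounds the
first neglected term by tol (default 1e-12) at the smallest positive
dimensionless time τ = D·t/L²; a hard cap (200 terms at the user surface,
64 inside the fitter) triggers a warning if it binds. At t = 0 the series
identity Σ weights = 1 holds only in the infinite sum (the remainder
decays like 1/N for moderate α), so the solution returns 0 exactly by
convention and clamps to [0, 1]. Hours at all interfaces, seconds
internally, D always in cm²/s.

**PDE oracle.** An independent check of the series: a cell-centred
finite-volume discretisation of the dimensionless diffusion equation on
[0, 1] (nx cells, default 800), zero-flux left face, and a right face in
partition equilibrium with a well-stirred bath state b of capacity α
(α·db/dτ equals the interface flux 2(u_N − b)/h). The semi-discrete system
conserves total mass identically; it is advanced *exactly* in time by
eigendecomposition of the operator symmetrised under the mass-weighted
inner product (weights h per cell, α for the bath), so the scheme is
unconditionally stable and the only error is spatial. At nx = 800 the
series and the oracle agree to ≈ 1e-5 absolute over τ ∈ [1e-3, 10] for
α ∈ [0.05, 10], and mass is conserved to ≈ 1e-9 relative.

**Fitting.** Least squares on MR(t)% over log₁₀D (bounds [−13, −9],
initialised by a coarse 0.5-decade grid scan) with scipy's bounded
trust-region solver. Two modes: `fix_alpha_from_plateau` treats the last
observed point as the equilibrium plateau (α₀ = MR_last/(100 − MR_last))
and fits D alone — adequate only when the curve has truly plateaued;
`co_fit_alpha` (default) fits α jointly (bounds (1e-6, 10³], plateau
start). R² = 1 − SS_res/SS_tot; non-convergence is flagged, not raised,
and the best candidate returned. On noise-free 8-point curves the co-fit
recovers D and α to machine precision; under 5 % multiplicative noise with
triplicates the median relative error of D is ≈ 4 % over 100 seeded
repetitions.

## Bioaccessibility

Only the measurement arithmetic of the static digestion protocol is
modelled — no enzyme kinetics, micelle chemistry or pH staging. Digest
concentrations are corrected by subtracting the analytical batch's
procedural-blank value (the batch *mean* when several blanks exist; the
statistic is configurable), floored at zero with a flag rather than
propagating negative concentrations. BA > 100 % is retained with a
warning, since the spike is nominal and replicate noise can overshoot.
The digestion-mixture volume V_d is an explicit input defaulting to
8·V_s, the cumulative 1:1 dilution of three successive digestion phases
(oral, gastric, intestinal) applied to a V_s = 5 mL food sample; only the
product C_d·V_d enters the result, so any consistent volume bookkeeping
gives the same BA. The spike denominator uses the nominal spiked
concentration (100 ng/mL default), not a measured t₀ value.

## Exposure and risk

Defaults: packaging additive content C_p = 100 µg/g (0.1 g/kg), packaging
mass per kg food m_p = 4 g/kg, body weight 60 kg, reference doses per the
packaged registry (TPhP 70,000; EHDPP 6,000; TBOEP 15,000; TnBP 10,000;
TPPO 20,000 ng/kg bw/day). m_p = 4 g/kg is adopted as tabulated even
though the 6 dm²/L × 80 µm × 0.9 g/cm³ geometry yields 4.32 g/kg; it is
configurable. MR_f is the migration ratio at the final contact time
(72 h) by default, with the fitted equilibrium plateau as an option.
HQ < 1 is classified acceptable; the boundary HQ = 1 is not.

**Consumption table.** Per-food daily intakes are not part of the packaged
tables. For demonstration runs they are derived by inverting the EDI
identity against the packaged exposure table: anchoring the most
bioaccessible compound (TPPO) at a representative BA of 90 % fixes V per
food from its median-scenario EDI, and the remaining per-(food, compound)
BA values follow from the same identity. This is a systematic inversion
(no per-quantity adjustment); the implied BA values independently
reproduce the expected polarity ordering TPPO > TBOEP > TnBP > TPhP >
EHDPP, which supports the construction. The 95th-percentile scenario uses
a per-food multiplier on the median intake, taken from the exposure
table's own p95/median EDI ratios — these are constant *within* each food
but vary across foods (2.5 for the aqueous foods, 3.0 for
vinegar/beer/cooking wine/coconut milk, 10/3 for baijiu, 4.0 for soy
milk), so no single global multiplier is assumed.

**Known inconsistencies of the packaged exposure table** (preserved
verbatim, attached as errata metadata): the printed HQ columns are
row-permuted against the EDI columns for three food pairs
(vinegar↔soy milk, beer↔baijiu, cooking wine↔coconut milk); one soda-water
entry has an exponent typo; and the narrative ranking of foods matches the
permuted rows. Only the two fully self-consistent food blocks (Eastern
leaf, Jasmine tea) serve as quantitative anchors; worst-case per-compound
HQ maxima are computed from the EDI columns, which are unaffected by the
permutation. Implied BA values slightly above 100 % occur for three pairs
in the permuted foods and are flagged, not truncated.

## Synthetic data

The generator regenerates the study design: 5 compounds × 9 foods,
triplicate migration curves on the default grid {0.5, 1, 2, 4, 6, 24, 48,
72} h (the sampling times are configurable), and triplicate digestion
measurements. Kinetic ground truth is the packaged fitted-parameter
table; BA ground truth is either the representative per-compound levels
(90/80/65/45/20 %, following the polarity ordering, ≥ 5 points apart) or
the fixture-implied per-pair values above. Replicate noise is
multiplicative lognormal with unit mean and CV 0.05 by default — chosen as
a typical relative spread for triplicate LC-MS quantification, since the
source reports only mean ± SD — and cv = 0 reproduces the analytic model
exactly. Procedural-blank contamination is added for TPhP, TBOEP and TnBP
at a level drawn once per batch uniformly within the reported ranges
(1.13–1.47, 0.94–1.31, 1.07–1.44 ng/mL respectively), and the emitted
blank table carries the exact level added, so correction inverts it. All
generators are pure functions of (truth, configuration, seed).

What passing recovery tests on these data do **not** show: robustness to
heteroscedastic or correlated measurement error, matrix-dependent recovery
losses, drift between analytical batches, or model misspecification (real
curves need not follow a single-D Fickian law). They validate the
estimation machinery under the model's own assumptions at the study's
design size.

## Problem sizes and tolerances used in checks

Oracle comparisons use 25 log-spaced times per α over τ ∈ [1e-3, 10] and
five α values spanning [0.05, 10] at nx = 800 (< 1e-3 absolute required,
≈ 1e-5 achieved). Stochastic recovery uses 100 seeded repetitions of the
reference pair (TPhP / Eastern leaf) at 5 % CV with triplicates (median
relative D error < 15 % required) and one seeded digestion data set
(per-compound mean BA within 3 points of truth; per-pair means are not
required to meet that bound, as at 5 % CV a triplicate mean has σ ≈ 2.6
points for the most bioaccessible compounds). Large-α limit checks run at
α = 1e6 against the infinite-bath closed form.

## Limitations

- No temperature extrapolation: D and K_P/F apply at the 40 °C test
  condition only; no Arrhenius or worst-case upper-bound modelling.
- No swelling, multilayer films, or concentration-dependent transport.
- Exposure is per food, deterministic, single population (60 kg adult);
  no Monte Carlo variability, no age stratification, no aggregation
  across foods.
- The demonstration consumption table inherits the printed exposure
  rows' inconsistencies and is not a dietary-survey substitute.
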