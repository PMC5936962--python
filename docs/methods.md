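# Methods

## Model structure and assumptions

The feto-placental vasculature is idealised as a symmetric bifurcating tree
of cylindrical channels in steady laminar flow.  Generation 0 is the
umbilical artery; each channel splits into two identical daughters whose
diameter and length both scale by 2^(−1/3) (Murray's law, the optimum for
laminar flow at a symmetric bifurcation and independent of branching angle).
Consequences used throughout: the per-branch Poiseuille resistance doubles
per generation, the 2^k parallel branches of a generation combine back to
the umbilical value R(0), every generation drops the same pressure, and the
total cross-section grows by 2^(1/3) per level.

Exchange happens only in the terminal villi: convective resistance in the
capillaries and diffusion inside the conducting tree are both neglected.
Each of the 2^N terminal villi holds one capillary, modelled as a cylinder
with height equal to its diameter, so the exchange area is
A = (3π/2)·d_ft² (lateral plus both ends); the barrier separating fetal and
maternal blood has thickness δ = 0.2·d_ft.  The terminal-capillary diameter
is defined geometrically as the length deficit of the N-level tree against
the infinite tree, d_ft = L0·2^(−(N+1)/3)·τ with tail coefficient
τ = 1/(1 − 2^(−1/3)) = 4.847322…, making d_ft + L_total(N) an invariant of N
(the identity the geometry tests assert to 10⁻¹² relative).

Pulsatility, non-Newtonian rheology, asymmetric or stochastic branching,
CO₂/nutrient transport, the villous venous tree and maternal-side flow are
all outside the model.

## Resistance composition

Total oxygen-transfer resistance across α parallel cotyledons, each with β
terminal villi:

    R(N) = (1/α) [ A'·(N+1) + c·ρ_b R'_ox T ρ_ox·2^((1−2N)/3) / (β D_ox C_cap L0) ],
    A' = 128 μ_b ρ_b L0 / (π d0⁴ ΔC).

Notes on conventions the package fixes explicitly:

* **Generation count.** The tree-sum form counts N generations; the total
  expression uses N+1.  Both are available (`convention="eq13" | "eq19"`);
  the default is N+1 so that evaluation and optimisation match the total
  expression verbatim.  They differ by exactly R(0).
* **Diffusive prefactor.** c = 0.2/((3π/2)·τ).  With the rounded τ = 4.85
  this is the conventional 0.00875 (`coefficients="paper"`, default); the
  closed form gives 0.0087556 (`"exact"`).  In exact mode the folded
  expression is identical to the unsubstituted form that uses d_ft from the
  geometry — the equivalence test pins this to 10⁻⁶ relative (it holds to
  machine precision); in paper mode the rounding introduces ~0.1%.
* **Exponent placement.** The decaying factor 2^((1−2N)/3) sits in the
  numerator of the diffusive term; this is forced by substituting d_ft into
  the unsubstituted form and is the only placement under which the diffusive
  resistance decreases with depth.
* **Sign of ΔC.** The published arithmetic subtracts capillary from arterial
  content in an order that gives a negative number; the magnitude
  |C_artery − C_capillary| is used, since a negative resistance is
  unphysical.  ΔC = 0 is rejected as an error.
* **Units.** The published expression mixes a hydraulic resistance with a
  molar concentration difference; the package evaluates everything
  numerically in SI with concentrations in mol/m³ and labels results with
  the nominal unit Pa·s/m³ rather than re-deriving a dimensionally
  consistent replacement.  The audit report carries the consequences.
* **Junction losses.** Bifurcation resistance
  mdot0·(1 − 2^(−2N/3))/(758 ρ_b L0 μ_b) is computed and reported but
  excluded from totals by default: it saturates ~20 orders of magnitude
  below the channel terms.  `mdot0` is stored as the printed numeral
  (8.33×10⁻⁶ human, 8.76×10⁻⁶ mouse); the numeral equals the volumetric
  flow in m³/s despite the kg/s label it is usually given.

## Oxygen chemistry

Bound oxygen follows the Hill curve S(P) = (KP)ⁿ/(1+(KP)ⁿ) with K = 0.04
mmHg⁻¹ (half-saturation at 25 mmHg), n = 2.65 and C_max = 9.82 mol/m³;
dissolved oxygen is a fixed 3 ml O₂/l content (0.134 mol/m³, conventionally
quoted as 0.13) — no solubility-coefficient model, since none is specified
upstream.  Two compartment-concentration sources coexist:

* `"printed"` (default): the reported literals 1.647/4.244 mol/m³ bound,
  giving totals 1.777/4.374 and ΔC = 2.597 — the values the downstream
  published arithmetic uses;
* `"computed"`: direct Hill evaluation, giving 2.216/5.710 bound.

The two disagree and no single K reproduces both printed values (inverting
gives K ≈ 0.035 and 0.032 at the two pressures); the package treats the
printed values as data, the Hill evaluation as the model, and reports the
mismatch in the audit rather than resolving it.

## Optimisation and calibration

R(N) = A(N+1) + C·2^((1−2N)/3) is strictly convex in N, so it has one
continuous stationary point N* = (1 + 3·log₂((2ln2/3)·C/A))/2 and the
integer optimum (exhaustive grid search, ties toward smaller N, default grid
1..60 — wide margin around all anatomically reported generation counts) lies
within one level of N* whenever interior.  With the shipped constants
C/A ≈ 1.11 (human) and 2.94 (mouse), putting N* below the grid: the
uncalibrated model does not reproduce the published optima 18/22.
`calibrate_kappa` computes, in closed form, the factor κ on the diffusive
scale that places N* exactly at a target depth (κ ≈ 6.34×10³ human at 18,
1.52×10⁴ mouse at 22), then verifies by grid search; the round-trip holds
for every target 2..40 on both presets.  κ multiplies only the diffusive
term — scaling the convective term is the reciprocal problem and is not
duplicated.

## Parameters

All presets are transcribed from the published measurement compilation, SI
units except pressures (mmHg, converted with 1 mmHg = 133.322 Pa at use
sites).  Defaults that involved a choice:

* T = 309.15 K (oxygen properties quoted at 36 °C); R'_ox = 259.8 J/(kg·K),
  ρ_ox = 0.0468 kg/m³.
* Human L0 = 0.5 m, the midpoint of the reported 0.3–0.7 m range and the
  value the published analysis itself adopts; α = 80 cotyledons (middle of
  60–100); β = 65 terminal villi, midpoint of the stated 60–70.
* Mouse presets: α = 1 (the whole mouse placenta is comparable to one human
  cotyledon), L0 = 5.6 mm, stage-specific d0 and flow; oxygen-chemistry
  constants shared with the human preset, as the source states.
* Mouse mean velocities are stored in mm/s: the tabulated "m/s" label is an
  erratum (the surrounding text quotes the same numbers in mm/s).
* Driving pressure for the oxygen volume flow: 19 mmHg by default — the
  difference between the largest reported output (37) and input (18)
  partial pressures, and the unique round-mmHg value consistent with the
  published 25.13 ml/min human flow.  Always overridable.

The Hill exponent is stored as `n_Hill` and the cotyledon count as
`alpha_cotyledons`; the source reuses one symbol for both.

## Audit: what reproduces and what does not

The literature module stores every printed comparison value (versioned,
never recomputed).  Computed and confirmed at printed precision: the tail
coefficient 4.85; the diffusive prefactor 0.00875 (via the rounded-tail
construction); the mouse bifurcation prefactor 5.16×10⁻⁷; the totals
1.777/4.374 from the printed components; dissolved oxygen 0.13; the human
oxygen volume flow 25.13 ml/min; and the mutual consistency of the printed
totals with their printed logarithms (7.77, 10.55).  Documented as *not*
reproduced by the printed equations + parameters: the headline optima 18/22
(uncalibrated), the totals 5.95×10⁷/3.56×10¹⁰, L_tot 2.34 m/26.56 mm (~2%
off the closed forms), d_ft 300 µm/28 µm (factors ~100 and ~4.8 off), the
Reynolds numbers (the human value printed equals the mean velocity in m/s),
the human bifurcation prefactor 1.82×10⁻⁸ (implies L0 ≈ 0.15 m), and the
Hill-evaluated bound concentrations.  Each failing row carries a note on
the documented origin.

## Numerical and testing notes

Everything is closed-form; no iteration, no randomness (the acceptance
script's `--seed` is interface plumbing).  Reports round floats to six
significant digits and sort JSON keys for byte-stable regeneration.
Property tests randomise parameter sets over wide log-uniform ranges
(200 sets for landscape unimodality; 500 (A, C) pairs spanning twelve
orders of magnitude for stationary-point/grid agreement) with fixed RNG
seeds; hypothesis profiles are derandomised.  Degenerate inputs are
explicit errors: negative depths, non-positive viscosity/diameter/length,
zero ΔC, empty grids, unknown presets or units.  All checks run in seconds
on one CPU.

Because the model is parameter-driven with no external data, the test
fixtures *are* the presets; passing tests demonstrate internal consistency
of the closed forms and faithful transcription of the constants — they say
nothing about real placental morphometry beyond what the audited
literature comparisons state.
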