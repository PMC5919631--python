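# Methods

This note records the model, its assumptions, the parameter provenance, the
numerical choices and the known limitations of `exermet`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model structure

The simulated state is four-dimensional: suprabasal oxygen uptake PVO2max
(%VO2max), plasma epinephrine C_E, insulin C_I and glucagon C_G (all pM).
Arterial glucose C_a,g (mmol/l) is an *input*, supplied by a provider object,
because the multi-organ metabolic network that would predict it is outside
this package's scope.

**Oxygen kinetics.** PVO2max relaxes first-order toward the piecewise-constant
intensity input u(t) with rate 0.8 min⁻¹, so a new target intensity is
effectively reached ~5–6 min after a step (1 − e^(−0.8·5.76) ≈ 0.99). The
single-exponential description is valid below the lactate threshold; above it
a second kinetic component would be required, which is why fixtures flag
above-threshold segments and the model makes no claim there. u(t) takes the
segment's T_v on the closed interval [t_start, t_end] and 0 elsewhere; the
boundary convention is irrelevant to the integrals but fixed for
reproducibility.

**Epinephrine.** Secretion is f₁ + f₂(C_a,g) + f₃(PVO2max), scaled by BW/V_d;
f₂ is a falling sigmoid in glucose (hypoglycaemia-triggered release, inactive
near euglycaemia), f₃ a rising sigmoid in relative intensity. Elimination is
first-order with constant k *derived* — not fitted — from the requirement that
C_E stays at its basal value C_E,0 at fasting glucose (5 mmol/l) and zero
exercise. k is therefore recomputed whenever body weight or any secretion
constant changes; there is no way to leave a stale calibration behind because
no code path reads a stored k.

**Insulin/glucagon controller.** Multiplicative (relative-rate) dynamics with
cross- and self-inhibition through the gains k₁–k₄ and the bilinear
epinephrine→insulin coupling k₅ acting on the suprabasal deviation ΔC_E. The
glucose-modulation hooks φ, ψ default to the constant 1; the offset h is
derived as D/φ(5 mmol/l) with an explicit consistency check that ψ agrees
there — if φ ≠ ψ at basal glucose the two equations would not share the basal
fixed point, and the calibration raises instead of silently preferring one
equation. The multiplicative form preserves non-negativity: a hormone at zero
has zero derivative.

Consequences that the test suite verifies: the all-basal state is an exact
fixed point of the full system; k₅ = 0 decouples the pancreatic hormones from
any epinephrine forcing; f₂/f₃ are strictly monotone and bounded by their
amplitudes.

## Parameters

| constant | default | units | provenance |
|---|---|---|---|
| oxygen rate | 0.8 | min⁻¹ | published rate constant (target reached in 5–6 min) |
| V_d | 20 | L | plausible epinephrine distribution volume |
| f₁ | 10 | pmol·kg⁻¹·min⁻¹ | model default (see below) |
| c₁, c₂, c₃ | 40, 2, 3 | pmol·kg⁻¹·min⁻¹, L·mmol⁻¹, mmol·L⁻¹ | model defaults: f₂ near-silent at 5 mmol/l, strong below ~3 mmol/l |
| d₁, d₂, d₃ | 115, 0.1, 60 | pmol·kg⁻¹·min⁻¹, (%VO2max)⁻¹, %VO2max | model defaults: ~6-fold epinephrine rise at T_v = 60 |
| C_E,0 | 400 | pM | basal plasma epinephrine (~0.4 nM) |
| C_I,0 / C_G,0 | 60 / 30 | pM | basal insulin (~10 µU/ml) / glucagon (~100 pg/ml) |
| k₁, k₂, k₃, k₄ | 8e-3, 4e-3, 2e-3, 4e-3 | pM⁻¹·min⁻¹ | model defaults: stable, overdamped controller; ~40% insulin fall at T_v = 60 |
| k₅ | 3.6e-5 | pM⁻¹·min⁻¹ | published coupling estimate |
| D | 0.1 | min⁻¹ | published turnover rate |
| C_a,g* | 5 | mmol·L⁻¹ | fasting arterial glucose |
| VO2rest | 3.5 | ml·kg⁻¹·min⁻¹ | 1 MET, ACSM convention |

The secretion-sigmoid constants, V_d, f₁, the basal concentrations and k₁–k₄
are not published alongside the equations they parameterize. The values above
were chosen once for physiological plausibility (basal concentrations at
textbook resting levels; an epinephrine response and an insulin decline of
realistic magnitude at 60% VO2max; controller time constants of ~4 min so the
hormones settle within an exercise bout) and ship as the documented reference
configuration (`src/exermet/data/reference_params.json`). All estimation
tests are *self-consistent* — data are simulated from the configuration and
the coupling is re-identified from them — so their validity does not depend
on these particular values; they hold under any positive configuration.

The normative VO2max table (`src/exermet/data/vo2max_norms.csv`) is external
reference data following the standard fitness-classification convention
(gender × decadal age bracket × five ordinal categories, clamped at the age
extremes); it is not model output, its header says so, and an explicit
`vo2max_override` always takes precedence.

**Energy-equivalent work rate.** For walking/running/stepping the session's
work-rate surrogate is VO2·BW·duration·5·10⁻³·1.163, via the ~5 kcal per
litre O2 caloric equivalent. The duration factor makes the quantity
energy-like although conventionally labelled in Watt; the function implements
the conventional form exactly and its docstring flags the dimensional
oddity rather than resolving it unilaterally.

## Simulation

LSODA (stiff-capable, adaptive) with rel_tol 1e-9 / abs_tol 1e-11, restarted
at every segment boundary so the discontinuous input never straddles a solver
step. The tolerance choice is the package's accuracy contract: the integrated
oxygen state must agree with the chained analytic solution (the closed-form
oracle shipped in `exermet.oxygen`) to better than 1e-6 %VO2max on any
protocol, which one decade of margin over the observed error guarantees; the
cost is negligible for a four-state system. Initial conditions are always
basal; the output grid (default 1 min) is evaluated from the solver's dense
output and does not influence step selection, so refining it cannot change
the dynamics. Explicit `t_eval` sampling (used by the estimation module)
follows the same rule.

The toy feedback glucose provider
(dC_a,g/dt = a·(C_G/C_I − C_G,0/C_I,0) − b·PVO2max·C_a,g) is an invented
closed-loop stand-in so the glucose-dependent secretion term can be exercised
end-to-end; it is off by default and documented as not part of the published
model.

## Estimation

Weighted residuals (observed − simulated)/(cv·observed) for both hormones,
insulin block first; cv defaults to 0.04, the assumed assay coefficient of
variation. Weighting by the observed value is the measurement-CV convention;
weighting by the model prediction is available (`weight_by="predicted"`) but
off by default. Minimization is scipy's Levenberg–Marquardt (`lm`; the
bounded variant `trf` when box constraints are given), with relative
finite-difference step 1e-6 and x-scaling by the start value so the ~1e-5
magnitude of k₅ does not degrade conditioning.

Precision: CV% = 100·SDe/|e| with SDe from the inverse of JᵀJ, J the forward
finite-difference weighted Jacobian at the optimum (central differences
available as a verification mode). The ×100 convention is used because the
quantity is named a *percent* CV. A rank-deficient information matrix raises
an identifiability error naming the offending parameter instead of returning
a pseudo-inverse CV.

The estimation design mirrors the published fit's study: a 60-min bout at
T_v = 60 preceded by a 30-min baseline and followed by 120 min of recovery,
sampled every 10 min (22 time points × 2 hormones = 44 residuals). The
sampling schedule of the original study is not published; 10-min spacing is a
realistic assay cadence for such protocols. The fitting subject is a 25-year
male of 70 kg (the classical reference body weight, inside the study group's
66–85 kg range) with the study's imposed VO2max of 44 ml·kg⁻¹·min⁻¹.

## Synthetic data

`generate_observations` applies multiplicative Gaussian noise,
observed = simulated·(1 + cv·z), per point and hormone, re-drawing
non-positive values; it emulates assay error only. It does **not** emulate
inter-subject variability, diurnal or pulsatile hormone secretion,
assay-specific bias, or model misspecification — so passing recovery tests
demonstrates identifiability and correctness of the estimation machinery
under the model's own dynamics, not accuracy against real plasma data. The
six study fixtures encode published protocol *designs* (groups, ranges,
segments), not the measured data points, which are unavailable as numbers;
envelope simulations over the corner subjects reproduce the range-band
construction used to visualize group variability.

Problem sizes used by the test suite and acceptance script — 210-min
horizons, 22-point designs, 8–20 Monte-Carlo noise realizations — were chosen
as the natural scale of the protocols themselves; a full suite runs in well
under a minute.

## Known limitations

- Valid only below the lactate threshold; the final stage of the incremental
  fixture is above it and flagged, with no accuracy claim.
- Arterial glucose is exogenous; closed-loop glucose predictions require the
  out-of-scope metabolic core (the toy provider is qualitative plumbing).
- Cortisol and growth hormone, the slower counter-regulatory hormones, are
  not modelled.
- The unpublished constants make absolute hormone magnitudes
  configuration-dependent; only the published constants (0.8 min⁻¹, D = 0.1,
  k₅ = 3.6·10⁻⁵ pM⁻¹·min⁻¹) and the derived-calibration structure are fixed
  by the source model.
- Heart-rate-based intensity anchors and field estimation of VO2max are out
  of scope; intensity personalization is %VO2max only.
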