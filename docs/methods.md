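# Methods

## The cost model and its assumptions

The model treats a cancer patient as a two-compartment energy system, host
plus tumor, and prices the tumor in kcal/day through ATP bookkeeping. Three
stoichiometric constants drive everything: 30 ATP per glucose fully
oxidized (the modern respiratory-chain estimate, not the textbook 38),
2 net ATP per glucose glycolysed to lactate, and 6 ATP per glucose of
lactate reconverted by liver and kidney (Cori cycle). Because the Cori bill
is three times the glycolytic yield, a tumor making a fraction
`X_anaerobic` of its ATP anaerobically costs the host

    P_cost = K_cancer · M_cancer · (1 + 2·X_anaerobic),

a multiplier running from 1 (fully oxidative) to 3 (fully glycolytic). The
model assumes: steady state (no tumor growth term in the energy ledger);
all tumor lactate is recycled rather than excreted or oxidized elsewhere;
glucose is the only substrate whose recycling is priced (glutamine-derived
lactate is not separately tracked); and immune activation, acute-phase
response and altered food intake are deliberately excluded from `P_cost`.

Indirect calorimetry cannot see the split: it reports
`REE_IC = P_normal + P_aerobic + P_Cori`, because both the tumor's aerobic
burn and the host's reconversion work consume oxygen. `P_normal` comes from
Kleiber allometry (`69.6·M^0.75` kcal/day) or the Cunningham fat-free-mass
equation (`370 + 21.6·FFM`). The Kleiber coefficient appears in the
source literature as both 69.6 and 69.9; this package standardizes on 69.6
and treats 69.9 as a variant — the headline "32 % of reference-man BMR"
statistic survives either choice, which the reproduction report verifies.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `K_cancer` | kcal/kg tumor/day | 200 | REE-cohort estimate; comparable to liver (200) |
| `X_anaerobic` | fraction | 0.25 | base case consistent with in-vitro colon-line and in-situ tracer estimates |
| `M_cancer` | kg | 0–3 grid | clinically plausible burden range; retrospective sample mean 0.83 kg |
| ATP yields | per glucose | 30 / 2 / 6 | see above; all three overridable via `EnergyConstants` |
| glucose energy | kcal/mol | 686 | combustion enthalpy used to price lost glucose |
| reference mass | kg | 70 | reference man; the oxygen-slope study is bracketed at 60 and 70 |

Overriding any constant propagates consistently; the `reproduce` command
flags exactly the downstream headline numbers a perturbation moves.

## Glucose-fate statistics

A glucose entering the blood is captured by the tumor with probability
`p_cancer = (t_cancer − t_control)/t_cancer` (excess turnover) and, if
captured, recycled with probability
`p_anaerobic = (C_cancer − C_control)/(t_cancer − t_control)` (excess Cori
cycling). The expected host payout per glucose is the fixed point of

    g = (1 − p_c)·30 + p_c·p_a·(g − 6) + p_c·(1 − p_a)·0,

i.e. `g = [30(1 − p_c) − 6·p_c·p_a]/(1 − p_c·p_a)`, and
`p_lost = (30 − g)/30`. Two modelling choices are worth making explicit:

- **The tumor's own 2 glycolytic ATP never enter the host ledger.** A
  one-pass (non-recycling) expectation does not reproduce the published
  loss percentages (23/12/21 %); the recycling fixed point does, and is
  additionally validated against a direct Monte-Carlo chain simulation
  (10⁶ glucose fates per lattice point, agreement within 3 σ).
- **`p_lost` is not clipped.** Near `p_c·p_a → 1` the recycling chain
  diverges and the payout goes negative (`p_lost > 1`); surfaces encode
  such cells as NaN/empty, and any clipping is display-only.

A property worth knowing because it is counter-intuitive: `p_lost` is
strictly increasing in `p_cancer` but **not** in `p_anaerobic`. At fixed
capture below `p_cancer = 4/5`, a more anaerobic tumor loses the host
*less* energy — recycling returns glucose that an oxidative tumor would
have destroyed at 30 ATP, for a 6-ATP fee. Only above `p_cancer = 4/5`
does the compounding Cori cost dominate (`∂g/∂p_a ∝ p_c(24 − 30·p_c)`).
The test suite asserts this sign structure rather than a blanket
monotonicity.

The glucose-fraction ↔ ATP-fraction conversion is
`X = 2p/(2p + 30(1 − p))` with exact inverse `p = 15X/(1 + 14X)`; the
round trip is stable to 1e-12 across [0, 1].

`glucose_cost` prices a measured excess turnover Δ (g/kg/day) as
`(Δ·mass/180 mol) · 686 kcal/mol · [(1 − p_a) + p_a·6/30]`: oxidized
glucose is lost at full combustion energy, recycled glucose costs the
6/30 Cori fraction. The exact constants behind the published per-study
costs (200/94/240 kcal/day, mean 180) are not published; under this
package's defaults the three studies compute to 180/86/220 kcal/day
(mean 162), each within 10 % of its published value — agreement is
claimed only at the 20 % level, and these are deliberately tolerance
checks, not exact targets. The related published figures of
220–260 kcal/kg tumor/day for the glucose-only specific cost of the
oxygen-consumption cohort (55 % of its `K_cost`) rest on the same
unavailable derivation and are documented here without being computed.

## Cohort estimation of K_cost

`fit_kcost_regression` is OLS of `REE/FFM` on `burden/FFM` — the ratio
regression exactly as published, with FFM dividing both sides rather than
entering as a covariate. This choice is faithful but statistically
debatable, and the package quantifies one consequence: the baseline share
`370/FFM` correlates with `burden/FFM`, so even a *noise-free* cohort with
heterogeneous FFM returns a slope biased away from the generating value
(the test suite pins this down; an exact round trip requires fixed FFM).
Under the study-like noise level the bias is small relative to the slope's
standard error and 95 % CI coverage is nominal (0.95 ± 0.03 over 1000
synthetic cohorts). The slope's p-value is a two-sided t-test with n − 2
df; no multiple-testing machinery, as there is a single hypothesis.

The oxygen-consumption route multiplies the published per-kg-patient
oxidative slope (6.67 kcal/kg tumor/day/kg patient) by an assumed patient
mass, evaluated at the two-point bracket 60/70 kg — giving 400–470, and
270–310 after dividing out the 1.5 multiplier.

## Synthetic data: what it emulates, and what it does not

`generate_ree_cohort` draws FFM uniform on 40–70 kg, tumor burden
lognormal moment-matched to mean 0.83 kg / sd 1.06 kg (reproducing the
heavy right tail — a ~4.7 kg draw appears at roughly the published rate in
n = 30 samples), and REE = baseline + `K_cost`·burden + FFM·N(0, σ) with
σ = 8.5 kcal/kg FFM/day. Noise enters on the per-kg-FFM scale so the ratio
regression is homoscedastic and classical OLS inference is exact; σ was
set so an n = 18 cohort with true slope 300 reproduces the published fit
quality (slope SE ≈ 110, r² ≈ 0.3). Draws that would make REE non-positive
(several σ below baseline, probability ~3×10⁻⁴ per patient) are redrawn —
a truncation far too rare to affect coverage. `generate_turnover_study`
inverts the capture/recycling estimators at chosen true fractions, so the
zero-noise round trip is exact by construction; the control Cori rate
defaults to 0.1·t_control and cancels exactly in the estimator.

What the generators do **not** emulate: correlation between tumor burden
and FFM (real cachexia wastes FFM as burden grows), measurement error in
CT-derived burden, organ-mass covariates behind REE, or longitudinal
trajectories. Passing recovery tests therefore shows the estimators are
correct under the stated sampling model, not that the published cohort
numbers are robust to those real-world features. Per-quantity named RNG
substreams (`SeedSequence.spawn`) keep every generated field stable when
new fields are added.

## Numerical choices

- Reported values are rounded only at reporting boundaries: two
  significant figures for rates (half away from zero; 466.9 → 470),
  nearest integer for percentages (half away from zero). Internal
  computation is never rounded.
- Standard errors of cost components propagate as exact scalar multiples
  of the driving SE (each component *is* a scalar multiple of the observed
  cost), not in quadrature: se(K_cancer) = se(K_cost)/(1 + 2X).
- Decomposition identities are enforced to 1e-9 relative by
  `CostBreakdown.validate`; degenerate inputs (zero mass, X = 0 or 1) are
  ordinary points of the formulas, not special cases.
- The Monte-Carlo payout oracle simulates the capture/recycle chain
  step-by-step with boolean masks (no closed-form shortcuts), seeded via
  `numpy.random.default_rng`.
- Surfaces: the cost map is evaluated on 0–3 kg × 0–1 grids (31 × 21 in
  the shipped driver); the energy-lost map on 0–0.5 × 0–0.5 (26 × 26),
  the region containing the three tracer studies.

## Problem sizes

The shipped test and analysis configuration uses: 10⁶ Monte-Carlo glucose
fates per lattice point on a 20-point (p_c, p_a) lattice; 1000 synthetic
cohorts (n = 18 each) for CI-coverage estimation; 10⁴ random parameter
draws for the algebraic-identity sweeps; 10⁵ draws for lognormal moment
checks. These sizes give Monte-Carlo standard errors an order of magnitude
below every tolerance tested.

## Known limitations

- `K_cancer` and `X_anaerobic` are weakly identified in vivo; the model
  propagates assumed values, it does not estimate them from imaging.
- The glucose-only cost underestimates total cost (glutamine and fatty
  acids are unpriced), and the published comparison values for it are
  reproducible only to ~10–20 % (constants unavailable, see above).
- The ratio-regression design is inherited, bias and all, for fidelity to
  the source method; a covariate-adjusted regression would be the modern
  choice and is deliberately out of scope.
- No dynamic simulation of weight loss, lipolysis or proteolysis: the
  model prices the tumor at an instant, it does not forecast cachexia.
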