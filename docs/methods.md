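# Methods

## Scope and model structure

`mfpbpk` predicts maternal plasma and fetal (umbilical cord) buprenorphine
concentrations between 15 and 40 weeks of gestation for sublingual dosing.
The dyad is a linear compartmental system of drug amounts (mg):

- a **transmucosal depot** emptying first-order (ka, default 2.0 h⁻¹)
  directly into maternal systemic plasma — transmucosally absorbed drug
  bypasses first pass;
- a **gut depot** for the swallowed remainder, emptying first-order
  (ka, default 0.6 h⁻¹) into the liver compartment; a fraction
  `1 − Fa·Fg` is lost to incomplete absorption and gut-wall metabolism
  (defaults Fa = 0.9, Fg = 0.6 nonpregnant; gut-wall extraction scales with
  the intestinal CYP3A4 induction multiplier);
- **perfusion-limited maternal tissues** (the thirteen-organ roster of the
  published Rodgers & Rowland composition table plus, when pregnant, the
  placenta), each exchanging with plasma at its plasma flow `Q_t` via
  `Q_t (C_p − C_t/Kp_t)`;
- **hepatic elimination** by the well-stirred model: intrinsic unbound
  clearance acts on the liver-venous unbound concentration
  `fu · C_liver / Kp_liver`, assembled as
  `CLu_int · Σ fraction_enzyme · induction_enzyme(GA)`;
- **renal clearance** on maternal plasma (small for this drug);
- **bidirectional placental diffusion** between maternal and fetal plasma
  water at the whole-organ clearance `CL_PD,total`, acting on unbound
  concentrations (`fu_m C_m` vs `fu_f C_f`);
- a **fetal plasma** compartment and one lumped, perfusion-limited fetal
  tissue; fetal intrinsic clearance defaults to zero (transfer is
  passive-diffusion dominated and fetal metabolism immature), configurable.

Enterohepatic recirculation is deliberately excluded; this is a known cause
of underpredicting maternal concentrations 12–24 h after a dose, when
recirculation peaks appear in observed data. Metabolites
(norbuprenorphine) are out of scope.

## Sublingual absorption

Salivary recovery of buprenorphine — the share of a sublingual dose washed
into saliva rather than absorbed — is linear in salivary pH:
`recovered(%) = α + β·pH`. The shipped model is the two-point interpolant
through (pH 7.01, 54.5%) and (pH 6.34, 65.7%), the mean salivary pH of
nonpregnant and pregnant women: α = 171.68, β = −16.716 %/pH. Absorbed
percentages are the complements (45.5% and 34.3%), giving the pregnancy
factor 34.3/45.5 = **0.754** applied multiplicatively to the absorbed
fraction for any pregnant simulation; postpartum women revert to the
nonpregnant model because salivary pH normalizes quickly after delivery.
The factor is derived from 2 mg solution data and applied to both
formulations and all doses — an explicit model assumption.

The dose dependence is `absorbed(%) = intercept + slope·log₁₀(dose in mg)`:
tablet 38.1 − 19.7·log₁₀(D), solution 53.3 − 25.6·log₁₀(D). The base-10
convention is fixed by the solution model reproducing 45.6% at 2 mg, in
agreement with the salivary-line estimate of 45.5%. Absorbed fractions are
clamped to [0.001, 0.999], mirroring the post hoc individualization range,
so extreme doses never produce negative absorption.

## Tissue partitioning

Kp values come from the Rodgers & Rowland equations for a moderate-to-strong
base: water distribution with intracellular ion trapping
(`(1 + 10^(pKa−pH_iw)) / (1 + 10^(pKa−pH_p))`), neutral-lipid/phospholipid
partitioning of the neutral species (`P·f_NL + (0.3P + 0.7)·f_NP`), and
electrostatic binding of the cation to acidic phospholipids with an
association constant back-calculated from blood-cell partitioning
(blood:plasma ratio, hematocrit 0.45, erythrocyte pH 7.22). Buprenorphine is
treated as a monoprotic base: the phenol (pKa 9.62) leaves under 1.5%
anionic at pH 7.4.

Two deliberate parameter choices:

- **log P = 3.8.** Published estimates span 3.8–5.0. At log P ≈ 5 the
  neutral-lipid term alone over-explains blood-cell uptake at a
  blood:plasma ratio of 1 and drives the back-calculated
  acidic-phospholipid affinity negative, which is unphysical; 3.8 yields a
  positive, stable affinity.
- **Kp scalar solved, not fixed.** A uniform scalar multiplies all predicted
  Kp values so that `Vss = V_plasma + Σ Kp_t·V_t` equals the nonpregnant
  reference of **6.23 L/kg**. The scalar's numerical value depends on the
  composition and volume tables; with the shipped public tables it is
  ≈ 0.57. The literature value 0.26819 (obtained with a proprietary
  composition table) is kept as a documented reference constant
  (`REFERENCE_KP_SCALAR`); the testable contract is the round-trip — solving
  the scalar and re-applying it reproduces 6.23 L/kg to 1e-6. Fetal Kp uses
  the same method and the same scalar on a single lumped fetal tissue with
  higher water and lower lipid content than adult tissue.

## Gestational physiology

Placental geometry (GA in weeks):

- `PVSA(m²) = 0.135·GA − 0.023·GA² + 0.0015·GA³ − 0.00002·GA⁴`
- `V_placenta(mL) = 1.0·GA + 0.51·GA² − 0.0028·GA³`

The quartic PVSA coefficient is −2·10⁻⁵. The frequently quoted −2·10⁻⁴
drives the surface area to −447 m² at term, whereas −2·10⁻⁵ gives 13.4 m²
and reproduces the term diffusion clearance of 0.1166 L/h/mL placenta
exactly, so the larger magnitude is treated as a misprint (a log notice is
emitted once per run).

Transplacental permeability is predicted from polar surface area and
hydrogen-bond donor count, `Peff(10⁻⁴ cm/s) = 10^(1.454 − 0.011·PSA −
0.278·HBD)` — a correlation originally fitted to intestinal permeability and
commonly transferred to the placenta for passively diffusing drugs. For
buprenorphine (PSA 62.2 Å², HBD 2): Peff = 1.636·10⁻⁴ cm/s. Diffusion
clearance is `CL_PD = Peff · 3.6 · PVSA / V_placenta` L/h/mL placenta, the
3.6 converting (10⁻⁴ cm/s)·m² to L/h. Values: 0.0441 (GA 15), 0.0989
(GA 27), 0.1166 (GA 40) L/h/mL; whole-organ CL_PD rises strictly from 5.3 to
78.9 L/h. Note that the **per-mL** clearance peaks near week 37 and declines
about 2% by term, because the surface-area polynomial flattens faster than
placental volume grows — the monotone quantity over all of [15, 40] is the
whole-organ clearance, which is what couples the circulations.

**Enzyme induction** is a set of piecewise-linear fold-change trajectories
starting at 1.0 at GA 0. Defaults: hepatic CYP3A4 rising to 1.6× at term
(CYP3A substrate clearance increases of 50–100% are reported in pregnancy)
and hepatic UGT1A1 to 1.5× (clearances of the UGT2B7 substrates morphine and
zidovudine rise ≈1.5-fold). Hepatic CYP2C8 and intestinal CYP3A4 copy
hepatic CYP3A4, and hepatic UGT2B7 copies UGT1A1 — enforced structurally, so
an aliased enzyme cannot carry its own trajectory. Exact induction
magnitudes are not well established; both trajectories are configuration.

**Fetal fraction unbound** is derived from binding-protein ontogeny: fetal
plasma binding proteins (notably α1-acid glycoprotein) rise roughly linearly
across gestation to about one third of the maternal concentration at term.
With equal binding affinity, `fu_f = 1 / (1 + (1−fu_m)/fu_m · r(GA))`,
`r(GA) = 0.34·GA/40`. This is the mechanism that makes *total* cord
concentration rise across gestation while *unbound* concentrations
equilibrate across the placenta: simulated fetal steady-state AUC increases
monotonically over GA 15 → 27 → 40 at a fixed maternal regimen, and the
term cord:maternal concentration ratio is ≈ 0.4, inside the 0.3–0.5 range
reported in delivery samples. A fixed `fu_fetal` can be configured instead.

Maternal non-placental physiology (70-kg reference; tissue volumes, flows as
fractions of a 336 L/h cardiac output, 3 L plasma) is held flat over
gestation by default: it is an interface (configurable tables), not
hard-coded science. Fetal weight follows a log-quadratic growth standard
(≈ 0.12 kg at 15 weeks, 3.6 kg at term); fetal plasma and tissue volumes and
fetal tissue perfusion scale with fetal weight; placental plasma flow scales
with placental volume (0.06 L/h/mL, ≈ 41 L/h at term).

## Numerics

Between dose events the system is linear and time-invariant, so the state is
propagated with matrix exponentials (`expm(A·Δt)`, cached per step size)
rather than an adaptive ODE solver: the solution is exact to machine
precision, deterministic across runs and platforms, and fast enough that a
14-day twice-daily simulation takes ~30 ms. The rate matrix has non-negative
off-diagonal entries, so the propagator preserves non-negativity; a
cumulative "eliminated" state is defined as the negative column sum of the
rest, making every column sum exactly zero and holding the mass balance
`dosed = Σ compartments + eliminated` to ~10⁻¹⁴ relative at all times
(the tested requirement is 10⁻⁶). Output grids default to 0.1 h;
concentrations are ng/mL (amount mg / volume L × 1000). AUC uses the
trapezoid rule on the output grid; Cmax/Tmax are grid extrema; CL/F is
dose/AUC over a steady-state interval.

## Virtual trials and post hoc individualization

Virtual dyads copy a template (age, gestational age, regimen) and draw a
mean-1 lognormal dose multiplier with CV 33.9% (σ² = ln(1 + CV²), truncated
at ±3 SD on the log scale to keep doses positive), representing
bioavailability variability. The dose-dependent absorbed fraction is
evaluated at the nominal dose; the multiplier scales the administered
amounts. Summaries pool all subjects across trials: per-time geometric mean
and 5th/95th percentiles, plus geometric-mean PK metrics over the last
dosing interval.

Post hoc individualization minimizes `|log C_pred(t_obs; f) − log C_obs|`
over the transmucosal fraction f ∈ [0.001, 0.999] with a bounded scalar
(Brent) search, tolerance 10⁻⁴. Because the disposition matrix does not
depend on the dose split, `C_pred` is affine in f; the two basis simulations
(f = 0 and f = 1) are computed once, making each objective evaluation free
and the optimum effectively exact. Observations outside the attainable range
pin the estimate to a bound and set `hit_bound`. Multi-point observations
would use the summed log-error (single points are the designed use case:
one maternal sample at delivery).

**Estimator information limit.** With one observation and multiplicative
noise `e^ε`, exact inversion of the affine prediction gives
`f̂ − f = (f + s)·(e^ε − 1)` where `s ≈ 0.16` is the swallowed-route share
of the predicted concentration. At 15% noise (σ = 0.149) and
f ~ U[0.1, 0.9], the median absolute error is therefore ≈ 0.06 — measured
0.057 at the default seed — and no estimator can beat it from a single
point without a prior. The companion checks are comfortably met: recovered
fractions show no systematic bias (sign test), the fetal fold-differences
are ≥ 90% within 2-fold (measured 100%), and their geometric mean ratio is
within 0.9–1.1 (measured 0.99).

Fold-difference statistics: GMR = exp(mean log(pred/obs)); 95% CI from the
t-distribution on log ratios (consistent with the Shapiro–Wilk normality
check, which is reported but never gating); fold-range boundaries are
inclusive ([1/2, 2] and [1/1.25, 1.25]) so boundary cases are deterministic.

## Synthetic data

The generator emulates a delivery study: doses log-uniform over 1–28 mg/day
(sublingual tablets, daily dosing), gestational ages uniform over 36–40
weeks, 14 days of dosing to pseudo-steady state, one maternal and one fetal
sample at a uniform random time within 24 h of the last dose, lognormal
observation noise (default 15% CV). Generating ("true") absorbed fractions
are drawn U[0.1, 0.9] and written to a separate ground-truth table that the
estimation path never reads.

What a green synthetic test establishes: the individualization and
verification machinery is self-consistent — parameters generated by the
model are recovered from noisy observations, and fetal predictions match
within the noise budget. What it does not establish: agreement with real
delivery datasets, which would require the clinical observations and a
validated population physiology; real data add model misspecification
(enterohepatic recirculation, absorption-site variability, delivery
hemodynamics) absent from the synthetic world.

## Default parameter summary

| Parameter | Default | Units | Provenance |
|---|---|---|---|
| pKa (amine / phenol) | 8.31 / 9.62 | — | measured |
| PSA / HBD | 62.2 / 2 | Å² / count | compound databases |
| log P | 3.8 | — | lower bound of published range (see above) |
| fu plasma / blood:plasma | 0.04 / 1.0 | — | literature (flagged: secondary sources) |
| hepatic CLu,int | 5100 | L/h | calibrated to ≈57 L/h well-stirred hepatic clearance |
| enzyme fractions | 3A4 .45, 2C8 .25, UGT1A1 .10, UGT2B7 .20 | — | metabolism literature |
| renal CL | 0.2 | L/h | negligible renal excretion |
| ka transmucosal / oral | 2.0 / 0.6 | 1/h | inherited model values, configurable |
| Fa / Fg (swallowed) | 0.9 / 0.6 | — | ≈14% net oral bioavailability |
| dose CV | 33.9 | % | bioavailability variability |
| pregnancy factor | 0.754 | — | salivary-pH line |
| target Vss | 6.23 | L/kg | nonpregnant reference model |
| fetal protein ratio at term | 0.34 | — | fetal AAG ontogeny |
| fetal CLu | 0 | L/h | passive-transfer-dominated |

## Known limitations

- Maternal non-placental physiology is flat over gestation by default;
  pregnancy enters only through absorption, induction, placental geometry
  and the fetal compartments.
- No enterohepatic recirculation: late-interval maternal concentrations are
  systematically underpredicted relative to drugs that recirculate.
- No metabolites; cord concentration is reported as fetal plasma without
  further anatomical resolution.
- The Kp scalar, and hence absolute tissue concentrations, are calibration
  artifacts; only plasma-side predictions are interpretable.
- Valid gestational-age range is 15–40 weeks; construction of geometry
  values is allowed down to GA → 0 for the polynomials only.
- The per-mL placental diffusion clearance is non-monotone near term (peak
  ≈ week 37) as a property of the geometry polynomials themselves.
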