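# Methods

## Model structure and assumptions

The disposition model is a nine-state whole-body PBPK system in amount
units (µmol). Blood is a single well-mixed compartment receiving all
venous returns. Adipose, muscle and skin are flow-limited with
tissue:blood partition coefficients `Kp = (0.1, 0.2, 0.5) × Kp_scaling`.
The liver is permeability-limited: the hepatic blood flow traverses the
extracellular (sinusoidal + interstitial) space `Vhe`; entry into the
hepatocellular space combines saturable active uptake and symmetric
passive diffusion, and metabolism is Michaelis–Menten inside the cell.
The target is a 5 mL organ with the same extracellular/intracellular
structure, its own uptake, diffusion and metabolism parameters, and the
receptor pool. The source model this study family builds on is not
published as explicit equations, so the rate laws here are the package's
own design, chosen to be the standard extended-clearance forms
consistent with the compartment diagram and the parameter set:

- flow-limited tissue: `dAi/dt = Qi (Cb − Ci/Kpi)`
- liver EC: `dAec/dt = Qh (Cb − Cec) − (Vmax,up·Cu/(Km,up+Cu) + PS·Cu) + PS·Cic`
  with `Cu = fub·Cec`
- liver IC: uptake − efflux − `Vmax,met·Cic/(Km,met+Cic)`
- target: same with its parameters; binding
  `dRC/dt = kon·Cic(Rtot − RC) − koff·RC`, `kon = koff/Kd`
- blood: venous returns − arterial outflows − `CLr·Cb` (renal clearance
  acts on total blood concentration)

Binding-site assumptions: the unbound fraction `fub` (plasma = blood)
applies in blood and every extracellular space; the intracellular
unbound fraction is 1 (no intracellular binding proteins are modelled).
The receptor sits in the target **intracellular** space by default —
consistent with modelling active target uptake and intracellular target
metabolism — and `receptor_site="extracellular"` switches it to binding
the unbound extracellular concentration instead. Saturable target
uptake draws on the extracellular unbound concentration.

There is no rest-of-body compartment (only the five tissues are
parameterised) and no oral absorption. All subjects weigh 75 kg; blood
volume uses the 79 mL/kg reference-human convention (5.925 L), since
the physiological table the study fixes omits it.

## Trial procedure

The estimated therapeutic dose is the minimal single IV bolus whose
average receptor occupancy over the 24 h after the dose reaches the
required level (default 60%). Evaluating a single dose rather than
steady state of once-daily dosing is a deliberate simplification: it
makes the therapeutic dose a well-defined scalar per compound and is
conservative for low-clearance compounds (their steady-state exposure
would only be higher). The microdose is `min(dose/100, 100 µg)`
(0.25 µmol at the fixed molar mass of 400 g/mol), administered at t=0
as a bolus into the target extracellular (interstitial) space. Success
means the 24-h average occupancy after the intra-target bolus reaches
the same required level.

Dose search: a 13-point log-spaced grid from 1e-4 to 1e5 µmol brackets
the criterion (covering sub-µg to multi-gram doses), then bisection in
log-dose converges to 1% relative tolerance; average occupancy is
empirically monotone in dose (a tested property), which the bisection
relies on. If 1e5 µmol fails, the dose is recorded as unachievable. If
the lowest bound already passes, it is returned as the minimal dose of
the search domain.

Compounds whose solver run fails or whose therapeutic dose is
unachievable are excluded from every success-probability denominator
and counted separately (at the default configuration roughly 4% of
compounds are unachievable — typically very weak binders or receptor
pools far above any deliverable amount — and solver failures are
rare, <0.2%).

## Virtual compound generation

Thirteen kinetic/binding parameters are sampled independently from
log-normal laws specified by interquartile ranges `[q25, q75]`
(`median = sqrt(q25·q75)`, `sigma_log = ln(q75/median)/0.67449`).
Protein binding, renal clearance and distribution volume come from a
trivariate log-normal: the protein-binding ratio `B = nPt/Kd,protein`
gives `fub = 1/(1+B)`, and `Vss` sets
`Kp_scaling = max((Vss − Vb)/(0.1·Va + 0.2·Vm + 0.5·Vs), 0.01)` (the
floor keeps partition coefficients physical when `Vss < Vb`). The
published correlation structure behind that joint law is not available,
so the default configuration is an approximate stand-in — B median 1
and sigma_log 1.5 (fub median 0.5), CLr median 3 L/h sigma_log 1.5,
Vss median 50 L sigma_log 1.0, zero log-correlations — and every piece
of it is overridable in YAML. Target-organ uptake/metabolism draws are
independent of the hepatic draws: their printed ranges already encode
the "1/5 of liver, size-normalised" scaling.

Every parameter draws from its own named RNG substream (seeded by the
study seed plus a CRC of the parameter name), so extending the
configuration never perturbs existing draws, and populations are
bit-for-bit reproducible.

What the generator emulates: the marginal spread of market-like small
molecules' binding kinetics, hepatic disposition and dosing. What it
does not: parameter correlations beyond the (configurable) trivariate
block, chemistry-driven structure–property coupling, and measurement
error in any of the inputs. Passing tests therefore demonstrate the
pipeline's behaviour under a market-like but idealised population, not
predictions for a specific chemical series.

## Numerical choices

- LSODA (stiff/non-stiff switching) via `scipy.integrate.odeint`, with
  a numba-compiled right-hand side and analytic Jacobian; rtol 1e-8,
  atol 1e-12 µmol. Receptor binding at intra-target doses (~100 µM
  against nM Kd) makes the system genuinely stiff.
- Bolus events are instantaneous state jumps at the event time (the
  integrator restarts there), never forcing spikes.
- Output grid 0.05 h; average occupancy by trapezoidal quadrature.
- Tiny negative solver excursions (below atol) are clipped to zero in
  the reported trajectories; occupancy is clipped to [0, 1].
- Decile subgroup bins: stable sort by (value, compound id), bins of
  ⌊n/10⌋ or ⌈n/10⌉ members, so ties cannot duplicate or drop compounds.
- Wilson score intervals for all success proportions (the analysis
  reports bounds at reduced n, so interval width matters).
- Sweep default values: 7 log-spaced points spanning the parameter's
  1st–99th sampled percentiles.

## Problem sizes

The main study runs 10,000 compounds at full scale; the bundled tests
and the acceptance script use 2,000 (subgroup estimates then carry
Wilson CIs of roughly ±2–5 points), sweeps use 7×200 compounds and the
required-occupancy sweep 3×250. These sizes were chosen so the complete
suite runs in minutes on one core while keeping Monte Carlo noise well
below the effect sizes being asserted.

## Known limitations

- The rate laws are a faithful but independent reconstruction of the
  extended-clearance PBPK family; absolute probabilities shift with the
  stand-in joint distribution for (fub, CLr, Vss). In particular, with
  independent heavy-tailed renal clearance, the subgroup "hepatic
  clearance < 1 L/h" contains compounds with large CLr whose ITM
  behaviour resembles high-clearance drugs; restricting to total
  clearance < 1 L/h restores the expected near-zero success rate.
- Receptor occupancy is treated as directly observable; biomarker
  transduction, imaging noise and safety are out of scope.
- Single-dose evaluation, IV route only, no inter-individual
  physiological variability.
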