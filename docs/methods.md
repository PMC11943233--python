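# Methods

`nmbsim` simulates neuromuscular blockade with rocuronium under an
automated TOF-count-1 closed loop, its reversal by the stepped
sugammadex protocol, and the post-reversal kinetics of the free
rocuronium effect-site concentration (Ce_Rb) that determine
recurarization risk.  This note describes the model, its assumptions,
the calibrated defaults, the synthetic-patient generator, and the
numerical choices.

## The PK-PD model

Three species are tracked: free rocuronium (Rb), free sugammadex (SGX)
and their 1:1 inclusion complex.  Each follows linear two-compartment
disposition (V1, V2, CL, Q).  In the central compartment the free
species associate by mass action,

    d[complex]/dt = kon [Rb][SGX] − koff [complex],

with molar concentrations; the engine tracks the complex in micromoles
and converts binding fluxes to mass through the molecular weights
(Rb 609.7 g/mol, SGX 2178 g/mol), so the 1:1 stoichiometry and the
per-species mass balance are exact by construction.  The complex
distributes and is eliminated with sugammadex-like, renally scaled
parameters: encapsulated rocuronium leaves the body with the complex.
Free rocuronium drives the effect site through a first-order link,
dCe/dt = ke0 (C_Rb − Ce).

Assumptions worth stating: binding occurs only in the central
compartment; the complex neither dissociates differently in the
periphery nor binds plasma proteins; infusion and bolus dosing are
ideal (no dead volume or injection delay beyond the configurable
manual-injection delay for sugammadex); and PD is a static function of
Ce (all hysteresis is carried by ke0).

## Train-of-four pharmacodynamics

Each TOF twitch follows an inhibitory sigmoid Emax curve of Ce with a
shared Hill slope γ.  Fade is modelled by giving twitches 2–4
proportionally lower EC50s (ratios `fade2..fade4` < 1).  T1 is the
first-twitch height (% of control); TOFC counts twitches above a 5%
detection threshold; TOFR = T4/T1, reported only when all four twitches
are detectable (0.0 otherwise, mimicking a monitor that cannot form the
ratio).  Because the EC50s are ordered, T1 and TOFR are monotone
non-increasing in Ce, and the TOFR = 0.9 recovery threshold sits well
below the TOF-count-1 concentration window — recovery is assessed at a
much lighter block than the intraoperative target, exactly the
structure the protocol exploits.

## Calibrated default parameters

The defaults describe an Asian reference adult (male, 40 y, 60 kg,
eCCr 100 mL/min).  Disposition magnitudes are in the range reported for
the two drugs in adults (rocuronium CL 0.24 L/min, V1 3 L, V2 9 L;
sugammadex CL 0.09 L/min ≈ 5.4 L/h renal, Vss ≈ 9.6 L; complex
disposition equal to sugammadex; Kd = koff/kon = 0.1 µM).  The
remaining constants (ke0 = 0.72 min⁻¹, EC50_T1 = 0.55 µg/mL, γ = 3.5,
fades 0.87/0.855/0.84, rocuronium Q = 0.70 L/min) were calibrated, as a
set, against the clinical anchors the simulation is meant to reproduce:

* intraoperative TOF-count-1 plateau concentration ≈ 1.1–1.3 µg/mL
  (inside the observed 0.29–3.0 µg/mL range);
* recovery concentration Ce_r ≈ 0.3 µg/mL (observed 0.02–0.99);
* reversal of shallow block by sugammadex 2 mg/kg in < 2 min in a
  healthy adult;
* post-reversal Ce nadir ≈ 7 min after recovery, followed by a small
  rebound (≈ 0.05 µg/mL) peaking ≈ 30 min after recovery and then
  declining, never re-crossing Ce_r.

The rebound mechanism in the model is explicit: the sugammadex bolus
strips free rocuronium from plasma almost instantly; rocuronium still
stored in the peripheral compartment then returns on the Q_Rb/V2_Rb
timescale, is captured by the remaining free sugammadex, and the
equilibrium free fraction Kd·[complex]/[SGX_free] produces a slow
re-rise of free drug that peaks when peripheral return fades and renal
elimination of the complex takes over.  Q_Rb is therefore the dominant
control on rebound-peak timing, and the renal clearances on its height.
Every value is overridable through a flat YAML/JSON parameter file.

## Covariate model

Multiplicative, continuous, identity at the reference vector:
rocuronium disposition scales with Devine ideal body weight and
sugammadex/complex disposition with actual body weight (volumes
linearly, clearances with exponent 0.75); sugammadex and complex
clearances scale linearly with Cockcroft–Gault eCCr, rocuronium
clearance only through a 30% renal fraction; age has small linear
fractional effects on clearances (−0.3%/y) and on EC50 (−0.4%/y, older
subjects more sensitive); non-Asian subjects get configurable clearance
and EC50 factors (the defaults are the Asian reference, matching the
modelled population); a sevoflurane EC50 factor exists but is unity — the
protocol is total intravenous anesthesia.  Covariate effects are
deliberately mild, consistent with the limited covariate influence the
clinical literature reports for sugammadex reversal.

## Dosing controller

Induction: 0.6 mg/kg (ideal body weight) bolus; if TOFC > 0 at the
1-min check, 0.3 mg/kg rescue; if block is still absent 3 min after the
rescue, a 7 µg/kg/min fallback infusion starts.  Maintenance: the
device's actual TOFC = 1 adjustment law is proprietary, so a bounded
step-rate rule stands in for it: every 12-s TOF cycle, count 0 steps the
rate down, count 1 holds, count ≥ 2 steps it up (0.02 µg/kg/min per
cycle), with a 5 µg/kg/min jump-start when dosing resumes from zero —
a pure ramp from zero hunts for tens of minutes against the ~6-min
effect-site lag, whereas the jump-start settles the loop inside the
count-1 window (> 80% of post-settling observations at count 1 for the
reference patient).  Two abnormal-state warnings are implemented: no
block after 12 min of continuous fallback dosing, and TOFC ≥ 3
sustained for 5 min.  Reversal: sugammadex 2 mg/kg (actual body weight)
bolus; while TOFR < 0.9, 0.5 mg/kg supplements at 3 min and every
minute thereafter; total dose is therefore quantized to
2.0, 2.5, 3.0, … mg/kg.  All timers quantize to the 12-s observation
cadence; nothing is observable between ticks.

## Synthetic cohort

Virtual patients reproduce the clinical-series demographics: age 62.2 ± 14.0 y
(truncated to ≥ 20), height 159.0 ± 7.8 cm, BMI 22.3 ± 2.2 restricted
to 18–26 kg/m², eCCr 75.9 ± 20.6 mL/min, 49/74 female, operation time
2.5 ± 1.0 h (≥ 0.5 h).  Truncated normals are sampled by rejection, so
the hard bounds hold for every draw.  Weight is derived from BMI and
height; serum creatinine is back-solved from the sampled eCCr through
the Cockcroft–Gault inverse, reproducing the printed eCCr distribution
exactly.  Between-subject variability enters as independent mean-one
log-normal multipliers: 30% CV on clearances, 30% on central volumes,
40% on EC50 (chosen so the plateau and recovery concentrations spread
across the clinically observed ranges) and 25% on ke0.  The ke0 term is
a generator design choice: without it every simulated patient recovers
in under ~2.6 min and the supplemented subgroup that the two-group
comparison needs never occurs; effect-site equilibration is known to
vary substantially between subjects.

What the generator does **not** emulate: covariate correlations beyond
those induced by the Cockcroft–Gault formula itself, comorbidities
(diabetes, renal/hepatic failure, antiepileptic co-medication),
tourniquet effects, monitor noise or calibration drift, and manual
injection-timing variability (beyond a configurable delay).  Passing
cohort-level checks therefore demonstrates internal consistency of the
model under idealized dosing and monitoring, not agreement with any
individual real patient.

## Endpoint extraction

Ce_r is the effect-site concentration at the first 12-s observation
with TOFR ≥ 0.9 (the first-crossing convention).  The nadir is the
global minimum of Ce after that point within a 60-min post-sugammadex
horizon; the rebound peak is the maximum after the nadir, declared only
when it exceeds the nadir by 1% (relative) so numerical ripple is not
called a rebound; recurarization risk is flagged when the rebound peak
exceeds Ce_r.  The 60-min horizon comfortably covers the ~30-min
rebound peak; an unbounded search would only ever move the peak later
for trajectories still rising at the horizon.  The intraoperative
target concentration is the mean Ce over the last 30 min of
maintenance restricted to count-1 ticks.  Correlation strengths use the
conventional bands on |r| (≥ 0.7 strong, ≥ 0.4 correlation, ≥ 0.2 weak,
else none); shared band edges are assigned to the stronger label.  The
two-group comparison uses the pooled-variance two-sided t-test by
default, with Welch as an option.

## Numerics

Internal time is seconds; rate constants are per minute and converted
in the engine.  While no sugammadex is on board the system is linear
and each 12-s tick is propagated with a cached matrix exponential
(augmented with the infusion response and the cumulative-elimination
state), which is exact to round-off — full-protocol mass-balance errors
are at the 1e-14 level.  Once sugammadex appears, the binding terms
(kon[SGX] ≈ 10³ min⁻¹ after a bolus) make the system stiff; steps then
use LSODA with rtol 1e-8 / atol 1e-10, restarted at every dose event
(boluses are instantaneous state increments, never interpolated
across).  Sub-tolerance negative excursions are clipped at tick
boundaries; a significantly negative state raises an error instead of
being silenced.  Trajectories are recorded on the 12-s device grid;
halving the grid moves the extracted endpoints by well under 1%.

## Problem sizes

The shipped configuration runs the full protocol for one patient in
about 0.1 s and a 74-patient cohort end-to-end in a few seconds on one
CPU, so the test suite and the acceptance script use the full-sized
cohort (n = 74) directly and the distributional checks sample up to
5000 virtual patients.

## Known limitations

* The controller law is a stand-in reproducing the observable behaviour
  (a sustained TOF count of 1), not the device's internal algorithm;
  rate-step sizes and bounds are configuration, not measurements.
* PD constants are calibrated to reproduce aggregate clinical anchors,
  not fitted to individual concentration–effect data; the model
  simulates, it does not estimate.
* The complex is assumed to share sugammadex disposition exactly;
  renal-failure regimes (eCCr near zero) extrapolate the linear renal
  scaling and should not be over-interpreted.
* TOFR is modelled as a deterministic function of Ce; measured TOF
  trains carry device noise that would blur the Ce_r distribution.
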