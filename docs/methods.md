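# Methods

## Scope and state

The simulator models a cascade of N well-mixed vessels operated
semi-continuously: a reaction window of fixed length, then a transfer
event, repeated for the whole operation time.  A vessel's state is its
liquid volume, dissolved glucose mass, active enzyme pool, and a set of
Lagrangian solid cohorts.  A cohort is a mass of *continuum particles*
(1 g of initial unreacted solids each) sharing one conversion `x`; its
remaining substrate, expressed as equivalent glucose, is
`count·(1−x)·glucan_fraction·(180/162)`.  α-Cellulose is 78.5% glucan;
the xylan and minor components (21.5%) are carried as inert dry mass that
contributes to wet-cake mass but never to glucose.  All liquids have
density 1 g/mL; concentrations are per litre of liquid phase.

## Governing kinetics

The modified HCH-1 rate law (see README for the equations) couples
conversion-dependent reactivity κ(x), a lumped adsorption constant α that
grows with glucose and conversion, non-competitive glucose inhibition
`i = 1/(1+β₁G1)`, and a free-site fraction φ.  Enzyme deactivates by
first-order decay opposed by a recovery term anchored to a reference
concentration E₀.

**Shared enzyme pool across cohorts.**  The rate of a multi-cohort stage
is *not* the sum of independent batch rates: at low glucose the HCH-1 rate
saturates at κ·E·i per vessel, so summing per-cohort saturated rates would
make the total scale with the number of cohorts — splitting one cohort
into k equal parts would multiply the rate by ~k.  Instead the saturation
denominator is evaluated once per stage, with the total substrate
concentration and the substrate-weighted adsorption term, and the
resulting rate is apportioned over cohorts by their reactivity-weighted
substrate κ(x_i)·Gx_i.  Two exact consequences, both tested: a
single-cohort stage reproduces the batch trajectory to solver precision,
and cohort splitting is additive.

**Time base of the rate constants.**  The package stores the published
numeric values (k₃ = 84.75, k₆ = 38.50, decay 0.023/0.174, …) and
interprets them **per day** by default (`KineticParameters.time_unit`,
also accepts `"h"`).  Per-day is the only internally consistent reading:
the train model's total rate carries g/(L·day) units; a 124 g/L batch at
5 mg/g then takes weeks to saturate, matching how this substrate is
described in the long-term hydrolysis literature, and the minimum batch
loading for full conversion of a 50 g/L-equivalent slurry in 40 days
comes out 16.7 mg/g against a reference value of ~17.6.  The decay
constants per day give a ~30-day half-life, reproducing the reported ~26%
activity loss of the cocktail over 20 days at 50 °C.  Read per hour, the
same numbers exhaust a batch within hours and kill the enzyme pool inside
a single 48-h window — under that reading enzyme cannot survive transport
across stages, front-stage dosing becomes optimal and countercurrent
operation needs *more* enzyme than batch, inverting the qualitative
behaviour the train model exists to capture.

**E₀ bookkeeping in a flowing system.**  The decay reference E₀ is reset
to each stage's total enzyme concentration at the start of every reaction
window.  In a batch it is the initial concentration; in a train no single
"initial" concentration exists, and a per-window reference is the simplest
reading that reduces correctly to the batch case.  With per-day constants
the reset policy has little numerical effect (windows are short against
the decay time).

## Transfer protocol

Per transfer, in order: (1) a 1-mL liquid sample from every stage
(recorded in the exit ledger, as in the experimental protocol);
(2) centrifugation of each stage into a wet cake — all solids plus
entrained liquid at the configured moisture (default 0.75, the middle of
the reported 70–80% range) — and a supernatant; the absorbed enzyme
fraction `y = clamp(d₁E + d₂G1 + d₃, 0, 1)`, evaluated at the stage's
total enzyme and glucose concentrations, travels entirely with the cake,
the rest splits with the liquid volumes; (3) supernatants move one stage
toward the front (Stage 1's exits as product) while cake marches one
stage toward the back, each stage retaining a fixed wet-cake mass
(default 80 g; Stage N's excess exits with the spent solids); (4) fresh
solids (one x = 0 cohort) to Stage 1 and fresh liquid to Stage N; the
0.7 mL of antibiotic solutions added to every vessel per transfer in the
experimental protocol is tracked as glucose-free liquid
(`per_stage_liquid_feed_L`, ~6% of the liquid fed per cycle — omitting it
concentrates every stream by that much); (5) the enzyme dose
(loading × solids feed) into the configured stage; (6) decay references
reset.  Hydration water consumed by hydrolysis (0.1 g per g cellulose) is
neglected in the liquid volume.

System conversion is glucose leaving the train (product liquid + exit
cake + samples) per transfer over the equivalent glucose fed
(solids × 0.785 × 180/162); whether the denominator carries the 180/162
factor is configurable (`feed_basis_includes_hydration`).

**Startup.**  `initial_enzyme_mode` is `"nominal"` (each vessel charged
with loading × initial solids, used for the 24/42-day validation runs,
where startup still matters) or `"none"` (used for 200-day design runs,
which forget the startup entirely — verified by the steady-state stability
of doubled operation times).

## Design-space mapping

A requested (LRT, SLR, solid concentration) triple is realised by holding
the liquid feed per transfer fixed, estimating the per-stage liquid
inventory as retained-dry-cake / solid-concentration, solving the transfer
interval from the LRT, and converting SLR to a solids feed using the
slurry volume (liquid inventory × Ratio C).  Under this mapping the pair
(LRT 29 days, SLR 3.4 g/(L·day)) at 124 g solids/L lands exactly on the
experimental base operation (48-h transfers, 10 g solids per transfer),
which is the consistency check the mapping was chosen by.  Batch and
countercurrent enzyme demands are compared at equal conversion, product
concentration and reactor volume via the Ratio A/B/C volume bookkeeping;
"100% conversion" targets are evaluated as ≥ 99.5% because the final
approach to exhaustion is asymptotic.  The minimal loading search is a
bisection on [0.5, 40] mg/g to 0.05 mg/g (conversion is monotone in
loading, so bisection is exact).  Solution density is linear through
(0 g/L, 1000 g/L) and (100 g/L, 1040 g/L).

## Numerics

Reaction windows integrate the coupled cohort/glucose/enzyme ODEs with
LSODA, rtol 1e−8 / atol 1e−10 (halving the tolerances moves endpoints by
< 0.1%).  Rates are forced to exactly zero below substrate or enzyme
floors of 1e−12 g/L, which removes the 0/0 in φ and the divergence of α
as E → 0.  After each transfer, cohorts closer than 5e−3 in conversion,
cohorts beyond x = 0.9995, and cohorts below 1e−12 of a stage's count are
merged, conserving particle count and mean conversion exactly; this keeps
cohort lists bounded over long runs (merging is what makes 200-day runs
take seconds rather than minutes, at no visible cost at the reported
precision).  Degenerate inputs — empty stages, zero enzyme, zero solids —
short-circuit analytically (enzyme relaxes along the closed-form decay
solution).  The whole pipeline uses no random numbers: identical
configurations give bit-identical outputs.

Simulated problem sizes: validation trains run 12/21 cycles; design
points run 200 days (67–100 cycles of 8 stages); sweeps rerun the train
per candidate point.  Each 200-day run takes a few seconds on one CPU.

## Fidelity and known limitations

Agreement with the reference predictions is strong for the closed-form
quantities (inhibition percentage, volume ratios — exact), the batch
enzyme requirement (−5%), and the LRT-43-day design family (steady
glucose +9%, conversion +4%); the dosing-location sweeps reproduce the
qualitative optimum at the back half of the train, though the argmax sits
1–2 stages earlier than reported (5 vs 7 at 2 mg/g, 7 vs 8 at 5 mg/g),
and the sensitivity scan agrees that d₂ matters least and d₃ most but
ranks d₁ above a₁.  The 48-h-transfer family (validation trains and the
LRT-29 point) runs systematically high: end-of-run Stage-1 glucose +20%
to +30%, conversions +12%.  The reference implementation discretised the
conversion axis into a finite number of Eulerian intervals of unreported
count and did not publish its startup enzyme amounts or enzyme/E₀
bookkeeping across transfers; those choices are not recoverable from the
published record, and no combination of the ambiguities exposed here
(time base, startup mode, hydration basis, SLR volume basis) closes the
remaining gap without breaking the better-matched quantities.  The
residual is reported as is rather than absorbed into parameter changes.

Also deliberately out of scope: cellobiose as an intermediate (the
cocktail's β-glucosidase makes it transient), xylan hydrolysis, lignin–
enzyme interaction (α-cellulose has no lignin), temperature/pH dependence,
and mechanistic (Langmuir) adsorption isotherms — the linear partition
model is an empirical fit over E ∈ [0, ~2.5] g/L, G1 ∈ [0, 93] g/L and is
clamped to [0, 1] outside its calibration range.  Fits of the partition
plane are ordinary least squares; on noiseless synthetic data they
recover the coefficients to 1e−10, which validates the fitting machinery
but — absent the original scatter — not the published R² = 0.99.
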