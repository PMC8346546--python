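# Methods

## Model overview

`fuzzymsc` simulates a monolayer-seeded MSC culture on a regular 3D
lattice of cubic patches (default edge 15 µm, eight z-layers — enough for
the multilayering osteoblastic cultures develop). Each patch holds at most
one cell; neighbourhoods are 26-connected Moore by default (von Neumann
available), truncated at solid walls. One iteration represents one hour.
Per step, every cell (i) relaxes its internal pH toward the ambient pH,
(ii) updates its DNA-damage state, (iii) is evaluated by the fuzzy
controller, (iv) samples its stochastic events, and (v) advances its
continuous differentiation; afterwards the growth-factor fields react and
diffuse and, in protocols longer than three days, the medium is reset
every 2.5 days.

## The fuzzy controller

Seven inputs are fuzzified by piecewise-linear membership functions
(triangles, trapezoids, saturating shoulders). The breakpoints encode
concentration bands reported for each cue:

| input | levels | key breakpoints (defaults) |
|---|---|---|
| Mg²⁺ (mM) | negligible, inhibitory, stimulatory, high, destructive | ≤0.8 negligible; stimulatory triangle over 2–10 peaking at `cmlt`=4.5; inhibitory shoulder from 1.8; high triangle peaking at `cmmt`=15; destructive shoulder peaking at `cmht`=30 |
| alkalinity (pH gap) | negligible, mild, severe | mild from 0.1–0.25; severe peaks at `a_t`=0.8 |
| BMP2 (ng/mL) | negligible, stimulatory, neutral, inhibitory | onset 0.008; stimulatory 10–20; neutral 50–200; inhibitory 500+ |
| TGF-β1 (ng/mL) | negligible, stimulatory, high | onset 0.05; plateau 14.2–36.3 |
| density | low, medium, high | `cclt1`=0.10, `cclt2`=0.25, `ccht1`=0.60, `ccht2`=0.85 |
| maturity | early, late | shoulder pair around `m_t` ± 0.1 |
| DNA damage | low, high | crisp {0, 1} |

`cmmt`, the peak of the "high" Mg level, has no reported value anywhere
and defaults to 15 mM, midway between the stimulatory and cytotoxic
bands. All breakpoints are configuration (several are themselves free
parameters), and the rule table is data: the shipped default transcribes
the qualitative effects the experimental literature reports (stimulatory
Mg/BMP2/TGF-β1 raise proliferation and early differentiation; Mg above
~1.8 mM blocks late differentiation; destructive Mg, severe alkalinity,
inhibitory BMP2 and DNA damage drive mortality; crowding triggers
migration and differentiation onset; solitude depresses growth).

Inference uses min for AND and max for OR. The "any two or more"
combinator is computed as the second-largest clause degree, which under
min/max norms equals the literal OR over all conjunctions of size ≥ 2
(the test suite checks this against explicit subset enumeration).
Defuzzification is the weighted fuzzy mean over fired rules: each rule
contributes its firing strength times the representative value of its
consequent level. Representative values are evenly spaced (0, 0.25, 0.5,
0.75, 1). Centroid-of-area defuzzification was the design alternative;
fixed representative values were chosen because the source description
("averaging on the activated outputs") matches a weighted mean of level
representatives, and they keep outputs piecewise-rational in the inputs.
When no rule fires for an action the output defaults to 0 — the
conservative null action.

## Cellular events

Probabilities are clamped to [0, 1] since the event equations are
unbounded products. Within a step the phases run mortality →
proliferation → migration → differentiation, cells visited in freshly
randomised order inside each phase, which avoids positional bias. A
division places the daughter on a uniformly random vacant neighbour
patch; with no vacancy the division is deferred (contact inhibition), the
cycle clock keeps running and the attempt repeats in later steps. Exactly
one of the two post-division cells receives the mitotic-damage flag δ_P
(uniformly chosen); the flag expires after one mean cycle time
(`delta_p_persistence`, default 26 h) — "shortly after proliferation"
read as a one-cycle transient rather than a permanent mark. Death frees
the patch immediately. Migration moves one patch per hour to a random
vacant neighbour.

Ω(t) = 1/(1 + e^(−k_Ω (t − T_cyc))) with k_Ω = 0.4 /h and T_cyc = 26 h.
The logistic gate keeps early-cycle divisions rare while leaving the
post-gate waiting time stochastic; with f_P = 1 the mean inter-division
time sits near T_cyc (a property test verifies this by direct
simulation). Seeded cells start with cycle clocks uniform on [0, T_cyc)
— an asynchronous culture.

DNA damage occurs at initialisation with probability γ_C (passaging
injury) and deterministically after one hour at or above pH_t; it never
reverts. Internal pH relaxes toward ambient at the constant rate r_r
(saturating, no overshoot), and the controller's alkalinity input is the
non-negative gap ambient − internal.

## Environment

Mg²⁺ and pH are spatially uniform (ions equilibrate much faster than the
protein fields); TGF-β1 and BMP2 are per-patch fields. The reaction step
applies per-cell production (full rate for early-phase cells, a
configurable fraction — default 0.5 — for late-phase cells, reflecting
the higher secretion observed during early differentiation), first-order
cellular consumption weighted by `wc`, and first-order degradation;
diffusion is an explicit finite-difference scheme with no-flux walls that
substeps automatically whenever D·dt/h² > 1/6. The default diffusivity
(100 µm²/h) is an effective value chosen for the lattice scale, far below
free-solution protein diffusivity; with medium resets every 2.5 days the
fields stay close to well-mixed, so results are insensitive to it. The
Mg→pH map is affine, pH = 7.4 + 0.02·(Mg − 0.8 mM), clamped at 10 —
placing 60 mM near pH 8.6, inside the alkaline range cultures report.

## Observables

Live count is the number of living cells; viability is
100·alive/(alive + cumulative dead); DNA content is proportional to live
count; ALP sums maturity/m_t over early-phase cells and OC sums
(maturity − m_t)/(1 − m_t) over late-phase cells (ALP the early, OC the
late marker; the κ scale constants are calibration degrees of freedom);
growth factors report mean medium concentration, optionally normalised by
DNA.

## Default parameters

Defaults describe an unstimulated culture: γ_P0 = 0.10 /step with
α_P = 2 gives divisions roughly every 35–40 h at baseline controller
output; γ_M0 = 0.002 /step with α_M = 2 yields ~10–20 % cumulative death
over nine days; r_D0 = 0.002 /step with α_D = 2 matures a continuously
committed cell in about three weeks, matching 21-day differentiation
protocols; γ_C = 0.05, pH_t = 9.0, r_r = 0.02 pH/h. Exactly twenty
parameters are flagged free and carry uniform priors.

## Synthetic studies and calibration scale

The fixtures module emulates three study designs: five Mg²⁺ conditions
measured for live count and viability at day 3 (study 1); two conditions
measured for DNA, ALP, OC and growth factors at days 7/14/21 (study 2);
four conditions measured for live count at days 3/6/9 (study 3).
Observation noise is Gaussian with relative sd defaulting to 15 %,
typical of culture-assay error bars. The generator reproduces measurement
schedules and schema, not the biological variability between donors,
plating batches or assay kits — passing recovery tests therefore
demonstrates that the pipeline inverts the model, not that the model fits
any particular laboratory's data.

The fit metric is R² = 1 − Σ|sim − obs| / Σ|obs| per observable,
averaged over observables (a normalised absolute difference, not the
regression R²; it can be negative for very poor fits). Datasets lacking
viability measurements may declare a minimum viability (e.g. 50 %);
parameter sets violating it receive the worst distance, preventing high
fitness at the cost of unrealistic mortality.

Screening uses a fold-over of a Hadamard design — resolution IV, so the
main effects that drive the ranking are unconfounded with two-way
interactions — with parameters set to their prior bounds, and ranks them
by main-effect F statistics scaled to a maximum of 1. Rejection ABC
samples uniform priors, simulates once per draw, and keeps the best
`n_keep`. A posterior is "significantly narrower" than its prior when its
IQR falls strictly below ρ = 0.5 times the prior IQR; accepted parameters
are fixed at the posterior median. The loop ends when an iteration
accepts nothing, the pool empties, a round limit is hit, or — as an
optional alternative stopping rule — the gain in mean R² of the kept runs
drops below a tolerance.

The built-in recovery experiment runs at reduced scale: a zero-noise
study-3-shaped dataset (live counts at days 3/6/9, one 3 mM condition,
20 cells seeded on a 20×20×8 lattice) generated at known ground truth,
six free parameters with factor-of-two priors bracketing the truth
off-centre (as an experimenter's order-of-magnitude ranges would), ABC
with 500 runs keeping the top 20, at most two rounds. The 20×20×8 world
matters: in smaller worlds the population hits the lattice capacity by
day 9, which caps the fit metric's sensitivity to the proliferation
parameters and lets the differentiation rate dominate the screen; without
saturation the proliferation parameters γ_P0 and α_P rank first, and
their posterior medians land within a few to ~15 % of truth. Because α_P
and γ_P0 enter the proliferation chance only through their product with
f_P, they are nearly confounded on single-study data; their individual
medians are pulled to the truth mainly by the priors, which is the
realistic behaviour of the full pipeline as well.

## Numerical and degenerate-case choices

Ties in the sensitivity ranking break lexicographically by parameter
name. A flat fit landscape yields all-zero scaled effects rather than an
error. ABC with every run violating the viability constraint flags the
posterior as degenerate and accepts nothing. Diffusion of a zero or
uniform field is exact; concentrations are floored at zero after the
reaction step. All randomness flows from one `numpy` `SeedSequence`:
replicate seeds, design-row seeds and ABC draws are spawned children, so
any run is bit-reproducible from the master seed; replicate seeds are
reused across conditions to give paired comparisons.

## Known limitations

Cell mechanics, adhesion, spreading and substrate stiffness are outside
the model; migration and growth are lattice-constrained; Mg²⁺ acts only
through the controller inputs and the affine pH map (no implant
degradation kinetics); growth-factor production laws are first-order
reconstructions; and the observable maps for ALP/OC are proportional
weightings, adequate for trends but not absolute assay units.
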