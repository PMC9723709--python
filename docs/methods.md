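# Methods

## Model

`commpharm` integrates a consumer–resource system with passive drug
partitioning. Each species `j` grows on a single shared carbon source
`C` through Monod kinetics, `U_j(C) = µ̄_j C/(K_j + C)`, converted to
biomass at yield `y_j`; growth is scaled by a Hill inhibition factor of
the species' internal drug pool, `I_j = 1/(1 + (A_j κ_j)^α)`, so the
drug is purely bacteriostatic (no death or lysis term, hence densities
are nondecreasing). Drug exchanges between the environment and each
species' pool by Fick's first law in its well-mixed form — flux
`φ_j (A_e − A_j) S_j` — and decays abiotically at rate `d`. All drug
pools are expressed per culture volume, which yields the exact identity
`A_e + Σ_j A_j = A_0 e^{−dt}` used as a continuous correctness check.

Assumptions worth keeping in mind: a single carbon source (no diauxie);
yields identical in pure and mixed culture; spatially homogeneous,
well-shaken cultures (no spatial derivative in the diffusion term); no
enzymatic drug degradation — tolerance is encoded purely through a
lower drug affinity `κ`.

### Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| µ̄ | maximal carbon uptake rate | mg/OD/h | 1.25 |
| K | carbon half-saturation | mg/mL | 0.5 |
| y | biomass yield | OD/mg | 0.65 |
| κ | drug affinity (A50 = 1/κ) | mL/µg | 0.1 |
| φ | drug exchange coefficient | 1/OD/h | 10 |
| S(0) | inoculum | OD | 1e-3 |
| d | drug decay rate | 1/h | 1e-4 |
| α | Hill coefficient | — | 2 |
| A0 | initial drug | µg/mL | 2 |
| C0 | initial carbon | mg/mL | 2 |
| t_end | assay horizon | h | 24 |

Two unit choices deserve explanation because the source tables for such
models often mix scales. First, the Hill factor is written with the
dimensionless product `A·κ` (κ in mL/µg), so `A50 = 1/κ = 10 µg/mL`;
the alternative `A/κ` reading is dimensionally inconsistent with κ's
unit and would invert the meaning of "affinity". Second, φ is treated
as an effective per-biomass exchange rate of 10 per OD per hour. Under
a literal µL→mL conversion (φ = 0.01) internal pools would equilibrate
two orders of magnitude more slowly than growth, the 24 h IC90 would
sit ~700× above A50, and the model's characteristic co-culture
predictions (see below) would vanish for every parameter combination we
tested; at φ = 10 the default A0 = 2 µg/mL sits mid-gradient of the
dose–response, as intended. A tolerant ("resistant") neighbour is
encoded as `κ₂ = κ₁/100` by default (`κ = 0` for ideal insensitivity).

### Numerics

LSODA (stiff-capable; the dynamics stiffen near carbon exhaustion) with
`rtol 1e-8`, `atol 1e-10`, sampled on a uniform 20-minute grid to mirror
plate-reader cadence. Inside the right-hand side, components below zero
by at most 1e-7 are clamped to zero (adaptive solvers probe trial steps
that can legitimately undershoot by more than the tolerance); larger
excursions raise instead of being silently clipped, to distinguish
round-off from model misuse. A fixed-step classical Runge–Kutta
integrator at `dt = 1e-3 h` serves as an independent cross-check of the
adaptive solution (terminal states agree to better than 1e-4 relative).

## IC90 estimation

The IC90 is the smallest dose at which the focal species' endpoint
density, normalised to the zero-drug endpoint of the *same* culture
composition, falls to 0.10. On gridded curves the crossing is
interpolated linearly between bracketing concentrations; multiple
crossings return the first and flag the curve. Model-based IC90s are
refined by bisection on the simulator to `|normalised − 0.10| < 1e-4`,
with automatic upward bracket expansion starting from A50. The default
display gradient is zero plus 60 geometric concentrations spanning
`[A50/100, 100·A50]`; 60 (not fewer) because the interpolated IC90 must
move by <2% under a 2× grid refinement, which coarser grids fail on the
canonical pure culture.

## Headline comparisons

With the canonical parameters, the focal species' IC90 is 46.8 µg/mL
alone, 77.2 next to an identical sensitive neighbour (+65%), and 46.2
next to a 100-fold tolerant neighbour (−1.3%). Per-cell drug content
(`A_focal/S_focal` at the endpoint) is compared across conditions **at a
common reference dose** — the focal species' pure-culture IC90 —
because that isolates how neighbours redistribute a fixed exposure: the
sensitive pair shows less drug per focal cell in co-culture (positive
pure-minus-mixed difference), the tolerant pair more (negative
difference). Dosing each condition at its own IC90 instead (available as
`dose_policy="own-ic90"`) conflates the redistribution effect with the
much larger mixed-culture dose and reverses the sensitive-pair sign,
which is why it is not the default. Equilibrium diagnostics re-run the
same analyses at `t_end = 240 h` ("long enough" is configurable; the
24 h assay sits far from equilibrium, which is what makes the
inoculum–IC90 profile nonlinear).

## Empirical pipeline

Plate files are long-format CSV (well, time_h, channel, value) with a
YAML layout mapping wells to strains, dose, replicate and blank status.
The pipeline: (1) blank correction subtracts the time-matched mean of
the blank wells per channel and floors at zero; (2) calibration
estimates an OD-per-fluorescence ratio from the strain's pure wells as
total OD over total fluorescence across points clearing a detection
floor of 3× the blank standard deviation — a signal-weighted mean,
chosen because the unweighted mean of pointwise ratios is biased
several percent upward by read noise in the denominator at low signal;
the pointwise-ratio CV is reported as a quality diagnostic; (3) eOD =
fluorescence × ratio tracks a strain's share of biomass in mixed wells;
(4) per replicate, the endpoint reading (grid point nearest 24 h) is
normalised to that replicate's zero-drug well and the IC90 interpolated
as above; replicate IC90s are summarised as mean ± Student-t 95%
half-width (n−1 degrees of freedom). Replicates whose curve never
reaches 0.10 are recorded as absent, never interpolated.

The exact Wilcoxon–Mann–Whitney test enumerates the permutation null of
the rank sum by a subset-sum dynamic programme over doubled mid-ranks
(doubling makes tied mid-ranks integral), exact up to pooled size 20,
with a tie-corrected normal approximation beyond. The default two-sided
p doubles the smaller tail (capped at 1), e.g. complete separation of
8 vs 8 gives ranksum 36 and p = 2/12870 ≈ 1.554e-4; a
both-tails-summation variant is available. Relative drug content per
condition is culture density at the IC90 divided by the IC90
concentration, reported as percent change of mixed versus pure. Note
this density/IC90 ratio is a proxy with reciprocal-like dimensions, kept
verbatim for comparability with how plate assays report it; on
model-generated plates it is negative for both neighbour types (the
co-culture density drop dominates), and the assertable property is the
ordering — tolerant-neighbour shifts sit above sensitive-neighbour
shifts.

## Synthetic plates

The generator simulates every (composition, concentration) condition
and layers a measurement model: OD600 = total biomass, per-strain
fluorescence = biomass ÷ calibration ratio, each multiplied by
lognormal noise (`σ_mult = 0.05`) and offset by a constant blank level
plus additive Gaussian read noise (0.003 OD; 5 fluorescence units).
These magnitudes are typical of bench-top plate readers and exist to
exercise the pipeline, not to reproduce a specific instrument. Plates
carry 12 concentrations (zero + 11) × 8 technical replicates per
composition plus 8 blanks — the geometry of a 96-well plate with
column-wise doses — read every 20 min for 24 h. The gradient spans one
geometric decade (15–150 µg/mL) straddling the anticipated IC90 scale
of the canonical sensitive species, the same way assay ranges are
chosen around an expected inhibitory concentration. Seeds are explicit
and mandatory; a fixed seed gives bit-identical plates. The sidecar
ground truth stores the noise-free trajectories, the calibration
ratios, and the true IC90s both as interpolated on the plate's own
gradient (the estimator's estimand) and, optionally, refined by
bisection on the model.

What the generator does *not* emulate: evaporation and edge effects,
well-to-well crosstalk, fluorescence drift (available as an option but
off by default), instrument-specific export dialects, or biological
replicate-to-replicate parameter variation. Passing tests therefore
demonstrate correctness of the analysis chain under the stated
measurement model, not robustness to every artefact of real plates.

## Problem sizes

The bundled studies are sized for a laptop-class run: bisection IC90s
cost ~50 simulations each (~1–2 s); the recovery study uses 50 seeds ×
8 replicates at 5% noise (bias <2%, CI coverage ≥90% against the
grid-truth estimand); the fixed-step oracle runs two scenarios at
`dt = 1e-3 h`. Noise-free condition trajectories are cached per
parameter set, so repeated-seed studies cost noise generation and
analysis only.

## Known limitations

The tolerant-neighbour IC90 drop is small (~1%) under the canonical
parameters — the model reproduces the direction, not the ~50% drop seen
in real resistant-neighbour competition data. The empirical
density/IC90 content proxy consequently does not change sign between
neighbour types on model-generated plates (only its ordering is
preserved). Pairwise (n = 2) scenarios are the tested envelope; the
core integrator supports arbitrary n but sweeps and presets do not.
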