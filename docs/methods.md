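# Methods

## Quality-decay kinetics

The quality of a monitored product is a single scalar `c` (tomato
firmness, N).  Its decay rate follows the Arrhenius ratio form
`k(T) = k_ref·exp(−(Ea/R)(1/T − 1/T_ref))` with `R = 8.314 J mol⁻¹ K⁻¹`;
interfaces accept °C and convert to kelvin internally.  The canonical
rate unit is **day⁻¹**: the shipped tomato preset uses
`k_ref = 0.2 day⁻¹` at 20 °C, which is the only unit reading consistent
with the model's own worked outcomes (≈7.1 days of initial life at 20 °C,
≈3 days at 30 °C, ≈1.5 days at 40 °C).

Two first-order decay forms are available behind a selector:

* `exponential` (default): `c' = c·e^(−kΔt)` — the unique form consistent
  with the shelf-life expression `SL = (1/k)·ln(c/c_eq)`;
* `equilibrium`: `c' = c_eq + (c − c_eq)·e^(−kΔt)`, which decays toward
  the failure level instead of zero.

Shelf life is clamped at 0 once `c ≤ c_eq`; quality is clamped at 0 under
the exponential form.  Under time-varying temperature the rate is held
piecewise constant over each sampling interval, using the reading at the
interval's start — the discrete analogue of the monitoring loop.  Sensor
accuracy (±2 °C) propagates to rate bounds (`k⁻` at `T+2`, `k⁺` at `T−2`)
and hence to a shelf-life interval `SL⁻ ≤ SL ≤ SL⁺`.

The rate-fitting helper linearises the exponential form (`−ln(c/c₀)`
against `t`) and takes the ordinary least-squares slope with its standard
error; two points give the exact two-point slope.

## Field reconstruction

The room is an `M1 × M2` cell lattice (default 5 × 5 over 6.3 × 6.7 m).
Sensors map to the cell containing their position via
`(⌊y/Δy⌋, ⌊x/Δx⌋)`, with a 1e-9 epsilon against floating-point edge cases
and clamping so far-wall sensors land in the last cell.  Internally
indices are 0-based; published layouts use 1-based matrix notation.

"Contiguous-element averaging" is realized as an iterative 4-neighbour
(von Neumann) fill: measured cells are held fixed, every unmeasured cell
is replaced by the mean of its available neighbours in a deterministic
row-major Gauss–Seidel sweep, starting from the measured mean, until the
largest per-sweep change drops below 0.01 (°C or %RH), with a 10 000-sweep
cap.  This is a discrete Laplace solve, so the reconstruction obeys the
maximum principle (derived values stay inside the measured span) and the
fill is idempotent at convergence.  A lattice with a single measured cell
floods to that value.

Nodes with battery < 5 % (strict) or a cleared working flag are excluded
from the measured mask before interpolation, each with an
intervention-request warning.

### Inter-sensor-distance characterization

The error study places a 3 × 3 section with spacing Isd, senses every
cell in Setup 1 and only the first column in Setup 2 (three sensors, as in
the reference two-setup experiment), derives the rest by the averaging
fill and reports mean/std of the per-event mean absolute error per Isd,
for temperature and RH.  Truth fields are synthetic smooth planes plus a
sinusoidal bump with per-replicate random coefficients (gradients
N(0.8, 0.2) and N(0.3, 0.2) °C/m, bump sd 0.5 °C); RH is inversely
coupled at −2.5 %/3 °C.  Replicates use **common random numbers across
Isd levels** (a paired design: the same 16 fields are evaluated at every
spacing), so the monotone error-versus-distance trend is not masked by
between-level sampling noise.  `Isd = 0` denotes full coverage and yields
zero error by construction.  Because the truth fields are synthetic, the
meaningful surface of this experiment is the trend and the zero-coverage
limit, not any particular absolute error value from a physical room.
The companion rule `Ns = round((l1 + l2)/Isd*)` converts the admissible
spacing into a sensor count.

## Monitoring loop

Defaults: `ts = 300 s`, references T = 20 °C, H = 55 %, L = 500 lux, with
half-widths equal to the sensor accuracies (±2 °C, ±3.5 %RH, ±100 lux ≈
±20 % of the day plateau).  Threshold semantics are symmetric two-sided
bands.  One flag is raised per violated band, but **only the temperature
test selects the rate**: in-band temperature uses `k_ref`, out-of-band
uses `k(T)`; humidity and light violations request human intervention
without altering the kinetics (automatic recovery for those is out of
scope).  A missing reading carries the previous one forward and raises
the working flag.  The loop runs while `SL > 0`; at constant temperature
its expiry time matches the closed form `(1/k)ln(c0/c_eq)` within one
sampling interval.

## Placement optimizer

For every pallet `p` and cell `(i, j)` the optimizer evaluates the
hypothetical shelf life `SL[i,j,p] = (1/k(T_ij))·ln(c_p/c_eq)` and the
one-interval-ahead quality, forming two `M1 × M2 × Np` cubes frozen for
the duration of one optimization run.  Displacement is gated by a
per-interval firmness-decrease trigger `C_th` (N/s) between two
consecutive measurements; the two shipped presets (2.68 × 10⁻⁵ N/s for
10 min at 24 °C and 3.184 × 10⁻⁵ N/s at 26 °C) are stored verbatim as
configurable constants rather than derived, since no unit reading of the
kinetic constants reproduces them exactly.

Selection works over cyclic orderings: for one ordering each pallet in
turn takes the free cell maximising its layer (n placements + 1 score
summation = n + 1 iterations); all n cyclic left-shifts are scored
(n(n+1) iterations); the winner's first pallet moves and is retired.  The
last remaining pallet is placed directly at its argmax (1 iteration, no
summation) — the unique simple accounting consistent with the 20/12/39
counts for four pallets, and with `Σ_{n=2..Np} n(n+1) + 1` in general.
Determinism: cell argmax ties break row-major (smallest row, then
column); equal ordering scores break to the earliest shift.  Candidate
cells are all cells not occupied by another pallet and not already
assigned within the ordering; a pallet's own cell is always legal, which
makes the warehouse overall shelf life non-decreasing under optimization.
`Np < M1·M2 − 3` is enforced at registry construction.

## Transport layer

Commands use the fixed 12-byte layout
`[89, add_btT, add_btP, 89, 90, x1, y1, 90, 91, x2, y2, 91]`; decoding
rejects wrong lengths, corrupted separators and out-of-bound coordinates
with distinct error types, and encode/decode is an exact round trip over
the full valid domain.  Paths are shortest unit-step 4-neighbour walks
around the encumbrance matrix (breadth-first search; neighbour expansion
prefers x-axis moves, then increasing index, fixing the tie-break).

The drive logic is a behavioural state machine over four compass
headings: a step along the heading actuates (IN1, IN2) = (0, 1) "go
ahead" at the central servo angle Cp; against the heading (1, 0) "go
backward"; a perpendicular step steers to Cp ± Rs (sign from the turn
direction) and updates the heading; a zero step keeps position with equal
motor bits.  The printed single-bit axis memory Z is exposed as the
axis-of-travel bit (0 = x, 1 = y).  The published gate-level equations
for the drive bits contain contradictory literals and cannot be executed
verbatim for all inputs, and one bit cannot encode four headings, so the
behavioural machine is the source of truth; it reproduces the motor
truth table wherever the printed logic is self-consistent.  Steps
changing more than one coordinate are rejected.

Metric coordinates map to grid indices by `round(position/cell size)`;
printed multi-cell hops are expanded to unit steps before replay.

## Synthetic environment

The generator emulates a non-refrigerated room monitored for 10 days 11 h
(default log length for statistics runs; the CLI default is 24 h):

* latent temperature = 21.3 °C base + 1.5 °C diurnal sinusoid (peak
  ≈15:00) + AR(1) jitter with 0.5 °C marginal sd and ≈1 h correlation
  time (via an IIR filter);
* window-adjacent nodes add a solar ramp rising linearly 9:00→16:00 to a
  daily peak drawn from N(2.8, 0.8) °C, then relaxing at 0.1 °C/h —
  successive days merge by elementwise max since the slow relaxation
  straddles midnight;
* RH = 55.73 % + (−2.5/3) %/°C × (T − 21.3) + its own AR(1) jitter;
* reported readings add noise N(0, acc/2) clipped at the accuracy bound
  (±2 °C, ±3.5 %RH), so |reported − latent| never exceeds the accuracy;
* illuminance is a 500/5 lux day/night square wave inside the 1–1000 lux
  sensor range; batteries drain linearly (default 1 %/day); the working
  flag can toggle randomly (default probability 0).

Identical seeds give byte-identical logs.  What the generator does *not*
emulate: spatial temperature correlation between neighbouring wall
sensors beyond the shared diurnal/base terms, door-opening transients,
HVAC interventions, and sensor drift/recalibration.  Tests passing on
this generator therefore demonstrate the correctness and determinism of
the computation chain under realistic summary statistics, not predictive
accuracy for any particular physical room.

## Problem sizes and numerical choices

The shipped scenario (5 × 5 lattice, 8 sensors, 4 pallets, 300 s ticks)
is the reference proof-of-concept scale and is what the test suite and
the acceptance script exercise; statistics use 100 seeds of 10-day runs,
rate-recovery 200 replicates of 100-point series, and planner
verification runs exhaustively on 3 × 3 lattices (≤3 obstacles, all
start/goal pairs) plus 500 seeded 4 × 4 instances against an independent
graph-shortest-path oracle.  Interpolation tolerance is 0.01 with a
10 000-sweep cap; iteration and score ties are broken deterministically
as above; all randomness flows from explicit integer seeds.

## Known limitations

Only one quality attribute (firmness) is parameterized; colour, weight
loss and microbial indices would need their own kinetic constants.
Non-Arrhenius secondary models (e.g. square-root) are out of scope.  The
optimizer is greedy over cyclic orderings — it reproduces the intended
iteration accounting exactly but is not an exhaustive assignment solver,
so it may return locally rather than globally optimal placements.  The
spatially varying recommended-temperature matrix is reduced to a scalar
reference for rate selection; per-cell references would only affect
flagging, not kinetics.
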