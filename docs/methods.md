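# Methods

## Model

### Field

Each occupied lattice cell is a point source of a secreted repulsive
factor.  Assuming diffusion is fast relative to tubule growth and the
factor is lost by first-order decay (or to the bulk medium above and
below the quasi-2-D tissue), the steady-state contribution of one
source at distance *d* is `s·exp(−d/λ)` with Euclidean *d* in cell
units.  The total field is the memoryless sum over current anatomy —
no diffusion history is stored — plus one zero-mean Gaussian draw of
sd η per evaluation, clamped at zero.  Sources outside the domain do
not exist; there is no periodic wrap.

When a tip evaluates the field (to decide branching, movement
probability or direction) its *own cell* is excluded from the sum:
the own-cell term is an identical constant for every tip and every
candidate direction and carries no information.  Everything else —
the tip's own stalk trail, its sibling, other trees — contributes,
and those contributions are what produce forward drive, sibling
repulsion and inter-tree avoidance.

### Direction sensing and the lattice

A tip moves onto one of its free 8-neighbour cells, but the *score*
of each candidate direction is the field sampled at **unit radius**
from the tip along that direction (the field accepts real-valued
points).  Scoring at neighbour-cell centres instead would give every
diagonal a systematic advantage — a diagonal cell is √2 away from the
tip and hence farther from all nearby sources — and entire trees then
grow as ±45° X-shapes.  Equal-radius sampling removes that lattice
artefact; it changes nothing else about the rules.

### Bifurcation

A tip bifurcates when (i) the sensed concentration is below θ and
(ii) it has grown at least the refractory length *r* since its last
branch.  The tip cell becomes the branch point and two daughter
branches sprout sideways — one stalk plus one tip each, flanking the
parent's heading at ±90°, i.e. the ampulla splits into two short
branches pointing in distinct directions.  Daughters are sources from
the moment they appear.  If a flank is blocked (crowded tissue, domain
edge) placement falls back to the two lowest-field free neighbours
that are not mutually 8-adjacent; if no admissible placement exists
the bifurcation is a silent no-op.

The sideways sprout matters.  With bare single-cell daughters placed
by lowest field, both daughters start on the two forward diagonals
and the steepest-descent rule locks them there: the first-branch
divergence is pinned near 90–110° for *every* parameter setting we
tried, and the continuum limit of those mechanics caps the measured
chord at ≈130°.  The one-cell sprout gives each daughter a trail
whose straightening force is initially lateral, which is exactly what
lets the wide first branch emerge (below).

The refractory length is a guard against degenerate instant
re-branching; the threshold gate alone would retrigger within a step
or two of a bifurcation.  Branch *timing* by an inhibitor threshold is
a modelling convenience, not a biological claim, and the gate is a
single predicate that could be swapped out.

### Advance

A tip moves with probability `1/(1 + C/K)` per step (C = sensed
concentration): growth slows in crowded surroundings, to an effective
stop as C ≫ K.  The destination is the lowest-scoring free direction;
exact ties break uniformly at random.  The vacated cell becomes a
stalk — trails are permanent; there is no retraction, remodelling or
tip death.  A tip with no free neighbour is marked stalled and
re-checked every step.  Tips act in a freshly shuffled order each
step to avoid first-mover bias.

### Default parameters

| symbol | meaning | default | units |
|--------|---------|---------|-------|
| s | source strength per occupied cell | 1.0 | conc. |
| λ | decay length of the kernel | 8.0 | cells |
| θ | bifurcation threshold | 8.6 | conc. |
| K | speed half-saturation | 7.5 | conc. |
| η | field noise sd | 0.2 | conc. |
| r | refractory length | 14 | cells |
| — | contact distance (Chebyshev) | 1 | cells |
| — | domain | 200×200 | cells |
| L | angle lever arm | 10 | cells |

Only ratios to *s* matter.  The anchor is the self-field of a long
straight trail at its own tip, `T(λ) = s/(e^{1/λ} − 1)` ≈ 7.5 for
λ=8: θ = 1.15·T sits just above it, so an unobstructed tip branches
and a freshly branched pair (whose mutual contribution raises C above
θ) must separate before branching again; K = T makes an ordinary tip
advance on roughly every second step; η = 0.2 ≈ 3% of T perturbs
direction choice where gradients are shallow without drowning them.
r = 14 sets inter-branch spacing comfortably above the measurement
lever L = 10.  λ = 8 is the pivotal value: long enough that the
ambient field of the growing tree folds later daughter pairs forward
(narrow angles) and that a neighbouring tree is repelled before
reaching contact, short enough that a first branch near a short trunk
is governed by its sibling rather than by the trunk.

Scenario trunks: a single (or triple) bud enters 4 cells from the
bottom edge — the first bifurcation happens close to the entry point,
before a long trunk accumulates below it; the paired scenarios use
85-cell trunks from opposite edges, leaving the opposing tips ~30
cells apart (closely-spaced, on a collision course).  Entering trunks
are branch-mature (the refractory gate does not postpone their first
split).

### Why the angles emerge, and the calibrated behaviour

First branch: with only a short trunk below, each daughter's local
field is dominated by the branch point and sibling directly behind
its lateral sprout, so both daughters run nearly horizontally apart;
the trunk's small upward pull, dithered by noise, bends the chords
slightly forward.  Measured over L=10, 20 seeds at 160 steps give a
generation-1 mean of ~154° (sd ~17°).  Later branches: the same ±90°
sprout pair now sits in the long-range field of the whole tree behind
it, which folds both daughters outward-forward; pooled generation-≥2
angles average ~92° (sd ~29°).  The gap exceeds 30° in ≥ 19/20 seeds.
No angle, spacing or generation rule appears anywhere in the code —
this is the model's central emergent behaviour.

Collision avoidance: two apposed trees (default parameters, 160
steps) interleave their growth fronts without a single Chebyshev-1
contact in 40/40 seeds; setting s = 0 (secretion knocked out, the
in-silico analogue of blocking the repulsive signal) produces
contacts in 20/20 runs.  In a finite domain unlimited further growth
must eventually force contact as free space is exhausted (observed
from ~step 240 with default geometry), so collision scoring is defined
at the same 160-step, 5–6-generation maturity as the angle runs —
comparable to the culture experiments the scenario mimics.

### What the model is not

No mesenchyme, no growth-factor signalling, no 3-D geometry, no
branch retraction, no energy minimisation (the grid is a bookkeeping
device, not a Hamiltonian), and no claim that branch timing in real
buds is inhibitor-gated.  The model is a thinking tool about one
mechanism: repulsion by a self-secreted factor.

## Morphometrics

*Divergence angle*: at a two-daughter branch point, walk each
daughter's skeleton to the first cell at cumulative arc ≥ L (stopping
early at the daughter's own next branch point or tip), and take the
angle between the two branch-point→stop-cell vectors.  Angles are
properties of elongated branches; L = 10 cells is the operational
lever.  Rasterization quantizes single measurements by up to ~3°.
Generation 1 is the first bifurcation from the trunk.

*Collisions*: categorical, as cultures are scored.  An inter-tree
event is any pair of cells from different trees within Chebyshev
distance 1 (the lattice reading of "no gap discernible by light
microscopy"); a self-loop is the same proximity within one tree with
a through-tree path longer than 10 cells, so parent/child and sibling
adjacency never count.  Raising the contact distance can only add
events.

*Kinematics*: tip speed is Euclidean frame-pair displacement over
elapsed time, sampled every 5 frames by default; closing speed of a
pair is the per-interval decrease of their Pythagorean separation.
The raw frame-difference velocity (negative during approach, as a
spreadsheet difference gives it) is emitted alongside its negation so
both sign conventions are explicit in the output.

## Statistics

Proportion CI half-width: `1.96·√(p(1−p)/n) + 1/(2n)` — the normal
approximation with a continuity term; formatted to whole percent at
≥10% and one decimal below.  Two-sample z: pooled standard error, no
continuity correction.  Two-sample t from summaries: pooled variance,
df = n₁+n₂−2 (Welch behind a flag).  Regression p:
`t = R·√((n−2)/(1−R²))` on n−2 df, two-tailed.  Both two-sample tests
default to **one-tailed** — the convention that reproduces the
published collision p value (0.0009 for 6/9 vs 0/10) exactly; the
two-tailed variants are one argument away.  The z test at n = 20 per
arm holds its nominal 5% type-I rate to within ±1% in simulation, but
as a normal-approximation test it is anti-conservative at small n and
extreme proportions.

## Synthetic fixtures

`gen_pair_tracks` emits head-on approaching tip pairs with closing
speed `max(0, c·ln(d/d₀)) + ε`, ε ~ N(0, σ²): a log-linear approach
law with a dead stop at d₀ = 30 µm (the observed stopping
separation), plus zero-mean observation noise on the recorded
positions.  The floor applies to the deterministic law, not to the
noise: measured frame-to-frame speeds scatter around the law and may
be slightly negative, as tracking data are — and below d₀ their mean
is genuinely zero, which is what the stop-regime check tests.
Defaults (c = 10 µm/h per ln-unit, σ = 2 µm/h, 6 pairs × 15 frames ≈
84 closing-speed observations) match the scale of the real time-lapse
analysis (~82 observations).  The law is a scaffold with known ground
truth for validating the regression pipeline; real movies add pair
selection, drift, segmentation error and tip identity switches that
the generator does not emulate, so recovering c within 15% here
validates the *pipeline*, not the biology.

`gen_toy_tree` rasterizes prescribed branch angles (daughters placed
symmetrically about the parent direction) for truth-comparison tests
of the angle measurement; recovery is within 3° at L = 12 on 20-cell
branches.

## Numerical and testing notes

* All randomness flows through one `numpy` Generator per run; a
  (parameters, seed) pair reproduces a run bit-for-bit, including
  serialized JSON/CSV artifacts.
* Tree JSON is canonical (sorted keys, stable layout): equality of
  files is equality of trees.  SWC export drops birth steps and
  recomputes generations from topology on read.
* The two published p values asserted in the acceptance tests that do
  not reproduce (printed 5.7×10⁻⁸ vs recomputed 6.6×10⁻⁸; printed
  4.8×10⁻¹² vs 5.8×10⁻¹² from R = 0.67) were originally computed from
  raw data; the printed summaries they accompany are rounded (R =
  0.672 reproduces 4.8×10⁻¹² exactly).  The assertions record the
  printed values and fail honestly.
* Simulation-dependent checks (angles, collisions) are stochastic
  properties over 20 seeds; their bands (150°±15°, 95°±15°, ≥90% of
  seeds ordered, 0 contacts) were chosen before the test suite and
  are not tuned per seed.
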