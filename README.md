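# selfavoid

A lattice model of **self-avoidance in branching epithelia**, with the
morphometric and statistical toolkit needed to analyse it — and the
equivalent measurements on cultured-organ data.

## The problem

The ureteric bud of the embryonic kidney branches iteratively into a
space-filling collecting-duct tree.  Two observations want a common
explanation: the *first* bifurcation opens very wide (~150°) while
later ones are much narrower (~95°), and branches — within one tree or
between neighbouring kidneys grown on a collision course — approach one
another but almost never touch.  A minimal hypothesis covers both:
every tubule secretes a rapidly diffusing, short-lived repulsive
factor, and growing tips slow down and steer away from high
concentrations of it.  Spacing, angle narrowing and collision
avoidance then all emerge from one unchanging rule; nothing
generation-specific is written into the system.

## The model

The tissue is a 2-D cell lattice.  Tree elements (tips and stalks)
occupy cells; every occupied cell is a point source whose steady-state
contribution at distance *d* is

    c(d) = s · exp(−d / λ)

and the field anywhere is the sum over all occupied cells, plus
zero-mean Gaussian noise of sd η (clamped at 0).  Per step, each tip:

* **bifurcates** if the concentration it senses (own cell excluded) is
  below the threshold θ and it has grown at least the refractory
  length *r* since its last branch — the tip cell becomes the branch
  point and two daughter sprouts (one stalk + one tip each) flank the
  old heading at ±90°;
* otherwise **advances** with probability 1/(1 + C/K) to the free
  neighbour cell in the direction of lowest field (one noisy
  evaluation per direction, sampled at unit radius so that lattice
  diagonals carry no artefactual advantage), leaving a stalk behind.

Defaults (s=1, λ=8 cells, θ=8.6, K=7.5, η=0.2, r=14, 200×200 domain)
are calibrated so a single bud reproduces the emergent wide-then-narrow
angles; see `docs/methods.md` for the reasoning behind every value.

The analysis side implements the corresponding measurements: skeleton
divergence angles with a fixed arc-length lever, categorical collision
scoring at Chebyshev contact distance, bead closest-approach, tip
speeds and pairwise closing speeds from frame pairs — plus the
statistics used on such data: proportion CIs with a 1/(2n) continuity
term, pooled two-sample z and t tests, and linear regression with
Pearson R and its t-based p value.

## Worked example

```
$ selfavoid simulate --scenario single_bud --seed 7 --steps 160 --out demo
wrote 1 trees, 268 track rows to demo

$ selfavoid angles demo/tree_0.json | head -4
       file  tree_id  generation   x  y  angle_deg
tree_0.json        0           1 100  3    129.560
tree_0.json        0           2 112 10    120.530
tree_0.json        0           2  87  8    105.018
```

The generation-1 record is the first bifurcation's divergence angle
(this particular seed gives 129.6°; the 20-seed mean is ~150°), and
the generation-≥2 records are the narrower later branches.  The same
statistics the culture experiments use are one command away:

```
$ selfavoid ci 6 9
p = 0.6667, CI95 half-width = 0.3635 (±36%)

$ selfavoid ztest 6 9 0 10
z = 3.121, 1-tailed p = 0.0009
```

i.e. 6/9 cultures with collisions against 0/10 controls is highly
significant under the pooled one-tailed z test.

Other subcommands: `collisions` (categorical verdict + self-loop
detection), `closing-speed`, `bead-distance`, `ttest`, `regress`,
and `fixtures` (synthetic ground-truth tracks and toy trees).

## Acceptance script

`scripts/acceptance.py` recomputes the headline numbers from scratch:
the five proportion-CI half-widths from the culture experiments, and
the emergent generation-1 / generation-≥2 mean divergence angles from
20 fresh seeded single-bud simulations (160 steps each, arc-length
lever 10 cells).

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It finishes in a few seconds and writes one JSON object with a
`{"value": ..., "n": ...}` entry per target.
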