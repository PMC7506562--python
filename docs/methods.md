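# Methods

## The measurement model

A football team is modelled as a population of n = 11 phase oscillators.
The phase of player k at frame t is the player-ball-goal angle (PBGA)

θ_k(t) = atan2(‖(P_k(t) − B(t)) × (G(t) − B(t))‖, (P_k(t) − B(t)) · (G(t) − B(t))),

computed with the vertex on the ball from planar coordinates (metres,
pitch-centred axes). The atan2(cross, dot) form is used rather than
arccos of the normalized dot product because it is numerically stable for
nearly-(anti)parallel vectors; the two agree wherever both are defined
(property-tested). The angle lies in [0, π]: it carries no left/right
information, only alignment with the ball-goal axis.

**Goal choice.** G is the goal-mouth centre of the goal *attacked* by the
team in possession, used for both teams: the attacked goal is the common
visual anchor of play — the attacking team orients toward it and the
defending team protects it. G is a point (not a goal segment) because only
a point gives a unique, symmetric angle definition.

**Synchronization.** Phases enter the Kuramoto order parameter
r'(t) e^{iψ(t)} = (1/n) Σ_k e^{iθ_k(t)}. The implementation computes the
complex mean once and takes modulus (r', the cluster amplitude) and
argument (ψ, the cluster phase). No Hilbert transform is involved
anywhere: phases are geometric quantities available at every frame, not
extracted from displacement oscillations, which sidesteps the
stationarity and band-limitation demands a transform-based phase would
impose on football data.

**Relative phase.** Φ_k(t) = θ_k(t) − ψ(t), reported unwrapped: with
θ ∈ [0, π] and ψ the argument of a mean of phasors in the upper half
plane, Φ already lies in [−π, π].

ψ is taken as the *argument of the complex mean* (the standard
cluster-phase convention). An arithmetic-mean-of-angles variant is
exposed via `psi_convention="arithmetic"` for sensitivity analysis; the
two differ only when phases spread widely.

## Domain handling and filtering

Frames are flagged alive/dead (play running or stopped) and with a
possession team. All analysis operations use alive frames only; dead
frames are retained in storage so the raw feed is preserved. A team's
*role* in a frame is `with_ball` when it has possession, else
`without_ball`.

Degenerate geometry — player within 1e−6 m of the ball, or ball within
1e−6 m of the goal centre — yields an explicitly flagged undefined angle
(NaN), never 0: atan2(0, 0) = 0 would silently count a degenerate sample
as perfectly aligned and bias r' upward. Undefined phases are dropped
from the frame's complex mean with n reduced accordingly (recorded as
`n_defined`).

Attack directions flip at half time. Normalization is an explicit
geometry operation (not an I/O default): second-half positions are
reflected through the pitch centre and the metadata rewritten so each
team attacks one fixed direction all match. The operation is
metadata-aware, hence idempotent.

## Binning

* **Linkage profiles**: per player and role, PBGA occupancy over 18 bins
  of π/18 (10°). Both raw frame counts (the conventional
  "relative frequency" axis of polar profile plots) and per-player
  proportions are emitted, labelled explicitly, since both readings are
  common.
* **Team configuration codes**: three sectors Front Support/Cover
  [0, π/3), Lateral Support/Cover [π/3, 2π/3), Back Support/Cover
  [2π/3, π]; the per-frame code is the ordered triple of sector counts
  ("6-4-1" = 6 front, 4 lateral, 1 back). "Support" when in possession,
  "cover" otherwise. Nominal closed-interval sector definitions overlap
  at boundaries; all bin grids here use half-open [lo, hi) intervals with
  the final interval closed at π — a deterministic disjoint partition
  whose boundary choice is measure-zero for continuous angles. The 3-bin
  sectors are exact unions of 18-bin blocks (bins 1–6, 7–12, 13–18), and
  this aggregation identity is property-tested.
* **Subgroup hulls**: convex hull (Qhull, via scipy) of each sector's
  member positions; subgroups with fewer than three members or collinear
  ones are flagged degenerate and keep their raw points.

## Pitch zones

The pitch is partitioned 4 longitudinal × 5 lateral = 20 zones, labelled
{D, MD, MO, O} × {L, CL, C, CR, R}. Default edges are an equal partition
(26.25 m quarters × 13.6 m fifths on the default 105 × 68 m pitch);
custom edge lists are accepted wherever a grid is taken. Zone membership
uses the same half-open edge rule as the angle bins. The zone of a frame
is indexed by the *ball* position after attack-direction normalization,
oriented so "O" (offensive) is the quarter nearest the goal being
attacked; lateral labels follow the attacking frame by default, with an
absolute-frame switch. Points outside the pitch are clamped to the
nearest cell and flagged.

## Mixed models

The per-frame response is r', one row per (alive frame, team). Fixed
effects: any subset of {team, role, lateral_zone, longitudinal_zone} and
pairwise interactions; random intercept by half; estimation by maximum
likelihood (statsmodels MixedLM, `reml=False` — the model-fitting backend
is standard supporting statistics, not this package's contribution).
Each term is tested by a likelihood-ratio chi-square against the explicit
null model with that term's design columns removed (df = removed-column
count). Reference levels are fixed — away team, with_ball role, D and L
zones — so positive coefficients read as "home > away" and "losing the
ball raises synchrony". Treatment-coded designs are checked for rank; a
singular design raises an error naming the collinear columns.

Frames are treated as independent observations. r' is in fact strongly
serially correlated (play evolves continuously at 25 Hz), so standard
errors and LRT statistics on real-speed data are anti-conservative; this
is a known limitation of the frame-level modelling convention, documented
rather than corrected (autocorrelation-robust variants are out of scope).

## The simulator

The simulator emulates the *statistical structure* the method consumes,
not football physics (no sprint-speed limits, collisions or offside).
Players are generated directly in angle space and mapped to positions —
this gives exact control of the measured quantity:

* team-mean angle μ(t): Gaussian random walk on [0, π] with reflecting
  boundaries, per-frame SD 0.01 rad (slow drift: ~0.05 rad/s at 25 Hz);
* player angle: μ(t) + von Mises(κ) noise folded into [0, π] by
  reflection (the fold keeps the stationary distribution symmetric about
  μ; κ = 0 reduces exactly to uniform angles on [0, π]);
* position: ball + radius · (cos θ û + side · sin θ v̂), with û the unit
  ball→attacked-goal vector; radius ~ U(5, 40) m and side ∈ {±1} redrawn
  per player per possession segment (so hulls and heatmaps are
  non-degenerate and recomputed PBGA equals the generated angle exactly);
* ball: bounded random-waypoint path inside 90 % of the pitch at 7 m/s;
  possession switches and dead-ball frames are iid per-frame Bernoulli
  events (defaults: switch 0.002/frame ≈ 20 s possessions; dead 0.3,
  the typical fraction of stopped play).

Defaults mirror a professional match recording: 25 Hz, two halves of
67,500 frames, 11 players per team, positions quantized to 0.01 m on
write. Coupling defaults κ = 1.6 (with ball) and κ = 2.3 (without ball)
place mean r' near 0.79 and 0.84 respectively — the regime reported for
elite matches, with the without-ball role more synchronized. κ is the
synchrony dial: mean r' rises monotonically from ≈ 0.64 + finite-n bias
(κ = 0, the uniform-phase limit 2/π) toward 1 (κ → ∞).

What the simulator does *not* emulate: realistic player kinematics and
spacing, tactical formations, true possession dynamics, measurement
noise, or serial structure in the dead-ball process. Tests passing on
simulated data therefore validate the *measurement chain* (geometry →
synchrony → binning → models) and its statistical calibration, not claims
about real match behavior.

**Desynchronization events** perturb a chosen subset of players' angles
by a magnitude scaled with a raised-sine envelope (zero at the window
edges, so the team relaxes back to baseline). Each perturbed player is
pushed toward the far end of [0, π] so boundary folding cannot swallow
the shift; positions are recomputed at the same radius and axis side.

## Problem sizes and numerical choices

* Synchrony summaries and conservation checks run on 5,000–10,000-frame
  simulations; the coupling-grid comparison uses 5,000 frames per κ with
  a block standard error (50-frame blocks) to respect the serial
  correlation induced by the μ random walk.
* Mixed-model recovery of a +0.15 role effect uses 20,000 frames
  (40,000 rows) generated directly from the LMM generative model; the
  type-I calibration of the team-effect LRT uses 50 replicates of 1,000
  frames each — the test's size is a property valid at any n, so smaller
  replicates are used for speed.
* Tolerances: analytic geometry cases to 1e−9 under similarity
  transforms; order-parameter oracle agreement to 1e−12; the
  uniform-phase limit to 0.01 at n = 10⁵ (the Monte-Carlo SD is
  ≈ 0.003).
* Tracking CSVs round-trip bit-exactly (pandas `round_trip` float
  parsing); optional 0.01 m quantization reproduces the source feed's
  resolution and uses IEEE round-half-even.
* Ties at bin/zone edges always resolve by the half-open rule; the final
  bin is closed so π and the far pitch boundary are included.

## Known limitations

* Frame-level independence assumption in the mixed models (above).
* The PBGA is planar; ball height is ignored.
* Possession and dead-ball flags are taken as given input; no event
  detection is performed on raw positions.
* The equal-partition zone grid is a declared default, not a claim that
  any particular analysis used those edges; penalty-area-aligned grids
  can be supplied as explicit edge lists.
* Substitutions and dismissals are unsupported: the schema requires
  exactly 11 players per team per frame.
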