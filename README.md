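# teamsync

Team synchronization analysis for football (soccer) tracking data.

`teamsync` measures the synergic behavior of a football team from planar
player/ball tracking feeds by treating the eleven players as a population
of coupled phase oscillators. The phase of player *k* at frame *t* is the
**player-ball-goal angle** (PBGA)

```
θ_k(t) = atan2(‖(P_k − B) × (G − B)‖, (P_k − B) · (G − B)) ∈ [0, π]
```

— the angle at the ball **B** between the ball→player vector and the
ball→goal vector, where **G** is the goal-mouth centre of the goal being
attacked by the team in possession (the same goal for both teams). θ = 0
means the player stands on the ball-goal line on the goal side; θ = π,
directly behind the ball. The team's per-frame synchronization is the
Kuramoto order parameter of these phases,

```
r'(t) e^{iψ(t)} = (1/n) Σ_k e^{iθ_k(t)},
```

with cluster amplitude r' ∈ [0, 1] (1 = perfect synchrony) and cluster
phase ψ. On top of this, the package computes the four standard
synergy-property measurements:

* **dimensional compression** — mean/SD of r' by team, half, possession
  role and 20-zone pitch partition, plus linear mixed-effects models
  (fixed effects team/role/zones, random intercept by half, ML
  estimation, likelihood-ratio tests against explicit null models);
* **reciprocal compensation** — the player-team relative phase
  Φ_k(t) = θ_k(t) − ψ(t);
* **interpersonal linkages** — per-player PBGA relative-frequency
  histograms (18 bins of 10°), split by with-ball / without-ball role;
* **degeneracy** — per-frame team configuration codes (TCC) counting
  players in the front/lateral/back 60° sectors (e.g. `6-4-1`), with
  convex hulls of each subgroup.

Because real professional feeds are proprietary, the package ships a
synthetic match simulator that emulates the schema and statistical
structure of an optical tracking feed (25 Hz, 2 × 11 players + ball,
alive/dead and possession flags) with players generated *directly in
angle space* at controllable von Mises coupling κ — so every downstream
measurement has a known ground truth.

Intended users: sports scientists and football analysts working with
spatiotemporal tracking data, and methodologists studying group
coordination.

## Worked example

```python
from teamsync import (SimulationConfig, simulate_match, compute_pbga,
                      kuramoto, summarize_synchrony,
                      team_configuration_code,
                      build_model_table, fit_lmm, LmmSpec)

cfg = SimulationConfig(n_frames_per_half=2500, seed=42)
ds, truth = simulate_match(cfg)          # 5,000-frame synthetic match

phase = compute_pbga(ds, "home")         # θ_k(t), NaN = degenerate geometry
sync = kuramoto(phase)                   # r'(t), ψ(t), n_defined
print(summarize_synchrony(sync, ds, group_by=("half", "role")))
```

```
  half          role      mean        sd  n_frames
0    1     with_ball  0.812279  0.086640      1167
1    1  without_ball  0.884359  0.067903       572
2    2     with_ball  0.769568  0.083433      1007
3    2  without_ball  0.803017  0.072220       756
```

Mean synchronization sits near 0.8 — a football match is predominantly a
highly synchronized state — and is higher without the ball than with it,
because defending compresses the team onto the ball-goal axis. Team
configuration codes and the mixed model follow the same pattern:

```python
print(team_configuration_code(phase, ds).head(3))
table = build_model_table([sync, kuramoto(compute_pbga(ds, "away"))], ds)
print(fit_lmm(table, LmmSpec(fixed=("team", "role"))).report())
```

```
            team role_label  fs_c  ls_c  bs_c
half frame
1    1      home    support     6     2     3
     2      home    support     7     4     0
     4      home    support     5     4     2

Linear mixed model (ML), n = 7004, logLik = 7853.84

              term  estimate       se
         Intercept  0.785134 0.017579
        team[home]  0.008005 0.001940
role[without_ball]  0.044304 0.001940

Likelihood-ratio tests vs null models without each term:
term      chisq  df       p_value
team  17.005249   1  3.727662e-05
role 503.035702   1 2.077145e-111
```

The `role[without_ball]` coefficient (+0.044, χ²(1) = 503, p ≪ 0.001)
recovers the without-ball synchrony increase that the simulator's higher
defending-role coupling builds in.

A CLI wraps the same functions:

```sh
teamsync simulate --seed 42 --frames-per-half 2500 --out match.csv --meta-out meta.yml
teamsync validate match.csv meta.yml
teamsync sync match.csv meta.yml --team both --out sync.csv
teamsync profile match.csv meta.yml --role without_ball --out profile.csv
teamsync tcc match.csv meta.yml --out tcc.csv --hulls-frame 1 0
teamsync lmm match.csv meta.yml --fixed team --fixed role --out lmm.csv
```

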