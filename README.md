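# internesting

Analysis pipeline for the inter-nesting movements of satellite-tagged
nesting loggerhead turtles (*Caretta caretta*): Argos track filtering,
behavioural segmentation with a switching state-space model, in-water
home-range estimation, site-fidelity testing, grid-cell occupancy
modelling, and overlap with anthropogenic threats (shrimp trawling, oil and
gas platforms). It is aimed at movement ecologists who want each of those
steps as a tested, reusable library function rather than a chain of GIS
clicks.

## The model at the core

Observed Argos fixes `y` (quality classes 3, 2, 1, 0, A, B; Z rejected) are
treated as noisy views of a latent track `x_t` on a regular 8-h grid. The
movement process is a first-difference correlated random walk whose
parameters switch under a hidden two-state Markov chain `b_t`:

    d_t = x_t − x_{t−1}
    d_t | b_t ~ N₂( γ_{b_t} · T(θ_{b_t}) · d_{t−1}, diag(σ²) )

with `T(θ)` a rotation matrix, `γ ∈ [0,1]` the move persistence, and
transition probabilities `α₁ = P(1|1)`, `α₂ = P(1|2)`. State 1 (γ₁ > γ₂) is
directed "migration"; state 2 is quiescent "inter-nesting/foraging". A fix
at fractional position `j` of interval `t` satisfies

    y = (1−j)·x_{t−1} + j·x_t + ε,

where `ε` is per-coordinate Student-t with degrees of freedom and scale
fixed per location class, times a free inflation ψ. The posterior is
sampled by Metropolis-within-Gibbs (forward-filtering backward-sampling for
`b_t`); the posterior mean state index `b̄ ∈ [1,2]` classifies each step as
migration (< 1.25), inter-nesting (> 1.75) or uncertain.

Downstream, inter-nesting periods run from the tagging date to the last
inter-nesting step. Mean daily locations feed a fixed-kernel KDE with an
LSCV bandwidth (50% core / 95% range contours, land removed); periods with
fewer than 20 mean daily locations get a 100% minimum convex polygon. Site
fidelity is judged by Monte Carlo: 100 random walks with the observed step
lengths, bounded to 0 to −200 m water; a track passes when its mean squared
displacement is below at least 95 of them.

## Worked example

No telemetry was deposited with the study, so the pipeline ships a
generative twin of the assumed movement model. The numbered scripts under
`analysis/` run the whole chain on a synthetic cohort:

```sh
python analysis/01_simulate_tracks.py   # tracks, emergences, environment
python analysis/02_filter_tracks.py
python analysis/03_fit_ssm.py
python analysis/04_home_ranges.py
python analysis/05_site_fidelity_and_distances.py
python analysis/06_grid_occupancy_glm.py
python analysis/07_threat_overlap.py
python analysis/08_printed_table_summaries.py
```

`05_site_fidelity_and_distances.py` prints, for the default 3-turtle cohort:

```
turtle_id  observed_msd  prop_null_exceeding  passes  seed
     sim1   1566.277038                 1.00    True    13
     sim2  10231.855249                 0.63   False    14
     sim3   2889.151133                 0.84   False    15
```

`observed_msd` is the dispersal statistic (km² in a local equal-area
frame), `prop_null_exceeding` the fraction of the 100 null walks more
dispersed than the turtle: sim1 sat on a stationary in-water centre (every
null walk was more dispersed — site fidelity), while sim2 and sim3 wandered
and are indistinguishable from random walks. `08_printed_table_summaries.py`
recomputes the study's published per-turtle tables, e.g.

```
table1        tracking_days 40   61.8  22.9  23.0   88.0 2470.0
table2           area50_km2 10   61.9  28.2  18.1  108.2    NaN
pooled emergence distance: 27.5 km over 45 distances
```

i.e. 2470 tracking days across 40 tracks, a mean 61.9 km² core-use area,
and a pooled mean of 27.5 km between successive beach emergences.

The same stages are exposed as a CLI (`internesting --workdir DIR all
--seed 7`), and everything the scripts do is importable from the
`internesting` package.

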