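# pseudotrack

Null movement models and one-sided Kolmogorov–Smirnov tests for detecting
environmental selection in marine animal tracks.

## The problem

Electronic tags tell us where a tracked animal *was*, but testing whether
it *selects* particular environmental conditions (here: sea-surface
temperature) requires knowing where it *could have been*. `pseudotrack`
generates that missing half of the comparison with **pseudo-absence
tracks**: simulated paths of environmentally naive walkers that share the
animal's movement statistics but have no access to the environment. If the
SST distribution experienced by the animal is shifted relative to the SST
sampled by its naive doubles, the animal shows (realized) selection.

Four null movement models are provided, each drawing a step length Δl and
a bearing per day:

| model      | bearing | step length |
|------------|---------|-------------|
| Brownian   | uniform on (−180°, 180°] | lognormal with the month's moments of ln Δl |
| Lévy       | uniform | truncated power law p(l) ∝ l^(−μ) on [l_min, l_max] |
| CRW        | previous heading + empirical monthly turning angle | empirical monthly steps |
| JCRW       | as CRW, but (θ, Δl) resampled **jointly** as observed pairs | — |

Every simulated track is **re-anchored to the observed animal position on
the 1st of each calendar month**, so pseudo-absences stay in the region
the animal actually used — unconstrained nulls diverge and produce trivial
rejections (the "Jack Horner effect"), over-constrained ones mimic the
data (the "Narcissus effect").

Selection is then tested with one-sided two-sample KS tests on the
presence vs pooled pseudo-absence SST samples. For the "warmer" direction
the statistic is D = max(F̂_absence − F̂_presence) with the asymptotic
one-sided p-value p = exp(−2D²mn/(m+n)). Positional uncertainty (ARGOS
95% CI) enters by Gaussian-weighted SST sampling with σ = 25% of the CI
radius.

Because daily positions on an autocorrelated SST field are far from
independent, these tests reject much more often than their nominal level
when there is **no** selection. The package quantifies exactly that: a
power harness simulates presence tracks of known selection strength
(fixed 50 km daily steps, Von Mises turning angles of concentration κ
aimed at the warmest SST within 50 km) over a synthetic SST field, and
tabulates the fraction of significant/correct tests against κ, the number
of aggregated tracks, and the p-value threshold, with bootstrap CIs.

## Worked example

```python
import datetime as dt
import numpy as np
from pseudotrack import (
    BiasedWalkConfig, GeoPosition, NullModelConfig, SyntheticEnvConfig,
    TrackSet, backward_rolling_mean, classify_selection, fit_monthly_stats,
    generate_env, generate_pseudo_tracks, ks_one_sided, match_track_to_env,
    simulate_biased_track,
)

# a synthetic northeast-Pacific-like SST field, 8-day composited
field = generate_env(SyntheticEnvConfig(n_days=95, seed=0))
sst8 = backward_rolling_mean(field, 8)

# an 80-day presence track that actively selects warm water (kappa = 5)
cfg = BiasedWalkConfig(kappa=5.0, n_days=80, start=GeoPosition(40.0, -135.0),
                       start_date=dt.date(2004, 1, 8), seed=1)
shark = simulate_biased_track(cfg, sst8, track_id="synthetic-05")
presence = match_track_to_env(shark, sst8)

# 100 pseudo-absence tracks per null model, anchored monthly to the track
stats = fit_monthly_stats(TrackSet([shark]))
absence = []
for model in ("brownian", "levy", "crw", "jcrw"):
    pts = generate_pseudo_tracks(
        shark, NullModelConfig(model=model, n_replicates=100, seed=2), stats)
    for t in pts.tracks():
        absence.append(match_track_to_env(t, sst8).sst)
absence = np.concatenate(absence)

warm = ks_one_sided(presence.sst, absence, "warmer")
cold = ks_one_sided(presence.sst, absence, "colder")
outcome = classify_selection(warm.p_value, cold.p_value, alpha=0.05)
print(f"presence mean SST: {presence.sst.mean():.2f} C over {len(presence)} fixes")
print(f"pseudo-absence mean SST: {absence.mean():.2f} C over {absence.size} samples")
print(f"warmer: D = {warm.D:.3f}, p = {warm.p_value:.3g}")
print(f"colder: D = {cold.D:.3f}, p = {cold.p_value:.3g}")
print(f"classified selection: {outcome.outcome}")
```

Output:

```
presence mean SST: 17.09 C over 80 fixes
pseudo-absence mean SST: 15.88 C over 31820 samples
warmer: D = 0.388, p = 3.68e-11
colder: D = 0.001, p = 1
classified selection: warmer
```

The warm-selecting track experienced water 1.2 °C warmer than its naive
doubles; the warmer-direction test is overwhelming and the colder one
null, so the track is classified as selecting warmer water — the correct
answer for κ > 0.

## Command line

`pseudotrack` exposes subcommands `gen-env`, `simulate-biased`,
`fit-stats`, `simulate-null`, `test-selection`, `power-grid`, and `run`
(end-to-end pipeline); every subcommand accepts a YAML `--config` with
flags taking precedence and writes an effective-config sidecar next to its
outputs. Example:

```sh
pseudotrack gen-env --days 95 --seed 1 --out field.nc
pseudotrack simulate-biased --env field.nc --kappa 0,0.5,20 --n 100 --out synth.csv
pseudotrack power-grid --env field.nc --kappas 0,0.5,20 --agg 1,15 --seed 1 --out grid.csv
```

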