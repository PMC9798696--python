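"""Simulation-study engine: power and error rates of the selection tests.

For each selection strength kappa the harness simulates a cohort of biased
presence tracks, fits monthly movement statistics to that cohort, generates
pseudo-absence cohorts under the requested null models, matches everything
to the SST field, and then runs both one-sided KS tests on pooled samples
of k aggregated tracks for each aggregation size k. Per-test p-values are
stored so that significance thresholds can be swept without re-simulation.

"Correct" follows the simulation ground truth: for kappa > 0 the right
answer is a significant warmer test and a non-significant colder test;
for kappa = 0 it is no significant test at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biased_walk import BiasedWalkConfig, simulate_cohort
from .env import EnvField, sample_point_many
from .movement import fit_monthly_stats
from .null_models import MODELS, NullModelConfig, generate_pseudo_tracks
from .selection_test import SelectionOutcome, classify_selection, ks_one_sided_from_sorted

logger = logging.getLogger(__name__)

__all__ = [
    "PowerCell",
    "PowerGrid",
    "correct_outcome",
    "bootstrap_fraction_ci",
    "run_power_grid",
    "summarize_results",
    "threshold_sweep",
]


@dataclass(frozen=True)
class PowerCell:
    """Outcome fractions for one (kappa, null model, k, alpha) grid point."""

    kappa: float
    null_model: str
    n_tracks_aggregated: int
    alpha: float
    fraction_significant_warm: float
    fraction_significant_cold: float
    fraction_correct: float
    ci_warm: tuple[float, float]
    ci_cold: tuple[float, float]
    ci_correct: tuple[float, float]
    n_replicates: int


@dataclass
class PowerGrid:
    cells: list[PowerCell]
    results: pd.DataFrame  # one row per KS test pair (stored p-values)
    metadata: dict = dc_field(default_factory=dict)

    def cell(self, kappa: float, null_model: str, k: int, alpha: float) -> PowerCell:
        for c in self.cells:
            if (c.kappa == kappa and c.null_model == null_model
                    and c.n_tracks_aggregated == k and c.alpha == alpha):
                return c
        raise KeyError((kappa, null_model, k, alpha))


def correct_outcome(kappa: float, outcome: SelectionOutcome) -> bool:
    """Whether the classified outcome matches the simulated ground truth."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa > 0:
        return outcome.outcome == "warmer"
    return outcome.outcome == "none"


def bootstrap_fraction_ci(
    outcomes,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI of the mean of binary outcomes."""
    arr = np.asarray(outcomes, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one outcome")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, arr.size, size=(n_bootstrap, arr.size))
    means = arr[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# matching helpers
# ---------------------------------------------------------------------------

def _match_pseudo_many(field: EnvField, lats, lons, dates) -> np.ndarray:
    """Flattened non-missing SST of all replicate fixes (vectorised)."""
    tidx = np.array([field.time_index(d) for d in dates])
    vals = sample_point_many(field, lats, lons, tidx[None, :])
    return vals[~np.isnan(vals)]


def _match_presence(field: EnvField, track) -> tuple[np.ndarray, np.ndarray]:
    tidx = np.array([field.time_index(d) for d in track.dates])
    vals = sample_point_many(field, track.lats(), track.lons(), tidx)
    ok = ~np.isnan(vals)
    dates = np.array([np.datetime64(d, "D") for d in track.dates])
    return dates[ok], vals[ok]


# ---------------------------------------------------------------------------
# the grid runner
# ---------------------------------------------------------------------------

def run_power_grid(
    field: EnvField,
    kappas: Sequence[float],
    n_tracks: int = 100,
    models: Sequence[str] = MODELS,
    aggregation_sizes: Sequence[int] = (1,),
    alphas: Sequence[float] = (0.05,),
    n_bootstrap: int = 1000,
    seed: int = 0,
    n_replicates: int = 100,
    n_subsets: int = 100,
    walk_config: Optional[BiasedWalkConfig] = None,
    start_region: Optional[tuple[float, float, float, float]] = None,
    per_model: bool = False,
) -> PowerGrid:
    """Run the full simulation study on ``field``.

    For each kappa: simulate ``n_tracks`` presence tracks, fit movement
    statistics to them, simulate ``n_replicates`` pseudo-tracks per null
    model per presence track, match all to SST, then for every
    aggregation size k draw ``n_subsets`` random subsets of k tracks,
    pool presence and (date-matched) pseudo-absence SST, and run both
    one-sided KS tests. By default the absence pool merges all requested
    null models ("pooled"); ``per_model=True`` additionally tests each
    model separately. Fully deterministic given ``seed``.
    """
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown null model {m!r}")
    max_k = max(aggregation_sizes)
    if max_k > n_tracks:
        raise ValueError(f"aggregation size {max_k} exceeds cohort size {n_tracks}")
    if walk_config is None:
        walk_config = BiasedWalkConfig(kappa=0.0)

    rows = []
    for ik, kappa in enumerate(kappas):
        cohort = simulate_cohort(
            [kappa], n_tracks, walk_config, field,
            seed=np.random.SeedSequence([seed, 1, ik]).generate_state(1)[0] % (2**31),
            start_region=start_region,
        )[float(kappa)]
        stats = fit_monthly_stats(cohort)
        presence: list[np.ndarray] = []
        absence: dict[str, list[np.ndarray]] = {m: [] for m in models}
        for it, track in enumerate(cohort):
            _, pres = _match_presence(field, track)
            presence.append(pres)
            for m in models:
                cfg = NullModelConfig(
                    model=m, n_replicates=n_replicates,
                    seed=int(np.random.SeedSequence([seed, 2, ik]).generate_state(1)[0] % (2**31)),
                )
                pts = generate_pseudo_tracks(track, cfg, stats)
                absence[m].append(_match_pseudo_many(field, pts.lats, pts.lons, pts.dates))
        pooled = [np.concatenate([absence[m][i] for m in models])
                  for i in range(n_tracks)]
        labels = {"pooled": pooled}
        if per_model:
            labels.update({m: absence[m] for m in models})

        sub_rng = np.random.default_rng(np.random.SeedSequence([seed, 3, ik]))
        for k in sorted(aggregation_sizes):
            if k == 1 and n_subsets == n_tracks:
                # per-track testing: each track exactly once
                subsets = [np.array([i]) for i in range(n_tracks)]
            else:
                subsets = [sub_rng.choice(n_tracks, size=k, replace=False)
                           for _ in range(n_subsets)]
            for label, abs_lists in labels.items():
                for isub, subset in enumerate(subsets):
                    pres = np.sort(np.concatenate([presence[i] for i in subset]))
                    absn = np.sort(np.concatenate([abs_lists[i] for i in subset]))
                    warm = ks_one_sided_from_sorted(pres, absn, "warmer")
                    cold = ks_one_sided_from_sorted(pres, absn, "colder")
                    rows.append({
                        "kappa": float(kappa), "null_model": label, "k": int(k),
                        "subset": isub, "D_warm": warm.D, "p_warm": warm.p_value,
                        "D_cold": cold.D, "p_cold": cold.p_value,
                        "n_presence": warm.n_presence, "n_absence": warm.n_absence,
                    })
        logger.info("kappa=%g done (%d tracks, models=%s)", kappa, n_tracks, list(models))

    results = pd.DataFrame(rows)
    cells = summarize_results(results, alphas, n_bootstrap, seed)
    metadata = {
        "seed": seed, "n_tracks": n_tracks, "n_replicates": n_replicates,
        "n_subsets": n_subsets, "models": list(models),
        "aggregation_sizes": [int(k) for k in aggregation_sizes],
        "alphas": [float(a) for a in alphas],
        "walk": {"n_days": walk_config.n_days, "step_km": walk_config.step_km,
                 "search_radius_km": walk_config.search_radius_km},
    }
    return PowerGrid(cells, results, metadata)


def summarize_results(
    results: pd.DataFrame,
    alphas: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list[PowerCell]:
    """Classify stored test rows at each alpha and tabulate fractions."""
    cells: list[PowerCell] = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    for (kappa, label, k), grp in results.groupby(["kappa", "null_model", "k"], sort=True):
        for alpha in alphas:
            sig_w = (grp["p_warm"] <= alpha).to_numpy()
            sig_c = (grp["p_cold"] <= alpha).to_numpy()
            outcomes = [
                correct_outcome(kappa, classify_selection(pw, pc, alpha))
                for pw, pc in zip(grp["p_warm"], grp["p_cold"])
            ]
            correct = np.asarray(outcomes, dtype=float)
            cells.append(PowerCell(
                kappa=float(kappa), null_model=str(label),
                n_tracks_aggregated=int(k), alpha=float(alpha),
                fraction_significant_warm=float(sig_w.mean()),
                fraction_significant_cold=float(sig_c.mean()),
                fraction_correct=float(correct.mean()),
                ci_warm=bootstrap_fraction_ci(sig_w, n_bootstrap, rng),
                ci_cold=bootstrap_fraction_ci(sig_c, n_bootstrap, rng),
                ci_correct=bootstrap_fraction_ci(correct, n_bootstrap, rng),
                n_replicates=int(len(grp)),
            ))
    return cells


def threshold_sweep(
    grid: PowerGrid | pd.DataFrame,
    alphas: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list[PowerCell]:
    """Reclassify stored p-values at new thresholds without re-simulation."""
    results = grid.results if isinstance(grid, PowerGrid) else grid
    for a in alphas:
        if not 0.0 <= a <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
    return summarize_results(results, alphas, n_bootstrap, seed)
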