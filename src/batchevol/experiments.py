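"""Simulation campaigns and their summary statistics.

Three campaigns mirror the standard analyses of serial-batch adaptation:

* stochastic competition assays (handled by :func:`batchevol.ibm.run_competition_ibm`),
* evolution at the three arsenic loci under scaled mutation rates
  (:func:`run_rate_scan`), and
* a factorial sweep over mutation-parameter sets contrasting pleiotropy
  variants of the genotype-phenotype map (:func:`run_sweep`).

Adaptation is summarized as the percentage of the stressed-to-unstressed
performance gap recovered by the population-mean phenotype, and as the
number of generations needed to reach 25/50/75 % recovery, read off a
monotone (isotonic) least-squares fit of the recovery trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from batchevol.deterministic import BatchProtocol
from batchevol.ibm import ReplicateResult, run_evolution
from batchevol.mutation import (
    GammaDfeModel,
    LocusTarget,
    MutationParameters,
    PhenotypeBounds,
    TargetedLociModel,
    default_locus_targets,
)

__all__ = [
    "AdaptationTrajectory",
    "recovery_fraction",
    "generations_to_recovery",
    "summarize_quantiles",
    "run_sweep",
    "run_rate_scan",
]


def recovery_fraction(
    value: float, stressed_ref: float, unstressed_ref: float
) -> float:
    """Percentage of the stressed-to-unstressed gap recovered.

    For time-like components (smaller is better): the stressed reference
    maps to 0 %, the unstressed reference to 100 %.
    """
    if stressed_ref == unstressed_ref:
        raise ValueError("degenerate references: stressed == unstressed")
    return 100.0 * (stressed_ref - value) / (stressed_ref - unstressed_ref)


@dataclass
class AdaptationTrajectory:
    """Recovery (%) of one population sampled on a generation grid."""

    generations: np.ndarray
    recovery: np.ndarray
    parameter_set_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.recovery = np.asarray(self.recovery, dtype=float)
        if self.generations.shape != self.recovery.shape:
            raise ValueError("generations and recovery must have equal length")
        if np.any(np.diff(self.generations) < 0):
            raise ValueError("generations must be non-decreasing")

    @classmethod
    def from_replicate(
        cls,
        result: ReplicateResult,
        protocol: BatchProtocol,
        bounds: PhenotypeBounds,
        parameter_set_id: str = "",
        replicate_id: str = "",
    ) -> "AdaptationTrajectory":
        """Doubling-time recovery of a :func:`run_evolution` result,
        sampled at every cycle end (every ``M`` divisions)."""
        gens = protocol.doublings_per_cycle * np.arange(
            len(result.mean_doubling_series), dtype=float
        )
        rec = np.array(
            [
                recovery_fraction(
                    d, bounds.stressed_doubling, bounds.unstressed_doubling
                )
                for d in result.mean_doubling_series
            ]
        )
        return cls(gens, np.clip(rec, None, 100.0), parameter_set_id, replicate_id)


def generations_to_recovery(
    traj: AdaptationTrajectory, thresholds: Sequence[float] = (25.0, 50.0, 75.0)
) -> dict:
    """Generations at which a monotone fit of the trajectory first reaches
    each recovery threshold.

    A non-decreasing function is fitted by least squares (isotonic
    regression); crossings are located by linear interpolation between
    fitted samples and are ``None`` for thresholds the fit never reaches.
    """
    if len(thresholds) == 0:
        raise ValueError("no thresholds given")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(traj.generations, traj.recovery)
    out: dict = {}
    for thr in thresholds:
        out[thr] = _first_crossing(traj.generations, fitted, thr)
    return out


def _first_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float | None:
    above = y >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0 or y[i] == y[i - 1]:
        return float(x[i])
    # linear interpolation inside the bracketing interval
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(x[i - 1] + frac * (x[i] - x[i - 1]))


def summarize_quantiles(
    trajectories: Sequence[AdaptationTrajectory],
    probabilities: Sequence[float] = (0.01, 0.10, 0.25, 0.50, 0.75, 0.90, 0.99),
) -> pd.DataFrame:
    """Per-generation empirical quantiles of recovery across populations.

    All trajectories must share the generation grid.  Returns a frame with
    one row per generation and one column per quantile (plus the median if
    not already requested).
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    grid = trajectories[0].generations
    for traj in trajectories[1:]:
        if traj.generations.shape != grid.shape or not np.allclose(
            traj.generations, grid
        ):
            raise ValueError("trajectories are on mismatched generation grids")
    probs = sorted(set(probabilities) | {0.5})
    mat = np.vstack([t.recovery for t in trajectories])
    data = {"generations": grid}
    for p in probs:
        data[f"q{p:g}"] = np.quantile(mat, p, axis=0)
    return pd.DataFrame(data)


def run_sweep(
    grid: Sequence[MutationParameters],
    protocol: BatchProtocol,
    map_variants: Sequence[str] = ("M1", "M2", "M3"),
    seed: int | None = None,
    bounds: PhenotypeBounds | None = None,
    fast_budget: float = 100.0,
) -> tuple[dict, pd.DataFrame]:
    """Factorial sweep over mutation-parameter sets and map variants.

    One population per parameter set per variant, with seeds paired across
    variants (the same parameter set gets the same stream under every
    variant, so variant contrasts are paired comparisons).  Returns the
    trajectory collections keyed by variant and a table of
    generations-to-25/50/75 %-recovery with a ``fast`` flag marking
    populations reaching 75 % within ``fast_budget`` generations.
    """
    bounds = bounds if bounds is not None else PhenotypeBounds()
    founder = bounds.founder()
    seeds = np.random.SeedSequence(seed).spawn(len(grid))
    trajectories: dict = {v: [] for v in map_variants}
    rows = []
    from dataclasses import replace

    for set_idx, (params, set_seq) in enumerate(zip(grid, seeds)):
        for variant in map_variants:
            model = GammaDfeModel(
                replace(params, map_variant=variant),
                bounds,
                protocol.doublings_per_cycle,
            )
            rng = np.random.default_rng(set_seq)  # paired across variants
            result = run_evolution(founder, model, protocol, rng=rng)
            traj = AdaptationTrajectory.from_replicate(
                result, protocol, bounds, parameter_set_id=str(set_idx)
            )
            trajectories[variant].append(traj)
            times = generations_to_recovery(traj)
            rows.append(
                {
                    "parameter_set_id": set_idx,
                    "variant": variant,
                    "gens_to_25": times[25.0],
                    "gens_to_50": times[50.0],
                    "gens_to_75": times[75.0],
                    "fast": times[75.0] is not None
                    and times[75.0] <= fast_budget,
                }
            )
    return trajectories, pd.DataFrame(rows)


def run_rate_scan(
    targets: Sequence[LocusTarget] | None = None,
    multipliers: Sequence[float] = (1.0, 3.0, 5.0, 10.0),
    protocol: BatchProtocol | None = None,
    n_replicates: int = 25,
    seed: int | None = None,
    bounds: PhenotypeBounds | None = None,
    base_rate_per_bp: float = 0.33e-9,
    presence_threshold: float = 0.05,
) -> pd.DataFrame:
    """Targeted-locus evolution at scaled mutation rates.

    For every multiplier, ``n_replicates`` populations evolve under the
    locus model; each row records the founder-extinction generation, the
    number of allele classes above ``presence_threshold`` at the end and
    the dominant class.  Because carrier frequencies of different alleles
    overlap in double mutants (whose phenotype is their best allele's,
    under complete negative epistasis), the dominant class is the
    fittest allele carried by a majority of cells; when none reaches 50 %
    it falls back to the most frequent present allele, or the founder.
    """
    targets = tuple(targets) if targets is not None else default_locus_targets()
    protocol = protocol if protocol is not None else BatchProtocol(100_000, 5, 50)
    bounds = bounds if bounds is not None else PhenotypeBounds()
    founder = bounds.founder()
    from batchevol.deterministic import analytic_selection_coefficient

    fitness_rank = {
        t.gene: analytic_selection_coefficient(
            bounds.stressed_lag, bounds.stressed_doubling,
            t.effect_lag, t.effect_doubling, protocol.doublings_per_cycle,
        )
        for t in targets
    }
    root = np.random.SeedSequence(seed)
    rows = []
    for mult, mult_seq in zip(multipliers, root.spawn(len(multipliers))):
        model = TargetedLociModel(
            targets, base_rate_per_bp=base_rate_per_bp, multiplier=mult, bounds=bounds
        )
        for rep, rep_seq in enumerate(mult_seq.spawn(n_replicates)):
            rng = np.random.default_rng(rep_seq)
            result = run_evolution(founder, model, protocol, rng=rng)
            final = result.frequency_series[-1]
            present = {a: f for a, f in final.items() if f > presence_threshold}
            majority = [a for a, f in final.items() if f > 0.5]
            if majority:
                dominant = max(majority, key=fitness_rank.get)
            elif present:
                dominant = max(present, key=present.get)
            else:
                dominant = "founder"
            rows.append(
                {
                    "multiplier": mult,
                    "replicate": rep,
                    "extinction_generation": result.founder_extinct_generation,
                    "n_classes_gt5pct": len(present),
                    "dominant_class": dominant,
                }
            )
    return pd.DataFrame(rows)
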