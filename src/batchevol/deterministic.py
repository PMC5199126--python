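"""Deterministic two-subpopulation batch-competition model.

A batch cycle starts with ``N`` cells split between a wild-type and a mutant
subpopulation.  Each subpopulation *i* is idle until its lag time ``lam_i``
has passed and then grows exponentially with doubling time ``tau_i``::

    N_i(t) = N_i(0) * 2 ** ((t - lam_i) / tau_i)    for t > lam_i

The cycle ends at the time ``t_end`` at which the total population has
doubled ``M`` times, i.e. ``sum_i N_i(t_end) = 2**M * N``; both
subpopulations are then diluted proportionally back to ``N`` cells and their
lags restart.  The per-generation selection coefficient of the mutant is the
slope of ``ln r`` (``r`` = mutant/wild-type ratio) against cumulative
generations, either obtained analytically for a single cycle dominated by
the wild type::

    s = ln 2 * (tau_1 / tau_2 - 1 + (lam_1 - lam_2) / (M * tau_2))

or by ordinary least squares over simulated cycle ends.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GrowthLaw",
    "BatchProtocol",
    "CompetitionTrajectory",
    "subpopulation_size",
    "cycle_end_time",
    "run_deterministic_competition",
    "analytic_selection_coefficient",
    "doubling_time_term",
    "lag_term",
    "regress_selection_coefficient",
]


@dataclass(frozen=True)
class GrowthLaw:
    """Deterministic batch growth of one genotype.

    Parameters
    ----------
    lag : float
        Time to the first cell division, in minutes.
    doubling_time : float
        Exponential-phase doubling time, in minutes.
    initial_count : float
        Cell count at the start of the batch cycle (real-valued).
    """

    lag: float
    doubling_time: float
    initial_count: float = 1.0

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")
        if self.doubling_time <= 0:
            raise ValueError(f"doubling_time must be > 0, got {self.doubling_time}")
        if self.initial_count < 0:
            raise ValueError(f"initial_count must be >= 0, got {self.initial_count}")

    def size_at(self, t: float) -> float:
        return subpopulation_size(self, t)

    def with_count(self, count: float) -> "GrowthLaw":
        return GrowthLaw(self.lag, self.doubling_time, count)


@dataclass(frozen=True)
class BatchProtocol:
    """Serial-transfer regime: bottleneck size ``N``, doublings per cycle
    ``M`` and the number of cycles."""

    bottleneck: int
    doublings_per_cycle: int = 5
    n_cycles: int = 20

    def __post_init__(self) -> None:
        if self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1")
        if self.doublings_per_cycle < 1:
            raise ValueError("doublings_per_cycle must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def cycle_capacity(self) -> int:
        """Total cell count that ends a cycle, ``2**M * N``."""
        return (2 ** self.doublings_per_cycle) * self.bottleneck


@dataclass
class CompetitionTrajectory:
    """Cycle-resolved record of a two-subpopulation competition.

    ``ratios``, ``frequencies`` and ``wt_counts`` have one entry per cycle
    end plus the leading ``t = 0`` entry; ``generations`` counts cumulative
    population doublings (``M`` per cycle).
    """

    cycle_end_times: np.ndarray
    ratios: np.ndarray
    generations: np.ndarray
    frequencies: np.ndarray
    wt_counts: np.ndarray
    mutant_counts: np.ndarray
    selection_coefficient: float | None = None

    def to_frame(self) -> pd.DataFrame:
        t_end = np.concatenate([[0.0], self.cycle_end_times])
        with np.errstate(divide="ignore"):
            ln_ratio = np.log(self.ratios)
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.ratios)),
                "t_end_min": t_end,
                "generations": self.generations,
                "ln_ratio": ln_ratio,
                "mutant_frequency": self.frequencies,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def fixation_generation(self, threshold: float = 0.99) -> float | None:
        """First cycle-end generation at which the mutant frequency reaches
        ``threshold``; ``None`` if it never does."""
        hit = np.flatnonzero(self.frequencies[1:] >= threshold)
        if hit.size == 0:
            return None
        return float(self.generations[1:][hit[0]])


def subpopulation_size(law: GrowthLaw, t: float) -> float:
    """Cell count of one subpopulation at time ``t`` within a batch cycle."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if t <= law.lag:
        return law.initial_count
    return law.initial_count * 2.0 ** ((t - law.lag) / law.doubling_time)


def cycle_end_time(laws: Sequence[GrowthLaw], protocol: BatchProtocol) -> float:
    """Solve for the time at which the total population has doubled ``M``
    times.

    The total size is continuous, non-decreasing and strictly increasing
    past the shortest lag, so the root is unique; it is bracketed by the
    longest lag plus twice ``M`` times the longest doubling time and found
    with Brent's method.
    """
    total0 = sum(law.initial_count for law in laws)
    if total0 <= 0:
        raise ValueError("all subpopulations are empty")
    target = (2 ** protocol.doublings_per_cycle) * total0

    def excess(t: float) -> float:
        return sum(subpopulation_size(law, t) for law in laws) - target

    alive = [law for law in laws if law.initial_count > 0]
    lo = 0.0
    hi = max(law.lag for law in alive) + 2.0 * protocol.doublings_per_cycle * max(
        law.doubling_time for law in alive
    )
    return brentq(excess, lo, hi, xtol=1e-9, rtol=1e-12)


def run_deterministic_competition(
    wt: GrowthLaw, mutant: GrowthLaw, protocol: BatchProtocol
) -> CompetitionTrajectory:
    """Drift-free competition between a wild-type and a mutant subpopulation.

    Each cycle solves ``t_end``, records the mutant/WT ratio, and rescales
    both subpopulations proportionally so the total returns to the
    bottleneck size (real-valued dilution, no sampling).  Lags restart at
    every cycle.
    """
    n = protocol.bottleneck
    start_total = wt.initial_count + mutant.initial_count
    if not math.isclose(start_total, n, rel_tol=1e-9):
        raise ValueError(
            f"initial counts ({start_total}) must sum to the bottleneck ({n})"
        )
    n_wt, n_mut = float(wt.initial_count), float(mutant.initial_count)
    t_ends, ratios, freqs, wt_counts, mut_counts = [], [_ratio(n_mut, n_wt)], [
        n_mut / n
    ], [n_wt], [n_mut]
    for _ in range(protocol.n_cycles):
        laws = [wt.with_count(n_wt), mutant.with_count(n_mut)]
        t_end = cycle_end_time(laws, protocol)
        n_wt = subpopulation_size(laws[0], t_end)
        n_mut = subpopulation_size(laws[1], t_end)
        scale = n / (n_wt + n_mut)
        n_wt *= scale
        n_mut *= scale
        t_ends.append(t_end)
        ratios.append(_ratio(n_mut, n_wt))
        freqs.append(n_mut / n)
        wt_counts.append(n_wt)
        mut_counts.append(n_mut)
    m = protocol.doublings_per_cycle
    generations = m * np.arange(protocol.n_cycles + 1, dtype=float)
    return CompetitionTrajectory(
        cycle_end_times=np.asarray(t_ends),
        ratios=np.asarray(ratios),
        generations=generations,
        frequencies=np.asarray(freqs),
        wt_counts=np.asarray(wt_counts),
        mutant_counts=np.asarray(mut_counts),
    )


def _ratio(n_mut: float, n_wt: float) -> float:
    return n_mut / n_wt if n_wt > 0 else math.inf


def doubling_time_term(tau1: float, tau2: float) -> float:
    """Selection per generation from a doubling-time difference alone,
    ``ln 2 * (tau1/tau2 - 1)``."""
    _check_taus(tau1, tau2)
    return math.log(2.0) * (tau1 / tau2 - 1.0)


def lag_term(lam1: float, lam2: float, tau2: float, m: int) -> float:
    """Selection per generation from a lag difference alone,
    ``ln 2 * (lam1 - lam2) / (M * tau2)``.

    Decreases with more doublings per cycle and with a longer mutant
    doubling time: the one-off head start is amortized over the cycle.
    """
    if tau2 <= 0:
        raise ValueError("doubling times must be > 0")
    return math.log(2.0) * (lam1 - lam2) / (m * tau2)


def analytic_selection_coefficient(
    lam1: float, tau1: float, lam2: float, tau2: float, m: int
) -> float:
    """Closed-form per-generation selection coefficient of the mutant.

    Assumes the wild type dominates the culture so that the cycle ends at
    ``lam1 + M*tau1``; the doubling-time and lag contributions are exactly
    additive.  Valid as a per-cycle rate while the mutant is rare.  The
    derivation assumes ``lam2 <= lam1``; the expression is evaluated as
    written otherwise, with a warning.
    """
    _check_taus(tau1, tau2)
    if lam2 > lam1:
        warnings.warn(
            "analytic selection coefficient derived under lam2 <= lam1; "
            "evaluating the expression as written",
            stacklevel=2,
        )
    return doubling_time_term(tau1, tau2) + lag_term(lam1, lam2, tau2, m)


def _check_taus(tau1: float, tau2: float) -> None:
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("doubling times must be > 0")


def regress_selection_coefficient(
    traj: CompetitionTrajectory,
    include_t0: bool = True,
    censor_wt_below: float | None = 1.0,
) -> float:
    """Estimate the selection coefficient as the OLS slope of ``ln r``
    against cumulative generations.

    By default the regression includes the ``t = 0`` point and stops once
    the wild type is effectively extinct: cycle ends are included up to and
    including the first one at which the diluted wild-type subpopulation
    falls below ``censor_wt_below`` cells (one cell by default).  Past that
    point the bottleneck no longer carries a single wild-type cell and the
    ratio ceases to describe a competition.  Pass ``censor_wt_below=None``
    to regress over every recorded cycle.

    The fitted slope is stored on the trajectory and returned.
    """
    lnr = np.log(traj.ratios)
    gens = traj.generations
    if censor_wt_below is not None:
        dead = np.flatnonzero(traj.wt_counts < censor_wt_below)
        if dead.size:
            stop = dead[0] + 1  # include the crossing point itself
            lnr, gens = lnr[:stop], gens[:stop]
    if not include_t0:
        lnr, gens = lnr[1:], gens[1:]
    finite = np.isfinite(lnr)
    if finite.sum() < 3:
        raise ValueError(
            "need at least 3 finite ln-ratio points (subpopulation extinct?)"
        )
    slope = np.polyfit(gens[finite], lnr[finite], 1)[0]
    traj.selection_coefficient = float(slope)
    return float(slope)
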