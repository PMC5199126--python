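"""Small closed-form estimators for mutation-rate and variant-table work.

* Fluctuation-assay (p0 method) loss-of-function mutation rate,
  ``mu = -ln(P0) / N``.
* Poisson probability of adaptive variants standing in clonally expanded
  founder populations.
* The confidence filter applied to population-sequencing variant
  trajectories before interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FluctuationExperiment",
    "fluctuation_mutation_rate",
    "standing_variant_probability",
    "filter_variant_trajectories",
]

REQUIRED_VARIANT_COLUMNS = ("variant_id", "time_point", "read_depth", "frequency")


@dataclass(frozen=True)
class FluctuationExperiment:
    """A p0-method fluctuation assay: parallel cultures grown from few
    cells, scored for the fraction ``p_zero`` with no resistant colonies,
    each culture containing ``cells_per_culture`` cells at plating."""

    n_cultures: int
    p_zero: float
    cells_per_culture: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_zero <= 1.0:
            raise ValueError("p_zero must be in [0, 1]")
        if self.cells_per_culture < 1:
            raise ValueError("cells_per_culture must be >= 1")


def fluctuation_mutation_rate(exp: FluctuationExperiment) -> float:
    """Mutations per locus per division from the zero-class fraction.

    Mutation events per culture are Poisson with mean ``mu * N``, so the
    probability of a culture with no mutants is ``exp(-mu * N)`` and
    ``mu = -ln(P0) / N``.  ``P0 = 0`` leaves the estimator undefined
    (every culture had mutants; repeat with fewer cells per culture).
    """
    if exp.p_zero == 0:
        raise ValueError(
            "p_zero = 0: estimator undefined; repeat the assay at higher "
            "dilution so some cultures stay mutant-free"
        )
    return -math.log(exp.p_zero) / exp.cells_per_culture


def standing_variant_probability(
    final_population: float, beneficial_rate_per_division: float, n_populations: int = 1
) -> tuple[float, float]:
    """Probability that clonally expanded founders harbour standing
    adaptive variants.

    A clonal expansion from one cell to ``final_population`` cells takes
    ``final_population - 1`` divisions; with Poisson-distributed adaptive
    mutations at the given per-division rate, one population carries at
    least one standing variant with probability ``1 - exp(-lambda)``, and
    all ``n_populations`` independently expanded populations do with that
    probability to the ``n``-th power.
    """
    if final_population < 1:
        raise ValueError("final_population must be >= 1")
    if beneficial_rate_per_division < 0:
        raise ValueError("rate must be >= 0")
    divisions = final_population - 1
    lam = beneficial_rate_per_division * divisions
    p_single = -math.expm1(-lam)
    return p_single, p_single**n_populations


def filter_variant_trajectories(
    table: pd.DataFrame,
    min_depth: float = 100.0,
    min_freq: float = 0.10,
    min_timepoints: int = 2,
    sift_cutoff: float = 0.05,
    depth_mode: str = "total",
) -> pd.DataFrame:
    """Confidence filter for variant frequency trajectories.

    A variant is kept iff its read depth exceeds ``min_depth`` (summed
    over time points by default; ``depth_mode="per_timepoint"`` requires
    every time point to pass instead), its frequency exceeds ``min_freq``
    at ``min_timepoints`` or more time points, and — when a ``sift_score``
    column is present — its SIFT score is below ``sift_cutoff`` (missing
    scores pass).  All rows of surviving variants are returned.
    """
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"variant table lacks required column(s): {missing}")
    if depth_mode not in ("total", "per_timepoint"):
        raise ValueError("depth_mode must be 'total' or 'per_timepoint'")
    if table.empty:
        return table.copy()

    grouped = table.groupby("variant_id")
    if depth_mode == "total":
        depth_ok = grouped["read_depth"].sum() > min_depth
    else:
        depth_ok = grouped["read_depth"].min() > min_depth
    freq_ok = grouped["frequency"].apply(lambda f: (f > min_freq).sum()) >= min_timepoints
    keep = depth_ok & freq_ok
    if "sift_score" in table.columns:
        sift = grouped["sift_score"].first()
        keep &= sift.isna() | (sift < sift_cutoff)
    kept_ids = keep[keep].index
    return table[table["variant_id"].isin(kept_ids)].reset_index(drop=True)
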