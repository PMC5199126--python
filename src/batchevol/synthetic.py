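"""Synthetic inputs with known ground truth.

Everything the analysis stages consume can be generated here: plate-reader
growth curves (logistic rise after a lag, Gaussian observation noise,
20-min cadence over 72 h), whole plates with founder-control wells at
randomized positions, and variant-trajectory tables with binomial read
sampling at Poisson depths.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from batchevol.phenomics import GrowthCurve

__all__ = [
    "SyntheticCurveSpec",
    "generate_growth_curve",
    "generate_plate",
    "generate_variant_table",
]


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Ground truth for one synthetic growth curve.

    The population sits at the inoculum size until ``lag`` minutes, then
    grows logistically with intrinsic doubling time ``doubling_time``
    toward ``carrying_capacity``; observed OD adds the instrument baseline
    and Gaussian noise.  The default inoculum (0.001 OD) corresponds to
    the ~1e5 cells used to found a microplate well, below the noise floor
    of a plate reader.
    """

    lag: float = 276.6
    doubling_time: float = 130.2
    carrying_capacity: float = 1.25
    baseline: float = 0.09
    noise_sd: float = 0.002
    inoculum: float = 1e-3
    cadence: float = 20.0
    duration: float = 4320.0

    def __post_init__(self) -> None:
        if min(self.lag, self.doubling_time, self.carrying_capacity, self.baseline,
               self.inoculum, self.cadence, self.duration) <= 0 and self.lag != 0:
            raise ValueError("curve parameters must be positive (lag may be 0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _logistic_size(spec: SyntheticCurveSpec, t: np.ndarray) -> np.ndarray:
    r = np.log(2.0) / spec.doubling_time
    k, n0 = spec.carrying_capacity, spec.inoculum
    dt = np.maximum(t - spec.lag, 0.0)
    grown = np.exp(r * dt)
    return k * n0 * grown / (k + n0 * (grown - 1.0))


def generate_growth_curve(
    spec: SyntheticCurveSpec,
    rng: np.random.Generator | None = None,
    well_id: str = "",
) -> GrowthCurve:
    """One synthetic time-OD series; pass ``rng=None`` only for noiseless
    specs (noise requires a seeded generator for reproducibility)."""
    t = np.arange(0.0, spec.duration + spec.cadence / 2, spec.cadence)
    od = spec.baseline + _logistic_size(spec, t)
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("a seeded rng is required for noisy curves")
        od = od + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return GrowthCurve(t, od, well_id)


def generate_plate(
    genotype_specs: dict,
    n_founder_controls: int,
    founder_spec: SyntheticCurveSpec | None = None,
    rng: np.random.Generator | None = None,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A wide-format plate table plus its companion layout table.

    ``genotype_specs`` maps genotype labels to curve specs; each genotype
    gets ``n_replicates`` wells and founder controls are interleaved at
    randomized positions.  The layout table records well, genotype and a
    founder flag; ``founder_spec`` defaults to the stressed wild type
    (lag 804.8 min, doubling 162.3 min).
    """
    if not genotype_specs and n_founder_controls == 0:
        raise ValueError("empty plate")
    rng = rng if rng is not None else np.random.default_rng()
    if founder_spec is None:
        founder_spec = SyntheticCurveSpec(lag=804.8, doubling_time=162.3)
    entries = [("founder", founder_spec, True)] * n_founder_controls
    for label, spec in genotype_specs.items():
        entries.extend([(label, spec, False)] * n_replicates)
    order = rng.permutation(len(entries))
    wells, layout_rows, columns = [], [], {}
    cadence_spec = entries[0][1]
    t = np.arange(0.0, cadence_spec.duration + cadence_spec.cadence / 2,
                  cadence_spec.cadence)
    columns["time_min"] = t
    for pos, idx in enumerate(order):
        label, spec, is_founder = entries[idx]
        well = f"{chr(ord('A') + pos // 12)}{pos % 12 + 1}"
        curve = generate_growth_curve(spec, rng, well)
        columns[well] = curve.od
        layout_rows.append({"well": well, "genotype": label, "is_founder": is_founder})
    plate = pd.DataFrame(columns)
    layout = pd.DataFrame(layout_rows).sort_values("well").reset_index(drop=True)
    return plate, layout


def generate_variant_table(
    true_trajectories: dict,
    mean_depth: float,
    rng: np.random.Generator,
    time_points: list | None = None,
    sift_scores: dict | None = None,
) -> pd.DataFrame:
    """Sequencing-like observation of known allele-frequency trajectories.

    ``true_trajectories`` maps variant ids to per-time-point frequencies.
    Depth is Poisson(``mean_depth``) per variant and time point; alternate
    reads are binomial at the true frequency; observed frequency is their
    ratio (zero at zero depth).
    """
    rows = []
    for vid, freqs in true_trajectories.items():
        freqs = np.asarray(freqs, dtype=float)
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError(f"frequencies of {vid!r} outside [0, 1]")
        tps = time_points if time_points is not None else list(range(len(freqs)))
        depths = rng.poisson(mean_depth, size=len(freqs))
        reads = rng.binomial(depths, freqs)
        for tp, depth, alt, true_f in zip(tps, depths, reads, freqs):
            row = {
                "variant_id": vid,
                "time_point": tp,
                "read_depth": int(depth),
                "frequency": alt / depth if depth > 0 else 0.0,
                "true_frequency": true_f,
            }
            if sift_scores is not None:
                row["sift_score"] = sift_scores.get(vid, np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
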