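"""Genotype-structured stochastic simulator of serial-batch evolution.

Cells with identical genotypes divide synchronously, so the population
state is a mapping from genotype to an integer cell count plus that
genotype's next division time.  Within a batch cycle a genotype first
divides at ``lag + doubling_time`` (the lag is the idle period before
growth resumes) and every ``doubling_time`` thereafter; division events
are processed in time order, doubling the genotype's count, until the
first event at which the total reaches ``2**M * N``.  A mutation hook may
convert some just-divided daughters into new single-cell genotypes whose
own clock starts at the division event.  The next cycle is founded by
drawing exactly ``N`` cells without replacement across genotypes
(multivariate hypergeometric), after which lags restart.

There is no cell death, no ploidy change and no interaction between cells;
drift enters only through the bottleneck.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from batchevol.deterministic import BatchProtocol

__all__ = [
    "GenotypePhenotype",
    "PopulationState",
    "ReplicateResult",
    "advance_cycle",
    "bottleneck_sample",
    "run_competition_ibm",
    "run_evolution",
]

#: hook contract: (carrier phenotype, number of daughters, rng) -> phenotypes
#: of newly mutated daughters (each founds a single-cell genotype)
MutationHook = Callable[["GenotypePhenotype", int, np.random.Generator], list]


@dataclass(frozen=True)
class GenotypePhenotype:
    """Heritable phenotype of a genotype: lag and doubling time in minutes,
    plus the set of allele-class labels it carries (empty for the
    founder)."""

    lag: float
    doubling_time: float
    alleles: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lag) and math.isfinite(self.doubling_time)):
            raise ValueError("lag and doubling_time must be finite")
        if self.lag < 0 or self.doubling_time <= 0:
            raise ValueError("lag must be >= 0 and doubling_time > 0")
        object.__setattr__(self, "alleles", frozenset(self.alleles))


@dataclass
class PopulationState:
    """Evolving state of one simulated population.

    ``counts``, ``phenotypes`` and ``next_division`` are keyed by an
    integer genotype id; extinct genotypes are pruned at each bottleneck.
    """

    counts: dict
    phenotypes: dict
    next_division: dict = field(default_factory=dict)
    cycle_index: int = 0
    elapsed_generations: float = 0.0
    founder_id: int = 0
    _next_id: int = 0

    @classmethod
    def from_counts(cls, genotypes: Mapping[GenotypePhenotype, int]) -> "PopulationState":
        counts, phenotypes = {}, {}
        for gid, (phen, count) in enumerate(genotypes.items()):
            counts[gid] = int(count)
            phenotypes[gid] = phen
        return cls(counts=counts, phenotypes=phenotypes, _next_id=len(counts))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict:
        tot = self.total
        return {gid: c / tot for gid, c in self.counts.items()}

    def allele_frequencies(self) -> dict:
        """Fraction of cells carrying each allele class (classes may
        overlap when genotypes carry several alleles)."""
        tot = self.total
        freqs: dict = {}
        for gid, c in self.counts.items():
            for allele in self.phenotypes[gid].alleles:
                freqs[allele] = freqs.get(allele, 0) + c
        return {a: c / tot for a, c in freqs.items()}

    def mean_phenotype(self) -> tuple[float, float]:
        """Population-mean (lag, doubling time)."""
        tot = self.total
        lag = sum(self.phenotypes[g].lag * c for g, c in self.counts.items())
        dbl = sum(
            self.phenotypes[g].doubling_time * c for g, c in self.counts.items()
        )
        return lag / tot, dbl / tot


@dataclass
class ReplicateResult:
    """Per-replicate record of a simulated competition or evolution run."""

    frequency_series: list
    loss_flag: bool = False
    founder_extinct_generation: float | None = None
    mean_lag_series: list | None = None
    mean_doubling_series: list | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cycle, entry in enumerate(self.frequency_series):
            if isinstance(entry, dict):
                for key, freq in sorted(entry.items()):
                    rows.append((cycle, key, freq))
            else:
                rows.append((cycle, "mutant", entry))
        return pd.DataFrame(rows, columns=["cycle", "class", "frequency"])


def advance_cycle(
    state: PopulationState,
    protocol: BatchProtocol,
    mutation_hook: MutationHook | None,
    rng: np.random.Generator,
) -> PopulationState:
    """Grow the population through one batch cycle (no bottleneck).

    Division events are processed in time order; simultaneous events are
    processed in genotype-id order and the stopping condition (total
    ``>= 2**M * N``) is checked after every genotype's doubling, so the
    realized total may overshoot by at most one genotype's count.  Returns
    the state at its pre-bottleneck peak.
    """
    counts, phens = state.counts, state.phenotypes
    heap = []
    for gid in counts:
        t0 = phens[gid].lag + phens[gid].doubling_time
        state.next_division[gid] = t0
        heap.append((t0, gid))
    heapq.heapify(heap)
    total = state.total
    cap = protocol.cycle_capacity
    while total < cap and heap:
        t = heap[0][0]
        batch = []
        while heap and heap[0][0] == t:
            batch.append(heapq.heappop(heap)[1])
        batch.sort()
        stop = False
        for gid in batch:
            n = counts.get(gid, 0)
            if n <= 0:
                continue
            counts[gid] = 2 * n
            total += n
            if mutation_hook is not None:
                mutants = mutation_hook(phens[gid], n, rng)
                if len(mutants) > n:
                    raise ValueError(
                        f"mutation hook produced {len(mutants)} mutants from "
                        f"{n} dividing cells"
                    )
                counts[gid] -= len(mutants)
                for phen in mutants:
                    new_id = state._next_id
                    state._next_id += 1
                    counts[new_id] = 1
                    phens[new_id] = phen
                    nd = t + phen.doubling_time
                    state.next_division[new_id] = nd
                    heapq.heappush(heap, (nd, new_id))
            nd = t + phens[gid].doubling_time
            state.next_division[gid] = nd
            heapq.heappush(heap, (nd, gid))
            if total >= cap:
                stop = True
                break
        if stop:
            break
    return state


def bottleneck_sample(
    counts: Mapping[int, int], n: int, rng: np.random.Generator
) -> dict:
    """Draw exactly ``n`` cells without replacement across genotypes.

    Multivariate hypergeometric: each genotype's expected survivor count is
    ``n * count / total``.  Genotypes that receive no cells are dropped.
    """
    gids = sorted(counts)
    colors = np.array([counts[g] for g in gids], dtype=np.int64)
    if colors.sum() < n:
        raise ValueError(f"cannot sample {n} cells from {colors.sum()}")
    sampled = rng.multivariate_hypergeometric(colors, n)
    return {g: int(c) for g, c in zip(gids, sampled) if c > 0}


def _finish_cycle(
    state: PopulationState,
    protocol: BatchProtocol,
    rng: np.random.Generator,
    deterministic_dilution: bool = False,
) -> None:
    """Apply the bottleneck in place and advance the cycle counters."""
    if deterministic_dilution:
        tot = state.total
        scale = protocol.bottleneck / tot
        state.counts = {g: c * scale for g, c in state.counts.items() if c > 0}
    else:
        state.counts = bottleneck_sample(state.counts, protocol.bottleneck, rng)
    state.phenotypes = {g: state.phenotypes[g] for g in state.counts}
    state.next_division = {}
    state.cycle_index += 1
    state.elapsed_generations += protocol.doublings_per_cycle


def run_competition_ibm(
    wt: GenotypePhenotype,
    mutant: GenotypePhenotype,
    protocol: BatchProtocol,
    n_replicates: int = 25,
    seed: int | None = None,
    deterministic_dilution: bool = False,
) -> list[ReplicateResult]:
    """Competition assays started from a single mutant cell.

    Each replicate founds cycle 1 with ``N - 1`` wild-type cells and one
    mutant cell, runs ``n_cycles`` of growth plus bottleneck with no
    further mutation, and records the mutant frequency at each
    post-bottleneck state.  ``loss_flag`` marks replicates in which the
    mutant lineage hit zero.  With ``deterministic_dilution`` the
    bottleneck becomes an exact proportional dilution (real-valued
    counts): the drift-free mean-field limit of the same event dynamics.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    results = []
    for rep_seq in seeds:
        rng = np.random.default_rng(rep_seq)
        # built directly so wt and mutant stay distinct genotypes even when
        # their phenotypes are identical (neutral competition)
        state = PopulationState(
            counts={0: protocol.bottleneck - 1, 1: 1},
            phenotypes={0: wt, 1: mutant},
            _next_id=2,
        )
        mutant_id = 1
        freqs = []
        lost = False
        for _ in range(protocol.n_cycles):
            advance_cycle(state, protocol, None, rng)
            _finish_cycle(state, protocol, rng, deterministic_dilution)
            m = state.counts.get(mutant_id, 0)
            freqs.append(m / protocol.bottleneck)
            if m == 0:
                lost = True
                break
        results.append(
            ReplicateResult(
                frequency_series=freqs,
                loss_flag=lost,
                seed=int(rep_seq.generate_state(1)[0] % 2**31),
            )
        )
    return results


def run_evolution(
    founder: GenotypePhenotype,
    mutation_model,
    protocol: BatchProtocol,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReplicateResult:
    """One population evolving from a clonal founder with de novo mutation.

    Runs ``n_cycles`` of growth (with the mutation model's ``spawn`` hook)
    plus bottleneck; records per-cycle allele-class frequencies,
    population-mean phenotypes and the generation at which the founder
    genotype first disappears from a post-bottleneck population.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    hook = mutation_model.spawn if mutation_model is not None else None
    state = PopulationState.from_counts({founder: protocol.bottleneck})
    allele_series: list = [state.allele_frequencies()]
    lags, dbls = [], []
    lag0, dbl0 = state.mean_phenotype()
    lags.append(lag0)
    dbls.append(dbl0)
    founder_gone: float | None = None
    for _ in range(protocol.n_cycles):
        advance_cycle(state, protocol, hook, rng)
        _finish_cycle(state, protocol, rng)
        allele_series.append(state.allele_frequencies())
        lag, dbl = state.mean_phenotype()
        lags.append(lag)
        dbls.append(dbl)
        if founder_gone is None and state.counts.get(state.founder_id, 0) == 0:
            founder_gone = state.cycle_index * protocol.doublings_per_cycle
    return ReplicateResult(
        frequency_series=allele_series,
        loss_flag=False,
        founder_extinct_generation=founder_gone,
        mean_lag_series=lags,
        mean_doubling_series=dbls,
        seed=seed,
    )
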