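"""Genotype-phenotype maps and mutation generators.

Two mutation models plug into the individual-based simulator:

``GammaDfeModel``
    A distribution-of-fitness-effects model.  Each daughter cell mutates
    with probability ``G * mu``; a mutation affects fitness with
    probability ``y`` and, given that, is beneficial with probability
    ``z``.  Effect sizes come from a gamma distribution (shape ``alpha``,
    scale ``beta`` in minutes of wild-type doubling-time change); the raw
    selection coefficient ``s_r`` relates to the doubling-time change
    through ``dT = T_wt * s_r / (s_r + 1)``, truncated at full recovery of
    the unstressed phenotype.  Three map variants control pleiotropy:
    ``M1`` touches doubling time only, ``M2`` drives doubling time and lag
    with one coefficient and one sign (positive pleiotropy), ``M3`` samples
    magnitude and sign independently per component.  Consecutive beneficial
    mutations show diminishing returns: their wild-type effect is scaled by
    the carrier's remaining distance to the unstressed optimum.

``TargetedLociModel``
    Beneficial mutations at three named loci (FPS1 and ASK10
    loss-of-function point mutations, ACR3 duplication) occurring at
    per-division rates given by mutational target sizes times a per-bp
    rate; carriers get empirical phenotypes with complete negative
    epistasis between alleles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from batchevol.deterministic import analytic_selection_coefficient
from batchevol.ibm import GenotypePhenotype

__all__ = [
    "MutationParameters",
    "PhenotypeBounds",
    "Mutation",
    "LocusTarget",
    "GammaDfeModel",
    "TargetedLociModel",
    "sample_mutation",
    "effect_on_doubling",
    "effect_on_lag",
    "apply_diminishing_returns",
    "targeted_mutation_rates",
    "combine_targeted_genotype",
    "parameter_grid",
    "default_locus_targets",
    "BETA_GRID",
]

LN2 = math.log(2.0)

#: gamma-scale grid (minutes); 33 min is the empirical point estimate
BETA_GRID = (13.3, 20.0, 27.35, 33.0, 40.0, 47.0)


@dataclass(frozen=True)
class PhenotypeBounds:
    """Wild-type phenotypes with and without arsenic stress (minutes).

    Adaptation moves phenotypes from the stressed values towards the
    unstressed ones; effects are truncated so neither bound is crossed.
    """

    stressed_doubling: float = 162.0
    stressed_lag: float = 805.0
    unstressed_doubling: float = 126.0
    unstressed_lag: float = 271.0

    def __post_init__(self) -> None:
        if not (0 < self.unstressed_doubling < self.stressed_doubling):
            raise ValueError("unstressed doubling must be < stressed doubling")
        if not (0 <= self.unstressed_lag < self.stressed_lag):
            raise ValueError("unstressed lag must be < stressed lag")

    @property
    def doubling_span(self) -> float:
        return self.stressed_doubling - self.unstressed_doubling

    @property
    def lag_span(self) -> float:
        return self.stressed_lag - self.unstressed_lag

    def founder(self) -> GenotypePhenotype:
        return GenotypePhenotype(self.stressed_lag, self.stressed_doubling)

    def clip(self, lag: float, doubling: float) -> tuple[float, float]:
        return (
            min(max(lag, self.unstressed_lag), self.stressed_lag),
            min(max(doubling, self.unstressed_doubling), self.stressed_doubling),
        )


@dataclass(frozen=True)
class MutationParameters:
    """Rates and effect-size distribution of the DFE model.

    ``base_rate_per_bp`` is the genomic point-mutation rate
    (mutations/bp/division); ``genome_size`` converts it to a per-division
    mutation probability.  ``fraction_affecting`` (y) and
    ``fraction_beneficial_of_affecting`` (z) partition mutations into
    neutral / deleterious / beneficial.  ``gamma_shape`` and
    ``gamma_scale`` parameterize the effect-size distribution (scale in
    minutes of doubling-time change).
    """

    base_rate_per_bp: float = 0.33e-9
    genome_size: float = 1.2e7
    fraction_affecting: float = 0.034
    fraction_beneficial_of_affecting: float = 0.13
    gamma_shape: float = 2.0
    gamma_scale: float = 33.0
    map_variant: str = "M2"

    def __post_init__(self) -> None:
        for name in ("fraction_affecting", "fraction_beneficial_of_affecting"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.base_rate_per_bp < 0 or self.genome_size <= 0:
            raise ValueError("rates and genome size must be positive")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be > 0")
        if self.map_variant not in ("M1", "M2", "M3"):
            raise ValueError(f"map_variant must be M1, M2 or M3, got {self.map_variant!r}")

    @property
    def per_division_rate(self) -> float:
        """Probability that a daughter cell carries a new mutation."""
        return min(self.base_rate_per_bp * self.genome_size, 1.0)


@dataclass(frozen=True)
class Mutation:
    """One sampled mutation and its phenotype deltas.

    Deltas are additive changes to the carrier's phenotype (minutes), so
    beneficial mutations have ``delta_doubling <= 0`` and
    ``delta_lag <= 0``.
    """

    raw_coefficient: float
    per_generation_s: float
    beneficial: bool
    delta_doubling: float = 0.0
    delta_lag: float = 0.0
    locus_class: str | None = None


@dataclass(frozen=True)
class LocusTarget:
    """A named beneficial-mutation channel.

    ``snp_target_size`` is the number of base pairs whose mutation is
    beneficial (for point-mutation channels); ``duplication_rate`` is a
    direct per-division event rate (for the duplication channel).  The
    carrier phenotype is the empirical reconstructed-mutant phenotype.
    """

    gene: str
    effect_lag: float
    effect_doubling: float
    snp_target_size: float = 0.0
    duplication_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.snp_target_size < 0 or self.duplication_rate < 0:
            raise ValueError("target sizes and rates must be >= 0")
        if self.snp_target_size > 0 and self.duplication_rate > 0:
            raise ValueError("a locus has either a SNP or a duplication channel")


def default_locus_targets() -> tuple[LocusTarget, ...]:
    """The three arsenic-adaptation loci with empirical carrier phenotypes.

    The ACR3 duplication rate is the empirical per-division estimate.  SNP
    target sizes are synthetic placeholders (the real values derive from a
    conservation-score screen of each coding sequence and are supplied via
    configuration in any serious use).
    """
    return (
        LocusTarget("FPS1", effect_lag=276.6, effect_doubling=130.2, snp_target_size=150.0),
        LocusTarget("ASK10", effect_lag=503.3, effect_doubling=134.6, snp_target_size=100.0),
        LocusTarget("ACR3", effect_lag=630.4, effect_doubling=122.8, duplication_rate=3e-7),
    )


def effect_on_doubling(s_r: float, t_wt: float, t_wt_n: float) -> float:
    """Doubling-time change (minutes) of a mutation with raw coefficient
    ``s_r`` arising in a wild-type cell: ``T_wt * s_r / (s_r + 1)``,
    truncated at full recovery ``T_wt - T_wt,N``."""
    if s_r == -1:
        raise ValueError("s_r = -1 is a pole of the conversion")
    if math.isinf(s_r):  # limit of s_r/(s_r+1) -> 1; the cap applies anyway
        return t_wt - t_wt_n
    return min(t_wt * s_r / (s_r + 1.0), t_wt - t_wt_n)


def effect_on_lag(
    s_r: float, tau_carrier: float, m: int, l_wt: float, l_wt_n: float
) -> float:
    """Lag change (minutes) of a mutation with raw coefficient ``s_r``.

    Inverts the lag term of the analytic selection coefficient,
    ``s = ln 2 * d_lag / (M * tau)``, for the sampled per-generation
    coefficient ``s = s_r * ln 2``; the ``ln 2`` factors cancel, leaving
    ``d_lag = s_r * M * tau``.  Truncated at full recovery
    ``L_wt - L_wt,N``.
    """
    if tau_carrier <= 0:
        raise ValueError("doubling time must be > 0")
    return min(s_r * m * tau_carrier, l_wt - l_wt_n)


def apply_diminishing_returns(
    delta_wt: float, current_value: float, stressed_ref: float, unstressed_ref: float
) -> float:
    """Scale a wild-type effect by the carrier's remaining adaptive gap.

    A carrier already at the unstressed optimum gains nothing; a wild-type
    carrier gets the full effect; interpolation is linear in between.
    """
    if stressed_ref == unstressed_ref:
        raise ValueError("degenerate references: stressed == unstressed")
    frac = (current_value - unstressed_ref) / (stressed_ref - unstressed_ref)
    return delta_wt * frac


def _raw_coefficient(delta_t_raw: float, t_wt: float) -> float:
    """Invert the doubling-time conversion: the ``s_r`` whose wild-type
    effect would be ``delta_t_raw`` minutes.  Effects at or beyond the
    wild-type doubling time map to an arbitrarily large coefficient and are
    handled by downstream truncation."""
    if delta_t_raw >= t_wt:
        return math.inf
    return delta_t_raw / (t_wt - delta_t_raw)


def sample_mutation(
    params: MutationParameters,
    carrier: GenotypePhenotype,
    bounds: PhenotypeBounds,
    rng: np.random.Generator,
    doublings_per_cycle: int = 5,
) -> Mutation | None:
    """Sample at most one mutation for a single daughter cell.

    Returns ``None`` with probability ``1 - G*mu``; otherwise classifies
    the mutation (neutral / deleterious / beneficial) and converts the
    gamma-sampled effect into phenotype deltas according to the map
    variant.  This is the reference single-cell path; the simulator uses
    the vectorized :meth:`GammaDfeModel.spawn`.
    """
    if rng.random() >= params.per_division_rate:
        return None
    if rng.random() >= params.fraction_affecting:
        return Mutation(0.0, 0.0, beneficial=False)  # neutral: zero deltas
    model = GammaDfeModel(params, bounds, doublings_per_cycle)
    beneficial = rng.random() < params.fraction_beneficial_of_affecting
    return model.draw_affecting(carrier, beneficial, rng)


class GammaDfeModel:
    """Gamma distribution-of-fitness-effects mutation model.

    Provides both the per-daughter reference sampler and the vectorized
    per-division hook used by the simulator (which skips neutral mutations:
    they leave the phenotype untouched and are irrelevant to the
    dynamics).
    """

    def __init__(
        self,
        params: MutationParameters,
        bounds: PhenotypeBounds | None = None,
        doublings_per_cycle: int = 5,
    ):
        self.params = params
        self.bounds = bounds if bounds is not None else PhenotypeBounds()
        self.m = doublings_per_cycle
        # cached per-daughter probability of a fitness-affecting mutation
        self._p_affect = params.per_division_rate * params.fraction_affecting

    # -- effect construction -------------------------------------------------

    def draw_affecting(
        self, carrier: GenotypePhenotype, beneficial: bool, rng: np.random.Generator
    ) -> Mutation:
        """Draw one fitness-affecting mutation for the given carrier."""
        p, b = self.params, self.bounds
        s_r = self._draw_s_r(rng)
        if p.map_variant == "M1":
            d_dbl = self._doubling_delta(s_r, carrier, beneficial)
            d_lag = 0.0
        elif p.map_variant == "M2":
            d_dbl = self._doubling_delta(s_r, carrier, beneficial)
            d_lag = self._lag_delta(s_r, carrier, beneficial)
        else:  # M3: independent coefficient and sign per component
            s_r_lag = self._draw_s_r(rng)
            ben_lag = rng.random() < p.fraction_beneficial_of_affecting
            d_dbl = self._doubling_delta(s_r, carrier, beneficial)
            d_lag = self._lag_delta(s_r_lag, carrier, ben_lag)
        return Mutation(
            raw_coefficient=s_r,
            per_generation_s=s_r * LN2,
            beneficial=beneficial,
            delta_doubling=d_dbl,
            delta_lag=d_lag,
        )

    def _draw_s_r(self, rng: np.random.Generator) -> float:
        raw = rng.gamma(self.params.gamma_shape, self.params.gamma_scale)
        return _raw_coefficient(raw, self.bounds.stressed_doubling)

    def _doubling_delta(
        self, s_r: float, carrier: GenotypePhenotype, beneficial: bool
    ) -> float:
        b = self.bounds
        d_wt = effect_on_doubling(s_r, b.stressed_doubling, b.unstressed_doubling)
        if beneficial:
            scaled = apply_diminishing_returns(
                d_wt, carrier.doubling_time, b.stressed_doubling, b.unstressed_doubling
            )
            return -scaled
        # deleterious: same magnitude, opposite sign; carriers never exceed
        # the stressed founder phenotype (enforced again by clipping)
        return min(d_wt, b.stressed_doubling - carrier.doubling_time)

    def _lag_delta(
        self, s_r: float, carrier: GenotypePhenotype, beneficial: bool
    ) -> float:
        b = self.bounds
        d_wt = effect_on_lag(
            s_r, carrier.doubling_time, self.m, b.stressed_lag, b.unstressed_lag
        )
        if beneficial:
            scaled = apply_diminishing_returns(
                d_wt, carrier.lag, b.stressed_lag, b.unstressed_lag
            )
            return -scaled
        return min(d_wt, b.stressed_lag - carrier.lag)

    def mutate(
        self, carrier: GenotypePhenotype, mutation: Mutation
    ) -> GenotypePhenotype:
        lag, dbl = self.bounds.clip(
            carrier.lag + mutation.delta_lag,
            carrier.doubling_time + mutation.delta_doubling,
        )
        return GenotypePhenotype(lag, dbl)

    # -- simulator hook ------------------------------------------------------

    def spawn(
        self, carrier: GenotypePhenotype, n_daughters: int, rng: np.random.Generator
    ) -> list[GenotypePhenotype]:
        """Phenotypes of the fitness-affected daughters of one division
        event (neutral mutants omitted; they stay in the parent class)."""
        p_affect = self._p_affect
        if p_affect <= 0.0:
            return []
        k = _fast_binomial(n_daughters, p_affect, rng)
        if k == 0:
            return []
        out = []
        z = self.params.fraction_beneficial_of_affecting
        for beneficial in rng.random(k) < z:
            mut = self.draw_affecting(carrier, bool(beneficial), rng)
            phen = self.mutate(carrier, mut)
            # bound truncation can null an effect (deleterious hits on a
            # founder-bound carrier, beneficial hits on a fully adapted
            # one); such daughters stay in the parent genotype class
            if phen.lag != carrier.lag or phen.doubling_time != carrier.doubling_time:
                out.append(phen)
        return out


def _fast_binomial(n: int, p: float, rng: np.random.Generator) -> int:
    """Exact Binomial(n, p) draw optimized for the common no-mutation case.

    Most division events carry no mutation; a single uniform decides that
    outcome, and the (rare) positive count is drawn by inverse CDF of the
    zero-truncated binomial.  Falls back to the generator's sampler when
    ``n * p`` is not small.
    """
    if n * p >= 0.1:
        return int(rng.binomial(n, p))
    p_any = -math.expm1(n * math.log1p(-p))
    if rng.random() >= p_any:
        return 0
    v = rng.random() * p_any
    odds = p / (1.0 - p)
    pk = n * p * (1.0 - p) ** (n - 1)  # P(k = 1)
    cum, k = pk, 1
    while v > cum and k < n:
        pk *= (n - k) / (k + 1.0) * odds
        k += 1
        cum += pk
    return k


def targeted_mutation_rates(
    targets: Sequence[LocusTarget],
    base_rate_per_bp: float = 0.33e-9,
    multiplier: float = 1.0,
) -> dict[str, float]:
    """Per-division beneficial-mutation probability of each allele class.

    SNP channels scale the target size by the per-bp rate; duplication
    channels use their event rate directly.  All channels scale linearly
    with the global rate multiplier.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    rates = {}
    for t in targets:
        if t.duplication_rate > 0:
            rates[t.gene] = t.duplication_rate * multiplier
        else:
            rates[t.gene] = t.snp_target_size * base_rate_per_bp * multiplier
    return rates


def combine_targeted_genotype(
    alleles: Iterable[str],
    targets: Sequence[LocusTarget],
    bounds: PhenotypeBounds | None = None,
    doublings_per_cycle: int = 5,
) -> GenotypePhenotype:
    """Phenotype of a cell carrying the given allele classes.

    Complete negative epistasis: the phenotype is that of the single best
    allele and further alleles confer nothing.  "Best" means fittest under
    the batch regime — the largest analytic selection coefficient against
    the stressed founder (lag and doubling time jointly), ties broken by
    smaller doubling time then smaller lag.  No alleles gives the stressed
    founder.
    """
    bounds = bounds if bounds is not None else PhenotypeBounds()
    by_gene = {t.gene: t for t in targets}
    alleles = set(alleles)
    unknown = alleles - by_gene.keys()
    if unknown:
        raise KeyError(f"unknown allele class(es): {sorted(unknown)}")
    if not alleles:
        return bounds.founder()
    best = max(
        (by_gene[a] for a in alleles),
        key=lambda t: (
            analytic_selection_coefficient(
                bounds.stressed_lag,
                bounds.stressed_doubling,
                t.effect_lag,
                t.effect_doubling,
                doublings_per_cycle,
            ),
            -t.effect_doubling,
            -t.effect_lag,
        ),
    )
    return GenotypePhenotype(
        best.effect_lag, best.effect_doubling, alleles=frozenset(alleles)
    )


class TargetedLociModel:
    """Beneficial mutations restricted to named locus channels.

    The simulator hook converts a binomial number of daughters per division
    into carriers of one additional allele class each; phenotypes follow
    the complete-negative-epistasis combination rule.
    """

    def __init__(
        self,
        targets: Sequence[LocusTarget] | None = None,
        base_rate_per_bp: float = 0.33e-9,
        multiplier: float = 1.0,
        bounds: PhenotypeBounds | None = None,
    ):
        self.targets = tuple(targets) if targets is not None else default_locus_targets()
        self.bounds = bounds if bounds is not None else PhenotypeBounds()
        self.rates = targeted_mutation_rates(self.targets, base_rate_per_bp, multiplier)
        self._classes = list(self.rates)
        self._probs = np.array([self.rates[c] for c in self._classes])
        self.total_rate = float(self._probs.sum())

    def spawn(
        self, carrier: GenotypePhenotype, n_daughters: int, rng: np.random.Generator
    ) -> list[GenotypePhenotype]:
        if self.total_rate <= 0.0:
            return []
        k = _fast_binomial(n_daughters, min(self.total_rate, 1.0), rng)
        if k == 0:
            return []
        channel_counts = rng.multinomial(k, self._probs / self.total_rate)
        out = []
        for cls, count in zip(self._classes, channel_counts):
            alleles = carrier.alleles | {cls}
            if count and alleles != carrier.alleles:
                phen = combine_targeted_genotype(alleles, self.targets, self.bounds)
                out.extend([phen] * count)
        return out


def parameter_grid(
    base: MutationParameters | None = None,
    fold_factors: Sequence[float] = (1 / 5, 1 / 3, 1.0, 3.0, 5.0),
    beta_grid: Sequence[float] = BETA_GRID,
) -> list[MutationParameters]:
    """Full-factorial grid over mutation rate, affecting fraction,
    beneficial fraction and gamma scale (5 x 5 x 5 x 6 = 750 sets).

    Scaled probabilities are capped at 1.  Use seeded subsampling for
    scaled-down sweeps.
    """
    base = base if base is not None else MutationParameters()
    grid = []
    for f_mu, f_y, f_z, beta in itertools.product(
        fold_factors, fold_factors, fold_factors, beta_grid
    ):
        grid.append(
            replace(
                base,
                base_rate_per_bp=base.base_rate_per_bp * f_mu,
                fraction_affecting=min(base.fraction_affecting * f_y, 1.0),
                fraction_beneficial_of_affecting=min(
                    base.fraction_beneficial_of_affecting * f_z, 1.0
                ),
                gamma_scale=beta,
            )
        )
    return grid
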