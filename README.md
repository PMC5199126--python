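# batchevol

Modelling toolkit for serial-batch (batch-to-batch) microbial experimental
evolution, built around the arsenite-adaptation system in budding yeast:
populations cycle through a lag phase, synchronous exponential growth to a
fixed number of population doublings `M`, and a bottleneck of `N` cells
that founds the next cycle. Fitness decomposes into two heritable
components — the lag λ (time to the first cell division) and the doubling
time τ — and the package answers questions like: how strongly is a mutation
that improves both components selected, how often is it lost to drift from
a single cell, and what mutation supply is compatible with fast but
heterogeneous adaptation?

It is aimed at experimental-evolution and population-genetics researchers
who want a tested, scriptable implementation of this model family rather
than one-off analysis code.

## What is inside

| Module | Contents |
| --- | --- |
| `batchevol.deterministic` | two-subpopulation batch competition: `N_i(t) = N_i(0)·2^((t−λ_i)/τ_i)`, cycle ends solving `ΣN_i(t_end) = 2^M N`, analytic selection coefficient `s = ln2·(τ1/τ2 − 1 + (λ1−λ2)/(M τ2))`, regression-based `s` |
| `batchevol.ibm` | genotype-structured stochastic simulator: synchronous divisions, per-division mutation hooks, multivariate-hypergeometric bottlenecks |
| `batchevol.mutation` | gamma distribution of fitness effects (shape α=2, scale β in minutes) with three pleiotropy map variants (M1/M2/M3), effect truncation, diminishing-returns epistasis, and the targeted FPS1/ASK10/ACR3 locus model |
| `batchevol.experiments` | campaign drivers: factorial parameter sweeps with paired seeds, mutation-rate scans, recovery metrics (isotonic fit, generations to 25/50/75 % recovery), quantile fans |
| `batchevol.phenomics` | growth-curve fitness components (lag, doubling time, efficiency) with log2 and founder-normalized transforms |
| `batchevol.estimators` | fluctuation-assay p0 mutation rate `μ = −ln(P0)/N`, Poisson standing-variant probabilities, the variant-trajectory confidence filter |
| `batchevol.synthetic` | seeded generators for growth curves, plates with founder controls, and variant tables with binomial read sampling |
| `batchevol.cli` | `batchevol` command with subcommands `compete-det`, `compete-ibm`, `evolve`, `sweep`, `phenomics`, `simulate-data`, `estimate` |

The scientific background, conventions and numerical choices are described
in [`docs/methods.md`](docs/methods.md).

## Worked example

Competition between the stressed wild type (λ = 804.8 min, τ = 162.3 min)
and a cell carrying the FPS1 loss-of-function phenotype (λ = 276.6 min,
τ = 130.2 min), starting from one mutant cell among 10⁵, five doublings
per cycle:

```python
from batchevol import (
    BatchProtocol, GrowthLaw, GenotypePhenotype,
    run_deterministic_competition, regress_selection_coefficient,
    run_competition_ibm, analytic_selection_coefficient,
)

protocol = BatchProtocol(bottleneck=100_000, doublings_per_cycle=5, n_cycles=20)
wt = GrowthLaw(804.8, 162.3, 99_999)
fps1 = GrowthLaw(276.6, 130.2, 1)

traj = run_deterministic_competition(wt, fps1, protocol)
print(f"s (regressed)  = {regress_selection_coefficient(traj):.3f}")
print(f"s (analytic)   = {analytic_selection_coefficient(804.8, 162.3, 276.6, 130.2, 5):.3f}")
print(f"fixed (>=99%) at generation {traj.fixation_generation(0.99):.0f}")

losses = run_competition_ibm(
    GenotypePhenotype(804.8, 162.3), GenotypePhenotype(276.6, 130.2),
    protocol, n_replicates=25, seed=1,
)
print(f"lost in {sum(r.loss_flag for r in losses)} of 25 stochastic replicates")
```

prints

```
s (regressed)  = 0.640
s (analytic)   = 0.733
fixed (>=99%) at generation 25
lost in 0 of 25 stochastic replicates
```

The regressed selection coefficient (0.64 per generation — enormous by
experimental-evolution standards) is the slope of the log mutant/WT ratio
against generations over the cycles in which the wild type is still
represented by at least one cell; the analytic value is larger because it
assumes the mutant stays rare. A mutant this fit fixes in about five
cycles (25 generations) and, because its lag advantage multiplies its
first-cycle growth, it is essentially never lost to drift — whereas the
same mutation stripped of its lag effect (doubling-time effect only) is
lost in roughly a fifth of replicates.

The same models run from the shell:

```sh
batchevol compete-det --wt-lag 804.8 --wt-doubling 162.3 \
    --mutant-lag 276.6 --mutant-doubling 130.2 --out runs/fps1
batchevol evolve --n-replicates 25 --seed 7 --out runs/ratescan
```

Each command writes delimited-text tables plus a JSON manifest (resolved
parameters, seed, config hash) sufficient to reproduce the run
bit-identically.

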