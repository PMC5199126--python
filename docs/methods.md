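# Methods

`batchevol` models serial-batch (batch-to-batch) experimental evolution of
budding yeast under arsenite stress: populations repeatedly cycle through a
lag phase, synchronous exponential growth to a fixed number of population
doublings, and a bottleneck that founds the next cycle. Fitness is broken
into two heritable components, the lag λ (time to the first cell division,
minutes) and the doubling time τ (minutes); growth efficiency (yield) is
measured by the phenomics module but deliberately excluded from the
evolutionary models, where its selective value under energy restriction is
doubtful.

## Deterministic competition model

Two subpopulations (wild type, mutant) grow within a cycle as

    N_i(t) = N_i(0) · 2^((t − λ_i)/τ_i)   for t > λ_i,  N_i(t) = N_i(0) before,

and the cycle ends at the unique time `t_end` with
`N_1(t_end) + N_2(t_end) = 2^M · N` (bottleneck `N = 1e5`, `M = 5`
doublings per cycle by default). `t_end` is found with Brent's method on
the monotone total-size function (`xtol 1e-9`, `rtol 1e-12`); both
subpopulations are then rescaled proportionally to total `N` (drift-free
dilution) and lags restart. Assumptions inherited from the underlying
model: no death, no interactions, exactly one lag + exponential phase per
cycle.

With the wild type dominating the culture (`t_end ≈ λ_1 + M·τ_1`), the
per-generation selection coefficient of a rare mutant is the closed form

    s = ln 2 · (τ_1/τ_2 − 1 + (λ_1 − λ_2)/(M·τ_2)),

whose doubling-time and lag terms are exactly additive; the lag term
shrinks as `M` or τ_2 grow (the one-off head start is amortized over more
divisions). For the empirical arsenic mutants (λ, τ) = (276.6, 130.2)
(FPS1 loss of function), (503.3, 134.6) (ASK10), (630.4, 122.8) (ACR3
duplication) against the stressed wild type (804.8, 162.3), the closed
form gives 0.733 / 0.453 / 0.420.

**Regression convention.** The whole-trajectory estimate regresses
`ln r` (`r` = mutant/WT ratio) at cycle ends — including the `t = 0`
point — on cumulative generations counted as `M` per cycle. The
regression window ends at the first cycle whose diluted wild-type
subpopulation falls below one cell: beyond that point the bottleneck no
longer carries a single wild-type cell and the ratio ceases to describe a
competition. Under this convention the three mutants give s = 0.640 /
0.407 / 0.358, below the closed form because later cycles are mutant-
dominated (the closed form's rare-mutant assumption fails as `t_end`
shrinks). Regressing over all 20 cycles instead (available via
`censor_wt_below=None`) drags the estimates further down (0.600 / 0.390 /
0.338) by including saturated, biologically meaningless cycle ends.

## Individual-based model

Cells with identical genotypes divide at the same time, so the state is
genotype-structured: integer counts, a phenotype and a next-division time
per genotype. Within a cycle a genotype first divides at `λ + τ` and every
τ thereafter; events are processed in time order (simultaneous events in
genotype-id order), doubling the genotype, until the first event at which
the total reaches `2^M · N`. The termination check runs after every
genotype's doubling, so the realized total can overshoot the target by at
most one genotype's pre-division count; the bottleneck then draws exactly
`N` cells without replacement (multivariate hypergeometric). A mutation
hook runs after each division event and converts a binomial number of
just-divided daughters into new single-cell genotypes whose own clock
starts at the event (lag applies only at cycle starts, matching the
definition of lag as the time to the first division of a cycle).

Two consequences of the synchronous-doubling discretization are worth
knowing. First, a lineage's per-cycle growth factor is `2^k` with integer
`k`, slightly below the continuum prediction `2^((t_end − λ)/τ)` (e.g. the
full FPS1 mutant grows 32× per cycle while rare, vs 39× in the continuum
model), so single-lineage stochastic trajectories systematically trail the
deterministic model by up to about one cycle at fixation. Second, the
loss probability of a beneficial single cell is governed by a branching
process whose offspring mean is that integer growth factor divided by the
dilution factor `2^M`: for the doubling-time-only FPS1 variant (λ 804.8,
τ 130.2) the mutant completes six doublings per cycle against the wild
type's five, offspring mean 2, and the extinction probability solves
`q = e^{2(q−1)}`, i.e. `q ≈ 0.20`. Simulated loss frequencies match this
closed-form oracle; the full pleiotropic variant (offspring mean 32) is
essentially never lost. Scheduling the first division at λ instead of
`λ + τ` (available as a sensitivity alternative in the event rules) makes
that variant critical (offspring mean 1) with loss ≈ 0.9 — the loss
statistic is therefore highly sensitive to the within-cycle division
phasing, which should be kept in mind when comparing loss counts across
implementations of this model family.

## Mutation models

**Gamma DFE model.** Each daughter mutates with probability `G·μ`
(genome size `G = 1.2e7` bp — a configurable conversion constant — times
the per-bp rate `μ = 0.33e-9`); a mutation affects fitness with
probability `y = 0.034` and is then beneficial with probability
`z = 0.13`. Effect sizes are sampled as a raw wild-type doubling-time
change `ΔT ~ Gamma(α = 2, β)` with β in minutes (grid 13.3–47, empirical
point 33); the raw selection coefficient is recovered by inverting
`ΔT = T_wt · s_r/(s_r + 1)`, and `s = s_r · ln 2` converts growth-rate
ratios to per-generation units. Keeping β in printed minutes and bridging
to `s_r` through the doubling-time conversion is the single largest
interpretive choice in the package; it is isolated in one sampler so the
alternative (a dimensionless gamma on `s_r` directly) is a one-line swap.
Effects are truncated at full recovery (`T_wt − T_wt,N` = 162 − 126 min;
lag span 805 − 271 min) and successive beneficial mutations show
diminishing returns: the wild-type effect is scaled by the carrier's
remaining distance to the unstressed optimum (applied to the lag by the
same rule). Deleterious mutations get the same sampled magnitude with
opposite sign, capped so phenotypes never exceed the stressed founder —
the founder therefore sits on the deleterious boundary, and mutations
whose truncated effect is exactly zero (deleterious hits on the founder,
beneficial hits on a fully adapted carrier) stay in the parent genotype
class rather than founding phenotypically identical lineages. Map
variants: M1 draws doubling-time effects only; M2 drives doubling time
and lag from one coefficient with one sign (positive pleiotropy); M3
samples magnitude and beneficial/deleterious sign independently per
component.

**Targeted-locus model.** Beneficial mutation is restricted to three
channels with per-division probabilities `target_size · μ · multiplier`
for FPS1 and ASK10 point mutations and a direct duplication rate
(3e-7/division, scaled by the same multiplier) for ACR3. The real SNP
target sizes derive from a conservation-score screen of each coding
sequence and are configuration inputs; the package defaults (FPS1 150 bp,
ASK10 100 bp) are synthetic placeholders chosen once by an
establishment-rate argument — they put roughly one establishing FPS1
lineage per 50-cycle run at the basal rate, so that adaptive solutions
stay heterogeneous at 1–3× rates while the tenfold rate reliably delivers
an early FPS1 sweep. Alleles combine with complete negative epistasis: a
multi-allele genotype has the phenotype of its fittest allele (ranked by
the analytic selection coefficient against the stressed founder, which
puts FPS1 first on the strength of its lag effect) and further alleles add
nothing.

## Campaigns and summaries

Adaptation is tracked as the population-mean doubling time at every cycle
end (every 5 divisions), expressed as the percentage of the
stressed-to-unstressed gap recovered and capped at 100 %. Generations to
25/50/75 % recovery are read off a monotone least-squares (isotonic) fit
with linear interpolation between samples; a "fast" scenario reaches 75 %
within 100 generations. The factorial sweep crosses fold factors
{1/5, 1/3, 1, 3, 5} on μ, y and z with the six β values (750 sets; a
seeded subset is used at desk scale) and runs one population per set per
map variant with seeds paired across variants, so M1-vs-M2 contrasts are
paired comparisons. The mutation-rate scan runs 25 replicates per
multiplier (1×, 3×, 5×, 10×) at full scale (`N = 1e5`, 50 cycles) and
summarizes founder-extinction generations, the number of allele classes
above 5 % at the end, and the dominant class. Because carrier frequencies
overlap in double mutants, dominance means the fittest allele carried by a
majority of cells (falling back to the most frequent present allele).

## Growth-curve phenomics

Plate-reader curves (20-min cadence, 72 h) are smoothed with a running
median (window 3), background-subtracted (mean of the first three
readings, floored at 1e-4 OD) and optionally calibrated OD → population
size (identity by default; any monotone mapping is accepted). The maximal
slope of log size over a 9-point sliding window (readings above 0.04 OD)
locates exponential growth; because logistic growth obeys
`d ln n/dt = r − (r/K)·n` exactly, the final rate comes from a weighted
least-squares fit of `ln n` on time and the running integral of `n` over
the rise (up to 80 % of the plateau), which removes the curvature bias a
short tangent window picks up. Doubling time is `ln 2 / r`; lag is where
the corrected tangent meets the log inoculum level; efficiency is the
total OD gain. The inoculum of a microplate well (~1e5 cells ≈ 0.001 OD)
sits below the instrument's resolution, so the reference level is a
parameter (`inoculum_od`, default 1e-3): lag estimates shift by
`τ·log2(n_0/ε)` if the true inoculum differs. On 200 synthetic noisy
curves the extractor recovers τ with ~0.5 % median error and λ within
~8 min (the acceptance checks require 5 % and one 20-min cadence
interval). Components are log2-transformed; relative values subtract the
founder-control mean with the orientation flipped for efficiency, so
positive always means adaptation.

## Synthetic data

The generator emulates the study conditions rather than idealized inputs:
growth curves are logistic-with-lag (intrinsic doubling time, carrying
capacity ~1.25 OD, baseline 0.09 OD, Gaussian noise SD 0.002 OD, inoculum
0.001 OD, 20-min cadence over 72 h); plates interleave founder-control
wells at seeded random positions with a companion layout table; variant
tables draw Poisson read depths and binomial alternate reads from known
frequency trajectories. What the generator does not emulate: instrument
drift and edge effects on plates, condensation artefacts, death phases,
diauxic shifts, or sequencing artefacts beyond binomial sampling — so
passing round trips demonstrate estimator correctness under the stated
noise model, not robustness to every failure mode of real data.

## Numerical choices and degenerate inputs

Cycle-end root finding brackets `[0, max λ + 2·M·max τ]`. Zero mutation
rates, empty allele sets, all-founder plates, no-growth wells (flagged,
never raised), `P0 = 0` in the fluctuation estimator (raised with
guidance) and extinct subpopulations in the ratio regression (points
censored; at least three finite points required) are all handled
explicitly. Simultaneous division events are processed in genotype-id
order for bit-reproducibility; all stochastic entry points take explicit
seeds and spawn independent child streams per replicate.

## Known limitations

- The printed mutant-loss count for the doubling-time-only FPS1 variant
  (14 of 25) is not reproducible under this model class: every
  synchronous-doubling convention yields either ~0.20 (first division at
  `λ + τ`) or ~0.91 (first division at λ) loss probability, while 14/25
  would require a per-cycle offspring mean of ~1.3. The package reports
  what its model produces (~5/25) and documents the sensitivity above.
- Replicate-mean stochastic trajectories match the drift-free limit only
  in the rare-mutant (linear) regime; around the sigmoid midpoint the
  mean is smoothed below the deterministic path by replicate timing
  jitter, as expected when averaging shifted sigmoids.
- The 750-set factorial grid is larger than the 500 sets quoted for the
  original sweep (the exact subset used there is not recoverable);
  sweep-level conclusions are therefore framed as paired, qualitative
  contrasts, and desk-scale runs use a seeded 50-set subset.
- Fitness-component extraction assumes a single lag + exponential +
  plateau episode; diauxic or declining curves will confuse the tangent.
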