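# Methods

This note documents the models implemented in `bgsisland`, the conventions
and numerical choices behind them, what the forward simulator does and does
not emulate, and the package's known limitations.

## 1. Local background selection with the migration effect

### Model

A neutral locus linked to selected sites experiences excess variance in
reproductive success equal to `V_A · Q²`: the additive genetic fitness
variance of the selected region times a *linkage inflation factor* that sums
the locus's cross-generation association with deleterious backgrounds. The
local fitness-effective size of a subpopulation in an island model is

    N_f,local = N_local · exp[ − Σ_i V_A,i Q_i² / 2 ]

summing over selected segments *i* (the division by 2 discards short-lived
associations with the homologous chromosome). Within a focal deme the
association between a neutral lineage and a deleterious background is broken
per generation by selection (factor `Z`), recombination (`1 − r`), and — the
model's distinguishing ingredient — **emigration** (`1 − m`): a lineage that
leaves the deme no longer contributes to the local accumulation of fitness
variance. Summing the autocorrelation `C(τ) = [Z(1−r)(1−m)]^τ` and squaring:

    Q∞²(r) = [ 1 / (1 − Z(1−r)(1−m)) ]².

For a segment of map length `M` with the neutral site at its centre, the
relevant recombination fractions run over `[0, M/2]`, and averaging gives the
closed form

    Q∞² = 1 / [ (1 − a)(1 − a + aM/2) ],   a = Z(1−m),

which the tests verify against adaptive quadrature of the point formula to
1e-6 relative error. (Because `r` is treated as additive along the map this
presumes small `M`; at the `M ≤ 0.01` used in the study design the
approximation error is negligible.)

### Weak selection and fixation

Under weak selection deleterious alleles drift and fix, and fixed alleles no
longer generate fitness variance. With fixation rate `R`,

    V_A = (U_dip − 2R) t,   Z = 1 − V_M / V_A = 1 − U_dip·t / (U_dip − 2R),
    R = 4 N_f U t / (e^{4 N_f t} − 1),

with `V_M ≈ U_dip t²` the mutational variance. **Units:** `U` on a
`SelectionSegment` is the *gametic* rate (`mu_del · L`); `U_dip = 2U` is the
diploid genomic rate. The fixation-rate formula uses the gametic `U` — it is
the mutation influx `N·U_dip = 2N·U` times the semidominant fixation
probability `≈ 2t/(e^{4Nt} − 1)` — so `R → U` (the neutral substitution
rate) as `t → 0` and `V_A = 2(U − R)t → 0` smoothly in the neutral limit.
In the strong-selection limit (`R → 0`, `Z = 1 − t`, `m = 0`, `M = 0`) the
model collapses exactly onto classic deterministic theory,
`B = exp(−U/t) = exp(−2U/(2t+M))|_{M=0}`.

### Solver

`solve_local_equilibrium` iterates a damped fixed point on `B_local`
(damping 0.5, initialised at `B = 1`, relative tolerance 1e-10, max 500
iterations, bracketed Brent root solve as fallback). Selective interference
is approximated by *interference rescaling*: the effective size governing
deleterious-allele fixation is the rescaled `B_local · N_local` (selected
sites experience the same BGS as the neutral site), which is what closes the
system into a fixed point. With the flag off, `R` is evaluated once at the
census size. `V_A` is clamped at 0 and `Z` to `[0, 1)`; a clamped segment is
flagged in its diagnostics (fully drift-dominated) rather than silently
adjusted. With the chosen unit conventions the clamp is a numerical
safeguard only — `R ≤ U` keeps `V_A ≥ 0` analytically.

### Heterozygosity-effective size

Equilibrium diversity reflects neutral alleles of all ages, and young
alleles have not yet accumulated the asymptotic association. With the
time-dependent factor `Q²(τ) = [(1 − a^τ)/(1 − a)]²` (region-averaged over
`r` with 64-point Gauss–Legendre quadrature), an allele that arose `τ`
generations ago experienced `N_f(τ) = N_local · exp[−Σ V_A Q²(τ)/2]`, and

    B_het = (1 / 2N_local) · Σ_{τ≥0} Π_{i<τ} (1 − 1/(2 N_f(i))),

the expected lifetime of a lineage relative to the neutral expectation
`2N_local`. The per-generation survival factor `1 − 1/(2N_f)` with an empty
product at `τ = 0` is the unique convention for which the neutral limit is
exactly 1. The sum is truncated at `10·N_local` generations with the
remaining geometric tail added analytically at the asymptotic `N_f`, so
truncation introduces no error in the neutral limit and `< e^{−5}`-order
relative error otherwise. `B_local ≤ B_het ≤ 1` always; the gap is largest
under weak selection and tight linkage, where associations build up slowly.

## 2. Metapopulation predictions

Differentiation uses the finite-island equilibrium with reproduction (drift)
occurring *before* migration each generation — the same event order as the
simulator, and load-bearing: permuting the two changes the `m²` terms —

    F_ST = 1 / (1 + (d−1)·d·(4−2m)·N_local·B_local·m / (d(1−m) − 1)²)
    G_ST = 1 / (1 +   d²  ·(4−2m)·N_local·B_local·m / (d(1−m) − 1)²).

`B_local` here is the heterozygosity variant `B_het` (differentiation is a
ratio of diversities). As `m → 0` the F_ST form reduces to the familiar
`1/(4 N_e m d/(d−1) + 1)`.

Total diversity: population structure inflates the metapopulation's
effective size, `N_e,global = N_global / (1 − G_ST)`. The global BGS factor
`B_global` is computed by running the same local solver in panmictic mode
(`m = 0`, interference rescaling, heterozygosity variant) at population size
`N_e,global` — the metapopulation treated as a single panmictic unit for
total diversity. This is a modelling choice where the theory is genuinely
open; it behaves sensibly in both limits (no structure: plain panmictic BGS;
strong structure: a larger effective size, hence more interference among
weakly selected alleles). Finally

    π_T = θ/(1+θ),  θ = 4 N_e,global B_global μ;   π_S = π_T (1 − G_ST);
    π_B = π_S / (1 − F_ST),

the saturating infinite-alleles form. Neutral baselines repeat the pipeline
with `B = 1`. Predicted reductions at the study parameters
(`N_global·t = 50`, `U = 7e-3`, `M = 0`): π_T by 0.27 and π_S by 0.45 at
`m = 0.00045`; both by 0.45 at `m = 0.09` — computed, not calibrated, by
`scripts/acceptance.py`.

## 3. Forward simulator

Diploid Wright–Fisher island model, non-overlapping generations, constant
census sizes. Genome: a neutral block of `L_neutral` sites flanked by
`L_selected/2` selected sites on each side; total map length `M` spans the
selected region with the neutral block — internally non-recombining — at the
midpoint. Per generation and deme, each offspring draws two parents with
probability proportional to `w = (1−t)^k` (`k` = deleterious allele copies;
soft selection within demes, selfing at random-mating rates); each parent
transmits a gamete with `Poisson(M)` crossovers placed uniformly on the map;
deleterious mutations arrive `Poisson(U)` per gamete at uniform selected
sites (irreversible, no-op on an already-mutant site — a negligible
deviation from mutation stacking at `mu_del = 1e-5`); neutral mutations
arrive `Poisson(μ·L_neutral)` per gamete, each creating a novel allele label
at a uniform site (infinite alleles per site, matching the `θ/(1+θ)`
expectation used by the theory). Fixed deleterious alleles remain in the
state; they generate no fitness variance because parent sampling normalises
by the deme mean.

Migration then exchanges individuals: each individual is marked with
probability `m·d/(d−1)` and the marked individuals are permuted across the
vacated slots metapopulation-wide, so the probability of actually changing
deme is `m`, destinations are equally partitioned among the other demes, and
deme sizes and metapopulation allele counts are conserved exactly.

Implementation notes. Because the neutral block never recombines internally,
each distinct neutral sequence is stored once in a per-replicate pool and
haplotypes carry integer ids; reproduction copies ids and only a mutation
materialises a new pool row (garbage-collected periodically). All replicates
advance in lock-step inside shared numpy arrays from a single generator
seeded with `master_seed`: runs are deterministic given the seed and the
full configuration (including the replicate count — replicate *i* alone is
not independent of the batch size). This batching is what makes ≥50-replicate
confidence intervals affordable on one CPU.

What the simulator does *not* emulate: tree-sequence recording with
post-hoc neutral mutation overlay (the forward infinite-alleles scheme is
equivalent in expectation for π and F_ST), distributions of selection
coefficients, dominance other than semidominance, and non-island
demographies. Passing tests therefore validate the theory under the island
model's own assumptions; they say nothing about, e.g., isolation-by-distance.

## 4. Estimators

`π_S`, `π_B`, `π_T` use unordered distinct-pair counting: per site,
`1 − Σ c(c−1)/(n(n−1))` within demes (averaged over demes), the cross-pair
analogue averaged over unordered deme pairs, and the pooled version. Hudson's
`F_ST = 1 − π_S/π_B` and `G_ST = 1 − π_S/π_T` are ratios of averages across
sites (the standard recommendation; average-of-ratios is noisier), computed
on sites whose *pooled* minor allele frequency — `1 − max allele frequency`
for multi-allelic sites — passes the 0.05 threshold. All haplotypes are
used; no subsampling. The unbiased corrections mean a table with literally
identical demes yields `F_ST ≈ 0` only up to `1/(n−1)`, and the ordering
`π_S ≤ π_T ≤ π_B` — exact for the underlying frequencies — can be inverted
by at most the correction terms on tiny tables; both are immaterial at the
simulator's sample sizes (n = 200+ haplotypes per deme). Cross-replicate
uncertainty is reported as percentile (2.5, 97.5) intervals.

## 5. Validation scale

The stochastic acceptance surface runs the simulator at a deliberately
reduced size chosen to preserve the composite parameters that control the
compared quantities: 10 demes of `N_local = 100`, migration rates
`{0.00225, 0.045, 0.45}` preserving `4 N m d/(d−1) ∈ {1, 20, 200}` of the
full design, `20·N_global = 20,000` generations of burn-in (≥10 coalescent
times at these sizes), 50 replicates, 100 neutral sites at `μ = 2e-5`. The
check is that the deterministic F_ST prediction falls inside the
cross-replicate 95% interval, and that a panmictic neutral run recovers
`θ/(1+θ)`. Full study scale (750 replicates × 250,000 generations ×
N_local = 500) remains available through the CLI configs.

## 6. Known limitations

- Predictions near `2 N_e t ≈ 1` (the crossover between regimes) are the
  least accurate; this is a recognised open problem for BGS theory
  generally, and the solver's fixed point inherits it.
- Under strong interference (large `N_e,global`, small `t`, `M = 0`) the
  pipeline tends to *over*-predict diversity; the reductions it reports at
  `N_global·t ≤ 50` should be read as lower bounds on the BGS effect.
- The `B_global` construction (panmictic solve at `N_e,global`) is a design
  choice, not derived; it is the piece most worth sensitivity-testing if the
  π_T predictions are used quantitatively.
- Fixed selection coefficient per segment; no dominance variation; island
  model only. Associative overdominance under recessivity, which can act
  opposite to BGS in low-recombination regions, is out of scope.
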