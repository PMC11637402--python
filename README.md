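# bgsisland

Background selection, F<sub>ST</sub> and genetic diversity in finite island
models: theory plus a forward-time Wright–Fisher simulator to validate it.

## The problem

Purifying selection against deleterious mutations also removes linked neutral
variation — *background selection* (BGS). Its strength is summarised by
`B = N_e / N_e0`, the factor by which the effective population size of a
neutral locus is reduced. In a *structured* population, local BGS rescales the
local effective size `N_e,local = B_local · N_local`, which inflates genetic
differentiation (F<sub>ST</sub>) between demes and shapes total metapopulation
diversity π<sub>T</sub>.

Classic BGS theory (deterministic mutation–selection balance,
`B = exp[−2U/(2t+M)]`) fails for weakly deleterious alleles, which drift,
interfere with one another and sometimes fix. And in a subpopulation that
exchanges migrants, the association between a neutral lineage and its
deleterious background is broken not only by selection and recombination but
also by **emigration** — so migration itself weakens local BGS. This package
implements a quantitative-genetic model covering both regimes with that
migration effect:

- local fitness-effective size: `N_f,local = N_local · exp[−Σ_i V_A,i Q_i²/2]`
  with `V_A = (2U − 2R)t` and the linkage inflation factor
  `Q∞² = [1/(1 − Z(1−r)(1−m))]²` (the `(1−m)` term is the migration effect;
  `Z = 1 − V_M/V_A` is the per-generation decay of the fitness-variance
  association),
- coupled to the deleterious fixation rate `R = 4N_f U t/(e^{4N_f t} − 1)`,
  solved self-consistently (interference is approximated by feeding the
  rescaled `B·N_local` back into the fixation rate),
- a heterozygosity-effective size `N_eH` (relevant to equilibrium diversity,
  between `N_f` and `N`) from the time-dependent `Q²(τ)`,
- finite-island equilibrium differentiation with drift-before-migration event
  order:
  `F_ST = 1/(1 + (d−1)d(4−2m) N_local B_local m / (d(1−m)−1)²)` and the
  analogous `G_ST` (with `d²` in place of `(d−1)d`),
- total diversity through the structure-inflated global size
  `N_e,global = N_global/(1−G_ST)` and a global BGS factor:
  `π_T = 4N_e,global B_global μ / (1 + 4N_e,global B_global μ)`.

The forward simulator reproduces the same study design (demes of diploids, a
neutral block flanked by selected sites, multiplicative fitness
`w = (1−t)^k`, reproduction → migration each generation) at configurable
scale, and the estimator module computes Hudson's
`F_ST = 1 − π_S/π_B`, `G_ST = 1 − π_S/π_T` and the π components with a
pooled minor-allele-frequency filter (default 0.05), so theory and simulation
can be compared like for like.

## Worked example

```python
from bgsisland import (IslandParams, SelectionSegment, NeutralRegion,
                       solve_local_equilibrium, classic_B_region,
                       predict_fst, predict_pi)

island = IslandParams(d=10, N_local=500, m=0.009)
seg = SelectionSegment(t=0.015, mu_del=1e-5, L=700, M=0.0)  # U = 7e-3

sol = solve_local_equilibrium(island, [seg])
print(f"B_local = {sol.B_local:.4f}  (classic, no migration effect: "
      f"{classic_B_region(seg.U, seg.t, seg.M):.4f})")

p = predict_pi(island, [seg], NeutralRegion(mu_neutral=1e-5, L_neutral=10_000))
print(f"F_ST = {p.F_ST_pred:.4f}  (neutral: {p.F_ST_neutral:.4f})")
print(f"pi_T = {p.pi_T_pred:.4f}  (neutral: {p.pi_T_neutral:.4f}, "
      f"reduction {1 - p.pi_T_pred/p.pi_T_neutral:.2f})")
```

prints

```
B_local = 0.8316  (classic, no migration effect: 0.6271)
F_ST = 0.0552  (neutral: 0.0469)
pi_T = 0.1172  (neutral: 0.1728, reduction 0.32)
```

With `N_local·t = 7.5` and moderate migration (`m = 0.009`), the migration
effect raises `B_local` from the classic 0.63 to 0.83 — much of the fitness
variance a neutral lineage would accumulate locally is cut short by
emigration. Differentiation is only mildly inflated over neutrality
(F<sub>ST</sub> 0.055 vs 0.047), yet total diversity still drops by roughly a
third: BGS removes diversity metapopulation-wide even when it barely
registers in F<sub>ST</sub>.

The same pipeline is scriptable from the shell:

```bash
bgsisland predict  --config configs/study_scale.toml --out predictions.tsv
bgsisland simulate --config configs/desk_scale.toml  --out replicates.tsv
bgsisland validate --config configs/desk_scale.toml  --out validation.tsv
bgsisland selftest
```

`predict` writes one row per parameter combination (B with and without the
migration effect, classic B, F<sub>ST</sub>/G<sub>ST</sub>/π predictions);
`simulate` writes one row per replicate (π_S, π_B, π_T, F_ST, G_ST); and
`validate` puts simulated means with cross-replicate 95% CIs next to the
theory predictions with a coverage flag. Every output gets a JSON manifest
recording the config, seed and package version.

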