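# dcinbreed

Two-step errors-in-variables analysis of inbreeding depression in wild,
non-pedigreed populations, built for long-term individual-based studies of
long-lived mammals (the motivating system is a population of Weddell seals
monitored over decades and genotyped at 29 microsatellite loci).

Detecting inbreeding depression from marker data is hard because individual
inbreeding coefficients estimated from a few dozen microsatellites carry
large measurement error, and regressions that ignore that error understate
both the effect and its uncertainty. `dcinbreed` addresses this with a
two-step maximum-likelihood pipeline:

1. **Inbreeding coefficients** (`dcinbreed.ibd`). A Gibbs sampler over
   latent identity-by-descent indicators x_il estimates each F_i from
   multilocus genotypes: heterozygotes are never IBD, homozygotes are IBD
   with probability F p_lm / (F p_lm + (1-F) p_lm²); conjugate
   Beta and Dirichlet updates handle F_i and the allele frequencies p_l.
   Data cloning (K = 1, 5, 10, 20, 40 copies) drives the posterior to the
   maximum-likelihood estimate, and each individual's posterior IBD count
   is summarized as a Beta(A_i, B_i) = Beta(1 + k_i, 1 + L_i − k_i)
   measurement distribution.
2. **Fitness models** (`dcinbreed.models`, `dcinbreed.dc`). Four
   hierarchical regressions with F_i as a Beta-distributed latent
   covariate: lifetime reproductive success r_i (zero-truncated,
   upper-censored normal), adult survival (geometric age at death),
   age at first reproduction (NB(4, p)), and pupping interval (geometric
   with a first-pup term). Each is fit by data cloning with a
   Metropolis-within-Gibbs sampler; Wald CIs come from K × the final
   posterior covariance, and nested candidates are compared by ΔBIC/ΔAICc
   with differences below 2.77 treated as evidential equivalence
   (`dcinbreed.selection`).

The fitness statistic r_i is the log dominant eigenvalue of the Leslie
matrix of each female's realized life table (`dcinbreed.life_history`):
one pup gives r_i = 0, and a pup every year from age 4 to the 19-year
horizon gives the censoring bound ≈ 0.38195. Genotype-panel summaries
(expected heterozygosity, F_IS, Brookfield null-allele frequency, identity
disequilibrium g2) live in `dcinbreed.genotypes` and `dcinbreed.g2`, and a
fully parameterized synthetic-data generator in `dcinbreed.simulate`.

## Worked example

The pipeline is most conveniently driven from the shell. Simulate a small
study, estimate inbreeding coefficients, and fit the survival family:

```bash
dcinbreed simulate --out study --seed 1 --n-individuals 40 --n-loci 29
dcinbreed estimate-f --genotypes study/genotypes.gen --out step1 \
    --seed 2 --clones 1,40 --quick
dcinbreed fit --life-histories study/life_histories.csv --step1 step1 \
    --out fits --seed 3 --families death --clones 1,40 --quick
```

`estimate-f` prints the scaled posterior variance of F at each clone level,
e.g.

```
clones=1: scaled posterior variance of F = 1.0000
clones=40: scaled posterior variance of F = 0.0149
```

— the ~1/K decay that signals the cloned posterior has collapsed onto the
maximum-likelihood estimate. `step1/inbreeding_summary.csv` then holds one
row per female (modal IBD count, A, B, posterior mean F, R-hat), and
`fits/delta_death.csv` the criterion table; in a library session:

```python
>>> from dcinbreed import leslie_matrix, individual_growth_rate, cost_of_inbreeding
>>> individual_growth_rate([8, 10, 12, 14, 16, 18])   # biennial breeder
0.1616256090806727
>>> individual_growth_rate([9])                        # one pup: minimum
0.0
>>> cost_of_inbreeding(beta0=0.1927, beta1_per_unit=-0.1056, F=0.25)
{'delta': 0.13700051894135962, 'raw': 0.13700051894135962, 'relative_fitness': 0.8629994810586403}
```

The last line is the proportional cost of inbreeding δ(F) = 1 − μ(F)/μ(0)
for a full-sib mating (F = 0.25) at a weak fitness slope: a 13.7%
reduction in lifetime reproductive success.

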