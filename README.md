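# capribreed

Pedigree-based genetic evaluation for dairy goats, built around the
question a breed association actually asks: does acknowledging the CSN1S1
(αS1-casein) genotype as a fixed effect change the estimated genetic
parameters and the ranking of breeding animals for 210-day milk, fat,
protein and dry-matter yields?

The package implements the full evaluation chain for a Murciano-Granadina
style breeding programme:

- **Pedigree machinery** — validation and topological sorting of herdbook
  parentage, inbreeding coefficients *F* by the Meuwissen–Luo recursion,
  the numerator relationship matrix **A** (tabular method) and its sparse
  inverse **A**⁻¹ by Henderson's rules with inbreeding accommodation.
- **Lactation records** — Fleischmann (test-interval) standardization of
  monthly test-day yields to 210-day totals, component yields in kg,
  depuration against breed reference ranges, pedigree-connection filtering.
- **Nonparametric screening** — Kruskal–Wallis *H* per fixed factor with
  the conversion *F = H/dfn* and partial eta squared
  η²ₚ = F·dfn/(F·dfn + dfd), Dunn–Bonferroni post-hocs, Shapiro–Francia
  normality, Levene (median-centred), median test, Spearman correlations.
- **Animal model REML** — the repeated-records model

  y = μ + farm + year + month + season + birth type [+ genotype]
      + b₁·age + b₂·age² + animal + pe + e

  with var(animal) = **A**σ²ₐ, var(pe) = **I**σ²ₚₑ, var(e) = **I**σ²ₑ,
  fitted by EM-REML (monotone restricted likelihood, convergence on the
  squared relative change of the component vector, default 10⁻¹²).
  Univariate fits give h² = σ²ₐ/σ²ₚ and repeatability
  (σ²ₐ+σ²ₚₑ)/σ²ₚ with average-information standard errors; bivariate fits
  give genetic and phenotypic correlations.
- **BLUP breeding values** — BLUEs and per-animal PBVs from Henderson's
  mixed-model equations, prediction error variance from the inverse
  coefficient matrix, SEP = √PEV, reliability R_AP = 1 − SEP²/σ²ₐ,
  accuracy RTi = √R_AP, confidence ranges PBV ± k·SEP, and the standard
  interpretation bands.
- **Selection index** — the combined ICO ranking over milk, fat and
  protein PBVs and the three-stratum (bottom / median-centred / top)
  sampling used to pick animals for genotyping.
- **Model comparison** — PBV descriptives by sex, Pearson correlation and
  OLS regression between the genotype-inclusive and -exclusive
  evaluations, and per-trait heritability deltas.
- **Synthetic data** — a generator that simulates the whole study
  structure (random-mating pedigree, Mendelian CSN1S1 genotype drop,
  gene-flow TBVs ~ MVN(0, **A** ⊗ G₀), fixed-effect structure, repeated
  lactations, Wood-curve test days), so every stage is testable without
  any proprietary herdbook data.

The REML and BLUP fitters follow the scikit-learn estimator protocol
(`fit`, `get_params`, trailing-underscore attributes) and compose with
sklearn tooling; module-level functions wrap them.

## Worked example

```python
import capribreed as cb

cfg = cb.SimulationConfig(n_founders=80, n_generations=3,
                          generation_size=80, lactations_per_doe=(1, 3),
                          seed=20190913)
ped = cb.simulate_pedigree(cfg)
geno = cb.drop_genotypes(ped, cfg.allele_freqs, seed=cfg.seed + 3)
records = cb.simulate_lactation_dataset(ped, geno, cfg)

est = cb.AnimalModelREML(trait="milk", include_genotype=True,
                         tol=1e-8, max_iter=60).fit(records, pedigree=ped)
print(f"n_records={len(records)}  sigma_a2={est.components_.sigma_a2:.1f}  "
      f"h2={est.h2_:.2f}+/-{est.h2_se_:.2f}  "
      f"repeatability={est.repeatability_:.2f}")
```

prints

```
n_records=453  sigma_a2=8752.8  h2=0.32+/-0.14  repeatability=0.47
```

i.e. on this small simulated herd (453 records on ~230 does) the EM-REML
fit attributes about 8750 kg² of the milk phenotypic variance to additive
genetics — an h² of 0.32 with a standard error of 0.14, consistent with
the simulation truth of 0.40 at this sample size. Plugging the fitted
components into `cb.BLUPEvaluator` then yields per-animal PBVs with SEP,
reliability and accuracy, and `cb.ico_scores` ranks the does.

A full pipeline run (simulate → standardize → depurate → screen → REML ×2
→ BLUP ×2 → ICO → comparison) is available from the shell:

```sh
capribreed all --config run.yaml
```

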