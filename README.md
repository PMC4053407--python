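# sociokin

Socio-genetic network analysis of wildlife telemetry and microsatellite
data, built around the question of how kinship and shared space shape
animal social structure — the setting it models is a wild boar
(*Sus scrofa*) population tracked by radio-telemetry and genotyped at
microsatellite loci, organised into matrilineal social units of
philopatric females with wide-ranging adult males.

It is aimed at behavioural and population ecologists who have (1)
telemetry fixes (individual, timestamp, projected x/y in metres),
(2) diploid microsatellite genotypes, and optionally (3) individual
metadata (sex, age class), and who want to go from those raw inputs to
population-level inference with every intermediate quantity testable.

## What it computes

- **Dyadic associations**: two individuals are associated on a sampling
  day if any pair of their fixes is simultaneous (< 1 h) and closer than
  350 m (both configurable). Association strength per dyad is the
  half-weight index, `HWI = x / (x + y_ab + 0.5 (y_a + y_b))`, in [0, 1].
- **Preferred-companion permutation test**: sequential within-day swaps
  of individuals between groups (preserving daily group sizes and each
  individual's identified days) build a null HWI distribution; an
  elevated coefficient of variation indicates long-term preferred
  companions.
- **Social units**: weighted Newman modularity
  `Q = (1/2W) Σ_ij (A_ij − s_i s_j / 2W) δ(c_i, c_j)`, maximised
  exhaustively for small networks and by leading-eigenvector bisection
  with Kernighan–Lin refinement otherwise; observed unit sizes can be
  corrected for the mark rate (proportion of animals tagged).
- **Genetics**: Queller–Goodnight pairwise relatedness, per-locus Na,
  rarefied allelic richness, expected/observed heterozygosity,
  Monte-Carlo exact Hardy–Weinberg tests, and sequential Bonferroni
  (Holm) correction.
- **Space use**: fixed bivariate-normal kernel utilization distributions
  (bandwidth 250 m, 200×200 shared grid) and the volume-of-intersection
  overlap `VI = Σ min(UD_a, UD_b)`.
- **Matrix tests**: Mantel and partial Mantel correlations between
  association, relatedness and overlap matrices (10 000 permutations),
  and within- vs between-unit randomisation tests.
- **Temporal dynamics**: lagged association rates g(τ), the null rate
  under random mixing, blocked-jackknife errors, and fitting/selection
  (qAICc) of exponential-decay social models
  `g(τ) = c_cc + Σ_k c_k exp(−τ/T_k)` whose components are constant
  companionships, casual acquaintances, and rapid disassociations.
- **Synthetic data**: a ground-truthed generator of matrilineal
  populations — pedigrees, genotypes, two-level correlated movement,
  telemetry-like sampling, and dyadic association series with known
  social-component mixtures — used by the test-suite and usable for
  power analyses.

## Worked example

```bash
sociokin simulate --seed 5 --months 8 --out sim/
sociokin run --fixes sim/fixes.csv --genotypes sim/genotypes.csv --out out/
```

prints

```
wrote synthetic dataset (1721 fixes, 31 genotypes) to sim
partition: 6 units, Q = 0.698; outputs in out
```

i.e. the simulated population's six matrilineal units are recovered with
a strongly modular association network (Q = 0.698; values above ~0.3
indicate marked structuring). `out/` then holds `hwi.csv`,
`relatedness.csv`, `overlap.csv` (labelled symmetric matrices),
`units.csv`, and `summary.json` with the permutation test (observed mean
HWI vs the null, CV p-value), Mantel and partial Mantel correlations,
and within/between-unit comparisons. The same analysis runs on real
fixes/genotype CSVs of the documented formats, or from Python:

```python
import sociokin as sk
records = sk.detect_associations(fixes_df)       # fixes_df: id, timestamp, x, y
hwi     = sk.hwi_matrix(records)
units   = sk.best_partition(hwi)                 # units.q, units.n_units
rel     = sk.qg_relatedness(genotypes)           # sk.GenotypeTable
result  = sk.partial_mantel(hwi, rel, sk.overlap_matrix(fixes_df))
```

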