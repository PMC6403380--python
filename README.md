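# mdums — multidomain unfolding mutation screen

Multidomain proteins (EGF-like, cadherin, sushi, TB, laminin-G, Ig-like
C2-type, fibronectin type-III repeats, ...) dominate the eukaryotic
proteome, and disease-associated missense mutations frequently act by
destabilizing one of their globular domains. `mdums` is a library and
command-line tool for the *unfolding mutation screen* over such domain
families: given per-domain saturation-mutagenesis matrices of unfolding
propensities (or ΔΔG tables to convert) and an alignment of the
homologous domains, it

* averages the unfolding matrices over the alignment to filter out
  structure- and model-specific noise,
* computes a per-position **foldability** statistic and a per-position
  one-way **ANOVA p-value**,
* calls **critical residues** — positions whose mutation consistently
  destabilizes the fold across all homologues,
* maps missense-variant lists onto domains with a severity class per
  variant, and
* compares residue conservation with foldability.

It is aimed at structural bioinformaticians studying stability effects of
missense variation in repeat-domain proteins.

## The model

Each domain carries an L×20 matrix of **unfolding propensities**
u ∈ [0, 1], one per possible substitution. When free-energy changes are
supplied instead, they are mapped through the two-state logistic

    u(ΔΔG) = 1 / (1 + exp(−ΔΔG / s)),    s = RT = 0.593 kcal/mol,

so a neutral mutation (ΔΔG = 0) sits at 0.5 and strong destabilization
saturates at 1. Self-mutations form an internal quality control: a good
matrix has identity propensities whose 95% CI contains 0.5 while being
clearly separated (small Welch p) from real substitutions.

For an alignment position *a* of a domain family, the per-substitution
propensities are averaged over the contributing domains (each domain
excludes its own wild-type cell), and

    foldability(a) = Σ { ū_i(a) : ū_i(a) > 0.9 },   i over the 19 substitutions,

a value in [0, 19]. A one-way ANOVA with domains as groups quantifies the
between-homologue variability of the substitution propensities at *a*.
A position is **critical** when foldability > 10 and p < 0.05 (all
threshold comparisons are strict). Variants with looked-up propensity
above 0.9 are **severe**; [0.5, 0.9] medium; below 0.5 low.

A synthetic-data generator plants critical positions with known ground
truth (Beta(50, 2) cells at planted positions versus Beta(2, 8)
background, per-domain offsets, gaps), so the whole pipeline is testable
end to end with precision/recall scoring.

## Worked example

```python
from mdums import SyntheticConfig, MultidomainScreen, generate, recovery_metrics

truth = generate(SyntheticConfig(n_domains=10, length=100, fraction_critical=0.2, seed=7))
results = MultidomainScreen(truth.aligned).fit()
print(results.summary())
m = recovery_metrics(set(results.critical_positions), truth.critical_positions)
print(f"precision={m.precision:.2f} recall={m.recall:.2f}")
```

prints

```
Multidomain Unfolding Screen Results
====================================================
domains:              10
alignment length:     100
scored positions:     100
critical positions:   20 (foldability > 10, p < 0.05)
mean foldability:     3.548
internal control:     10/10 domains pass (CI ∋ 0.5)
----------------------------------------------------
critical positions (position, consensus, foldability, p):
     1  V   17.77  8.76e-54
     5  D   17.73  6.56e-49
...
precision=1.00 recall=1.00
```

Ten homologous 100-residue domains were generated with 20 planted
critical positions; the screen's averaged matrix, ANOVA and foldability
recover exactly those 20 positions (precision and recall 1.0). The
internal control confirms every generated matrix centers its identity
cells on 0.5.

The same run is available from the shell:

```sh
mdums simulate --seed 7 --out fx/
mdums run --config fx/config.yaml
```

which writes the averaged matrix, the foldability profile, per-domain
UCSF-Chimera attribute files for structure coloring, conservation
reports and a JSON run summary under `fx/results/`. `mdums
map-mutations` and `mdums report` add per-variant severity tables and a
per-protein roll-up (counts, mean ± sd unfolding, % severe, % severe on
critical positions).

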