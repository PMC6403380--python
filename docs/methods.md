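# Methods

## Scope and data model

`mdums` operates downstream of structure-based energetics: the inputs are
per-domain L×20 unfolding-propensity matrices (or ΔΔG matrices in
kcal/mol), domain-range annotations on the parent protein, a gapped
alignment (AFASTA) of the homologous domains, and optional missense-variant
lists. Producing the matrices (homology modelling, molecular-dynamics
equilibration, structure-based ΔΔG estimation) and the alignment itself
(structural superposition or a multiple aligner) are out of scope; both are
consumed as files. All coordinates are 1-based inclusive, matrices use the
fixed residue alphabet `ACDEFGHIKLMNPQRSTVWY` for their columns, and
missing cells are `NA` on disk / `nan` in memory.

## ΔΔG → propensity transform

Free-energy changes are mapped through the two-state logistic
`u = 1/(1 + exp(−ΔΔG/s))` with `s` defaulting to RT at 298 K
(0.593 kcal/mol, configurable). This is the simplest strictly increasing
map onto (0, 1) that fixes the two facts the screen relies on: neutral
(identity) mutations center on 0.5, and the scale saturates at 0 and 1.
It is symmetric (`u(−x) = 1 − u(x)`); one RT of destabilization gives
u ≈ 0.73. Non-finite ΔΔG values are rejected; `nan` cells pass through as
missing.

## Identity-mutation internal control

Self-mutations should leave stability unchanged, so the identity cells of
a good matrix should scatter tightly around 0.5. Per domain the control
reports: n, mean, sample sd, a t-based 95% CI of the mean, and a Welch
two-sample p-value comparing identity against all non-identity cells. Two
readings are deliberately reported side by side: the **location check**
(quality flag: CI contains 0.5) and the **separation check** (small Welch
p ⇒ the matrix distinguishes real mutations from self-mutations). A
sharp-location test alone would reward constant matrices; the separation
test alone would pass an off-center control. Degenerate inputs: sd = 0
collapses the CI to a point; if both samples are constant and equal, p = 1
(and 0 if constant but different). Fewer than two usable identity cells is
an error, not a silent zero. Note the CI check is a 95%-coverage event: on
honest data roughly 1 domain in 20 fails it by chance, which is why
ensemble-level summaries report the pass count rather than demanding
unanimity.

## Foldability

For one position, foldability is the **sum** of the substitution
propensities strictly greater than the severe threshold (default 0.9),
taken over the 19 non-wild-type substitutions; the range is therefore
[0, 19], with 19 meaning every substitution fully destabilizes the fold.
"Sum" is taken literally rather than as a count (the two agree at the
extremes; the sum preserves more gradation just above threshold), and a
count-based variant is available behind the `count_based` flag for
sensitivity analysis. Missing cells contribute nothing; a position with
no observed cells has *missing* foldability, never 0. All threshold
comparisons in the package are strict: 0.9 is not severe, foldability
exactly 10 is not critical, p exactly 0.05 fails.

## Averaging over the alignment

Homologous-domain matrices are averaged per alignment cell (column a,
substitution aa): a domain contributes iff it has a residue (not a gap) at
a, the matrix cell is non-missing, and aa differs from that domain's wild
type there. Identity cells are thus excluded from averaging and from
foldability — they feed only the internal control. Contribution counts are
recorded per cell because wild-type heterogeneity across domains makes
coverage uneven across the 20 columns. Cells with zero contributors are
missing. Averaging is order-invariant and idempotent on duplicated
domains, and every averaged mean lies within the range of its
contributors.

Because each domain excludes only its own wild type, an alignment position
with heterogeneous wild types can have all 20 averaged columns defined.
To keep foldability on its 0–19 scale, the profile drops the **consensus**
(modal non-gap residue, ties broken alphabetically) column at each
position before summing. Columns with >50% gaps are retained but flagged
`gap_majority`.

## Per-position ANOVA and critical residues

At each alignment column a one-way ANOVA is computed with **domains as
groups** and each domain's non-identity, non-missing substitution
propensities at that column as observations. This grouping directly
quantifies how consistent the destabilization profile is across
homologues. Degenerate conventions: all observations equal ⇒ p = 1;
constant groups with unequal means ⇒ p = 0 (F diverges); groups with
fewer than two observations are dropped, and p is missing when fewer
than two groups remain. Foldability and p are only computed where at
least two domains contribute (configurable floor).

A position is **critical** when foldability > 10 and p < 0.05, the raw
(uncorrected) rule; an optional Benjamini–Hochberg mode is available but
off by default, since the critical call is a conjunction with a strong
effect-size gate rather than a pure significance screen. Positions with
missing foldability or p are never critical.

## Mutation mapping and severity

Variant lists accept `G123R` and `p.Gly123Arg` dialects, optionally
prefixed with a protein id and a tab; malformed lines are collected with
line numbers in an error report, never dropped silently. A variant maps to
the unique domain whose range covers its protein coordinate (overlapping
annotations are rejected at load); the annotated wild type is
cross-checked against the domain sequence and mismatches mark the
assessment invalid. Severity: severe > 0.9; medium in [0.5, 0.9]; low
< 0.5. The 0.5 medium/low boundary is this package's own convention
(chosen at the neutral point of the transform) and is configurable.
Variants outside every domain are `unmapped`; mapped variants with a
missing matrix cell are `unscored`. Per-protein summaries report n
retrieved/mapped, mean ± sd unfolding, severe count/percent, and the
fraction of severe variants that land on critical alignment positions
(computed against the averaged profile).

## Conservation classes

A column is `identical` if all residues agree with no gaps, `similar` if
all residues fall in one physicochemical group with no gaps
({AVLIM}, {FWY}, {ST}, {KRH}, {DE}, {NQ}, {C}, {G}, {P} — a standard
grouping standing in for an aligner's consensus rules), `gap-dominated`
above a configurable gap fraction (default 0.5), else `nonconserved`. The
strict no-gap rule is the default; a tolerant mode ignores gaps up to a
configurable fraction. The conservation/foldability report gives mean
foldability and percent-critical for conserved (identical ∪ similar)
versus nonconserved positions, plus a per-position table for bar-plot
style summaries; classes with no scored positions report missing values,
never 0.

## Synthetic generator

The generator emulates a homologous-domain family with planted signal:
`round(fraction_critical × L)` alignment positions are critical — all 19
substitution cells there are drawn from Beta(50, 2) (mean ≈ 0.96, mass in
the severe regime) in every domain — and background cells from Beta(2, 8)
(mean 0.2). Beta laws are used because propensities live in [0, 1].
Identity cells are 0.5 + N(0, 0.02) clipped to [0, 1]. Per-domain noise is
an additive offset N(0, sd) applied to all real-substitution cells of a
domain and clipped, emulating the systematic stability shifts between
homology models of different quality; it is an offset rather than iid
cell noise so that the between-domain ANOVA has a defined signal at every
covered position. Gaps (default rate 0.05 per domain-position) avoid
planted positions by default so recovery targets are unambiguous; a
`gaps_anywhere` stress mode exists. One seeded RNG stream drives the
entire generation and the seed is echoed in the truth object.

What the generator does *not* emulate: correlated substitution
preferences within a column, realistic amino-acid composition,
phylogenetic correlation between domains, position-dependent gap
structure, and matrices whose noise is cell-wise rather than
domain-wise. Recovery results on synthetic ensembles therefore
demonstrate the pipeline's correctness and its qualitative noise
response, not its accuracy on experimentally derived matrices.

Reference conditions (10 domains, L = 100, 20 planted positions,
Beta(50, 2) vs Beta(2, 8), offset sd 0.05, gap rate 0.05) were confirmed
by simulation to give planted-position precision and recall ≥ 0.95 —
in practice 1.0 across dozens of seeds — and mean recall decreases
monotonically as the offset sd grows through 0.05 / 0.15 / 0.3, since
larger offsets drag averaged critical cells below the 0.9 severity gate.

## Numerical and format choices

* scipy provides the ANOVA F-test, Welch test, t quantiles and the
  logistic; brute-force explicit-sum implementations exist only as
  independent oracles in the test suite.
* TSV everywhere (tab-separated, UTF-8, `#` comments); matrices carry a
  mandatory `#units=propensity` / `#units=kcal/mol` first line; floats
  are written with 10 significant digits, so write/read round trips are
  faithful to ~1e-9 (and pipeline outputs are byte-identical across
  reruns on identical inputs).
* Chimera attribute files use the `defattr` dialect (`attribute:`,
  `match mode: 1-to-1`, `recipient: residues`, tab-prefixed
  `:<resnum>\t<value>` lines) in protein coordinates; attribute names
  must contain no whitespace and empty files are refused.
* Tests and the acceptance script use problem sizes of 3–10 domains and
  15–100 residues, which exercise every code path while keeping the full
  suite in the tens of seconds.

## Known limitations

* Domain–domain interactions are ignored: each domain is treated as an
  independent folding unit, so stabilization contributed by interfaces
  or linkers is invisible to the screen.
* The logistic ΔΔG map is a documented stand-in for whatever calibration
  produced a given upstream matrix; supplying matrices already in
  propensity units bypasses it entirely.
* The ANOVA direction is a consistency screen, not a significance test
  of destabilization: with domains as groups, a small p flags
  between-homologue heterogeneity, and the critical call relies on the
  foldability gate for effect size.
* Foldability at positions with heterogeneous wild types drops the
  consensus column; positions dominated by a non-modal wild type can
  lose up to one substitution's worth of signal.
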