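# Methods

This note documents the models and procedures behind `sigreverse`, the
parameters that matter, the numerical choices, and what the synthetic study
does and does not demonstrate.

## Differential signatures

Counts are normalised to counts-per-million and transformed to
`log2(CPM + c)` with pseudocount `c = 0.5` (configurable). Each gene is
tested with a moderated t statistic: the pooled two-arm variance `s²_g`
(residual df `d = n1 + n2 − 2`) is shrunk toward the across-gene mean
variance `s̄²` with a prior weight of `d0 = 10` degrees of freedom,

```
s̃²_g = (d0·s̄² + d·s²_g) / (d0 + d),     t_g = Δ_g / sqrt(s̃²·(1/n1 + 1/n2)),
```

and `t_g` is referred two-sided to a t distribution with `d + d0` df. This
is a deliberate simplification of empirical-Bayes variance moderation: it
stabilises small-replicate contrasts without fitting a prior, at the cost
of mild non-pivotality (below). It is a ranking statistic for the
repurposing engine, not a reimplementation of a count-model DE method, and
exact DEG counts from count-model pipelines are out of scope by design.
Multiplicity uses Benjamini–Hochberg over the gene universe (statsmodels'
`fdr_bh`). Signatures are antisymmetric under arm exchange and invariant to
sample order; with a single sample in either arm only log2 fold-changes are
reported.

Tag sets come in two modes: the top/bottom `n_top` genes by statistic
(default 100, capped at half the universe so the sides are disjoint), or
all genes at `q < cutoff` split by fold-change sign (an empty side is an
explicit error; callers choose the fallback). Ranked lists sort by
statistic descending, ties broken by ascending gene identifier — a fixed,
platform-independent rule.

## Connectivity scoring

The enrichment of a tag set in a ranked list is the signed two-sided
Kolmogorov–Smirnov statistic of the tag positions against the uniform
distribution (formulas in the README); a tie `a = b` returns the positive
branch, with a 1e-12 guard so the rule is stable under floating-point
accumulation. Tag genes missing from the list are dropped; retaining fewer
than 25% of them is a coverage error, and a degenerate whole-list tag set
is rejected.

The composite score zeroes whenever the up- and down-tag enrichments share
a sign (or either is zero). Consequences worth knowing:

- Under the null, about half of all composite scores are exactly 0, so
  permutation p-values have an atom at 1 and are *super-uniform*. The
  calibration check is therefore one-sided: the empirical CDF of p must not
  exceed the uniform (no anti-conservatism), tested with the one-sided KS
  statistic D+. A two-sided uniformity test would reject any faithful
  implementation of this score.
- Reversing a ranked list maps the deviations `(a, b)` to
  `(b − 1/n, a + 1/n)`. The enrichment magnitude is preserved to within
  `1/n`; the sign flips — and the signed values cancel to within
  `1/t + 1/n` — except when `a` and `b` are within `2/n` of each other, in
  which case both orientations resolve to the same branch.

**Permutation null.** Both tag sets are redrawn as disjoint uniform random
gene sets of the same retained sizes and rescored; the two-sided p is
`(1 + #{|s_null| ≥ |s_obs|})/(n_perm + 1)`. The null law depends on the
instance only through `(n, t_up, t_down)`, so a library run shares one
Monte-Carlo null per shape (`share_null=True`, the default). This matters
for FDR resolution: with one BH family over `m` pairs of which `k` are true
hits, the smallest attainable q is `m / (k·(n_perm + 1))`. Calling FDR <
0.01 over a 2,040-pair run with 4 planted hits therefore needs
`n_perm > 51,000`; the standard study uses 100,000, which the shared null
makes affordable (a few seconds on one CPU). Per-pair independent nulls
remain available (`share_null=False`) and agree with the shared null within
Monte-Carlo error.

**Inverse concordance** requires every expected condition (default 4:
2 cell contexts × 2 doses) to score strictly negative at q strictly below
the threshold (default 0.01); a missing condition is an
incomplete-evidence error, never a negative call. **Percentile ranking**
sorts scores ascending (most negative = strongest reversal = rank 1), ties
share the best rank, percentile = 100·rank/N. At the compound level the
pipeline aggregates by the mean score across conditions — a deliberate
choice where best-condition or median would also be defensible.

## GSEA validation

The weighted running sum walks the ranked list with hit increments
`|r|^α / Σ|r|^α` (default exponent α = 1; α = 0 is the classic unweighted
statistic) and miss decrements `1/(n − t)`; ES is the extreme deviation,
signed, same tie rule as above. Significance uses gene-set permutation
(random sets of equal retained size) because the pipeline ingests
summary-level ranked profiles, not sample-level cohorts; phenotype
permutation is out of scope. NES divides ES by the mean |null ES| among
same-signed nulls (flagged unavailable if none share the sign). A drug/
profile pair is called *inverse* when up-tags score negative and down-tags
positive, both at q below the panel threshold (default 0.05), *concordant*
with both signs reversed, *null* otherwise; BH spans all tests of one
panel call.

## Upstream regulators

TF and kinase enrichment use the one-sided hypergeometric tail (exact, via
scipy) over a declared background; rows sort by p, ties by descending odds
ratio then term. Network expansion takes all nodes on simple paths of
length ≤ 2 (configurable) between distinct enriched-TF seeds (networkx
simple-path enumeration; exhaustive, deterministic, order-independent).
When fewer than two TFs pass the threshold the seed list is padded from
the ranking so the chain still completes. Libraries are user-supplied GMT;
nothing is downloaded.

## Histology metrics

The NAFLD activity score is the NASH-CRN sum steatosis (0–3) + ballooning
(0–2) + lobular inflammation (0–3), range 0–8; fibrosis stage and portal
inflammation are validated and carried but never summed. Per-animal mode
enforces integer components; group-mean mode accepts fractional values
because published cohort tables report fractional means (note that summing
independently rounded component means need not reproduce a rounded
per-animal NAS mean — the arithmetic identity is asserted, not every
printed table row). SEM is the sample standard deviation (n−1) over √n.

## Synthetic study design

The generator emulates the statistical structure of a repositioning
screen, not any real cohort's expression values:

- **Counts**: negative binomial, variance `μ + φμ²` with dispersion
  φ = 0.1 (typical bulk RNA-seq), around a shared lognormal per-gene
  baseline (ln-mean 5, ln-sd 1 → median ≈ 150 counts over ~3 decades of
  abundance).
- **Compound library**: 51 compounds (1 planted + 50 decoys) × 4
  conditions, 5 replicates per arm. The planted compound shifts its 100
  effect genes (of 2,000) by ±2 log2 units at high dose and half that at
  low dose — a monotone dose–response, the simplest encoding that makes
  cross-condition concordance meaningful. Cell contexts share effect genes
  and differ only in noise, the simplest structure under which
  all-condition concordance is achievable. Decoys get independent random
  effect gene sets of the same size, so the planted compound is
  distinguishable only through its disease relationship.
- **Disease library**: 10 diseases with 12 case / 5 control cohorts (the
  shape of a small clinical biopsy signature). The target disease carries
  the planted effect genes with opposite signs at `reversal_strength ×
  effect_size` (default 0.5 × 2 — a disease signature that mirrors the
  drug only partially and noisily); decoys carry independent effects at
  full magnitude.
- **Determinism**: every entity draws from its own RNG stream derived from
  the study seed plus a stable per-entity offset; identical configurations
  reproduce identical matrices.

Not simulated: library-size artifacts, batch effects, GC bias, correlated
gene modules, or dose-dependent toxicity. Passing the planted-recovery
study therefore shows the engine detects and FDR-controls a genuine
reversal against realistic overdispersed noise; it does not certify
performance under technical confounding, nor reproduce any specific
published cohort comparison (the real compound-library and reference-
database comparisons are explicit non-goals).

## Known limitations

- Global-prior variance moderation is not pivotal: true log-expression
  variance depends on abundance (`≈ φ + 1/μ`), so low-abundance genes get
  mildly inflated |t| in *both* the drug and disease contrasts of the
  shared gene universe. In the fully-null study this produces a small
  (D+ ≈ 0.02) anti-conservative drift in connectivity p-values — below the
  one-sided KS detection threshold at the study scale and harmless at
  FDR 0.01 (the null study yields zero discoveries), but visible at much
  larger scales. A trend-aware prior would remove it at the cost of a
  fitted mean–variance curve.
- The permutation null randomises gene labels, not samples; it tests tag
  placement, not the sampling variability of the disease cohort.
- The score's sign-opposition zeroing makes composite p-values discrete
  and super-uniform (see above); compare p-values only against one-sided
  calibration expectations.
- `expand_network` enumerates simple paths; it is exact but exponential in
  the bound, intended for path lengths ≤ 3 on sparse interaction networks.
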