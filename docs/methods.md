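# Methods

## Scope and model

`coexsurv` analyzes a genes × samples expression matrix on the
log2(x+1) scale together with per-sample follow-up (time in months,
event indicator). The chain is: seed co-expression signature →
per-gene survival z → signature prognostic fraction → two-seed
consensus → enrichment / upstream-regulator calls → marker-based
survival stratification, with a drug-response correlation utility and a
simulator that generates cohorts carrying exactly the structure the
chain assumes.

## Co-expression signatures

The signature of a seed gene is every other gene with |Pearson r| at or
above a cutoff (default 0.3), split into positive and negative arms and
sorted by descending r with ties broken by symbol. Two conventions were
genuinely open:

* **Boundary rule.** A coefficient exactly equal to the cutoff is
  *included* by default. The strict-inequality variant is exposed
  (`strict=True` / `--strict`); the difference is measure-zero on
  continuous data and only matters for hand-built fixtures.
* **Zero-variance genes** have no defined correlation and are dropped
  with a logged count rather than assigned r = 0.

No p-value accompanies r: membership is by magnitude only.

## Survival z-scores

The survival z of a gene is the Wald statistic β̂/se(β̂) of a univariate
Cox proportional-hazards regression of outcome on the gene's expression,
standardized per gene to mean 0, SD 1 so that β is a log-hazard per SD
and z is scale-free. Ties are handled by the Efron approximation. The
solver is a Newton iteration on the Efron partial likelihood, vectorized
across genes (risk-set sums via grouped reverse cumulative sums), with a
trust-region step cap of 1, convergence at |score| < 1e-10, and a
monotone-likelihood guard: genes whose β diverges (|β| > 20) or whose
|z| would exceed 37 are flagged `separated` and reported with z clamped
to ±37. The per-gene standard error comes from the observed information
at the optimum. lifelines fits the identical model and is used in the
test suite as an independent cross-check, as is a brute-force grid
maximization of a plainly coded Efron partial likelihood on n ≤ 8
fixtures (agreement to 1e-6).

A gene is *prognostic* when |z| strictly exceeds 2 — "more than 2 or
less than −2", so z = 2.0 exactly does not qualify — with z > 0 adverse
and z < 0 protective. A signature's profile is its percentage of
prognostic members plus the quadrant counts crossing sign(r to seed)
with sign(z); signatures are ranked by percentage, ties by seed symbol.
No multiple-testing correction enters the ±2 rule; a BH-adjusted column
is available downstream for information only.

## Consensus signature

The consensus of two seeds is the plain symbol intersection of their
prognostic signature members. Intersection is *not* sign-constrained:
each consensus gene instead carries its (sign r_A, sign r_B) pattern so
that users can filter on sign consistency themselves. Shared genes must
carry the same z in both inputs (they must come from one scoring run);
provenance records |A|, |B| and |A∩B|. Display order is descending r to
a chosen reference seed — the deterministic ordering that replaces a
clustering dendrogram.

## Enrichment

**Pre-ranked weighted-KS.** For a ranked (gene, score) list, hits
increment the running sum by |score|^p normalized over the hits
(default p = 1; p = 0 gives the classic KS form) and misses decrement by
1/(N − N_hits); the enrichment score is the signed maximum deviation,
computed in closed form from hit positions (the extremum can only occur
at a hit or immediately before one). When the positive and negative
extremes tie exactly, the positive one is reported. The null draws
`n_perm` random same-size gene sets from the ranked universe
(gene-label permutation — the input is a derived signature, not raw
expression classes). The permutation p is the one-sided tail among
*same-sign* null ES with add-one continuity,
p = (1 + #{|ES_null| ≥ |ES|, same sign}) / (1 + #{same sign}),
the variant that is uniform under the null; NES divides ES by the mean
|null ES| of the same sign. FDR is Benjamini–Hochberg across the
reported sets' permutation p-values — simpler and well defined at modest
`n_perm`, and a deliberate divergence from the original
FDR-by-null-NES scheme.

**Over-representation** is the one-sided hypergeometric tail
P[X ≥ k] for the overlap k between a query set and each collection set
within a stated universe, BH-adjusted, with −log10(p) reported. It is a
transparent stand-in for proprietary pathway-scoring tools.

**Upstream regulators.** Given signed (regulator, target, ±1) edges and
observed per-gene directions (±1, e.g. adverse/protective from the
consensus), a target is consistent when edge sign × observed direction
= +1, and z = (N_consistent − N_inconsistent)/√N over the observed
targets. z ≥ 2 is "activated", z ≤ −2 "inhibited"; regulators with
fewer than 3 observed targets are reported but flagged low-evidence.

## Stratification

IHC markers (integer scores 0–3) are high at score ≥ 2. Expression
markers split at the cohort median by default, ties to low (quantile and
fixed-value rules are exposed); this default is a package choice — the
IHC rule is explicit in the motivating analysis, the RNA split is not.
Kaplan–Meier curves, the k-group log-rank test and Cox hazard ratios on
indicator contrasts are delegated to lifelines. Two markers combine into
four labels (`a-high/b-low`, …); the default reference for the combined
contrast is the doubly protective cell (`a-low/b-high`), so the doubly
adverse cell's HR reads directly as the combined risk. Disease-free
survival is the same machinery on a different (time, event) table.

## Drug response

Pearson (t-approximation p) or Spearman correlation between a gene's
expression and per-cell-line response (AUC by default; any response
column such as IC50 can be named) on the id intersection, requiring at
least 4 overlapping lines. Discordant lines are flagged at
|standardized least-squares residual| > 2.

## Simulator

Two latent factors f_A, f_B are jointly standard Gaussian with
correlation ρ_AB (default −0.42). A seed gene equals its factor plus
N(0, 0.05²) noise; module gene g is s_g·λ_g·f + √(1−λ_g²)·ε with sign
s_g ∈ {±1} and loading λ_g ∈ (0,1], so its population correlation to the
seed is exactly s_g·λ_g (default λ = 0.6, last third of each module
negatively signed so both signature arms exist). Remaining genes are
independent noise; optional hazard-free decoy modules provide
negative-control seeds. A designated subset of module genes carries
log-hazard coefficients β·s_g (coherent through the factor); the linear
predictor is η_i = Σ β_g x_gi, survival times are exponential-baseline
proportional hazards by inverse transform (T = −ln U/(λ0 e^η)), censored
by min(Exp(censor_rate), administrative cutoff). Defaults emulate a
TCGA-style lung adenocarcinoma cohort: 521 samples, λ0 = 0.014/month
(median ≈ 50 months), censor rate 0.015/month, cutoff 200 months,
yielding roughly 45% observed deaths. Finally the matrix is mapped
affinely to non-negative log2-like values (7 + 1.5·raw, clipped at 0; the
clip touches a ~5·10⁻⁷ tail and leaves correlations intact).

What the simulator does *not* emulate: count-level noise
(library size, negative-binomial dispersion), batch structure,
non-proportional hazards, informative censoring, and gene–gene
correlation beyond the factor structure. Passing tests therefore
demonstrate correctness of the statistical machinery under the factor
model, not robustness to every property of real RNA-seq cohorts.

## Numerical and design choices

* Gene identifiers are uppercased symbols; matching is exact after
  uppercasing. Missing expression values are rejected at load, never
  imputed — every downstream statistic assumes complete vectors.
* Time unit is months throughout; survival times must be strictly
  positive, events coded 0/1, and any scoring operation requires at
  least 2 events.
* All orderings are deterministic (descending statistic, ties by
  symbol); writers emit TSV with a provenance comment line, and the
  `full` pipeline is byte-reproducible for a fixed config and seed.
* The packaged 140-patient IHC fixture fixes only the dichotomized
  margins (58/82 and 66/74 low/high); each margin is split evenly across
  its two constituent scores, which is a synthetic choice — only the
  margins are meaningful.
* Problem sizes in the test suite (e.g. 2000-gene null calibration at
  n = 300; 50–100 replicate simulation checks at n = 400–1000) were
  chosen as the smallest cohorts at which the asymptotic properties
  under test are comfortably expressed.

## Known limitations

* Single-cohort survival z only; no meta-combination across cohorts.
* Univariate Cox throughout — no covariate adjustment or stratification.
* Pre-ranked GSEA only (no phenotype permutation) and no leading-edge
  visualization.
* The upstream-regulator call uses the unweighted activation z; no
  literature-derived edge weights or bias correction.
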