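# Methods

## Scope and shape

`megex` implements a five-stage screen: (1) literature relation filtering
and gene-list overlap, (2) study-registry selection, (3) per-gene
multi-study expression mega-analysis, (4) moderator meta-regression of the
per-study effects, (5) gene-set over-representation reporting. A
synthetic-data module generates full study collections with known truth so
every stage can be validated without external downloads. Standard
numerics are delegated: scipy for hypergeometric/chi-square/normal/F tails,
statsmodels for OLS/WLS and Benjamini–Hochberg adjustment, pandas for all
tab-separated IO. The effect-size estimator, heterogeneity statistics,
DerSimonian–Laird combination, model-selection rule, and all pipeline
wiring are implemented here and cross-checked in the tests against
independent straight-loop oracles and exact rational enumeration.

## Effect size

The unit effect is the log2 fold change (LFC) of a gene in one study. Two
conventions for the control reference are offered:

- **geometric (default).** `lfc = mean(log2 case) − mean(log2 control)`,
  i.e. the mean over case samples of the log2 ratio to the geometric
  control mean, with variance `s²_case/n_case + s²_ctrl,log/n_ctrl` where
  both variances are of log2 values. For matrices stored on a log scale
  (most public array series) this is exactly "expression of cases over the
  mean of controls, log-transformed". Under symmetric log-scale noise this
  estimator is unbiased, which the calibration tests rely on.
- **arithmetic.** The log2 ratio of each case sample to the *arithmetic*
  control mean on the linear scale, averaged; the variance adds a
  delta-method term `s²_ctrl/(n_ctrl · mean_ctrl² · ln²2)` for the control
  mean's uncertainty. Under skewed (e.g. log-normal) linear-scale noise,
  log2 of an arithmetic mean exceeds the mean of logs by roughly
  `σ² ln 2 ∕ 2` (Jensen's inequality), so this variant carries a constant
  negative offset of that size on every gene — about −0.17 log2 units at
  σ² = 0.5. It is retained because the ratio-to-arithmetic-mean phrasing
  is common in the applied literature, but it is not used by the
  calibration or recovery checks.

Cases (and, for the geometric mean, controls) with non-positive values are
excluded sample-wise; at least two positive samples per group are required,
otherwise the gene is treated as absent from the study. A non-positive
control mean raises an error for that gene/study pair, which the
collection-level driver converts into an exclusion with a warning.

## Combining and model selection

Per gene, studies measuring the gene contribute `(y_i, v_i)`; `k` is their
count. Cochran's `Q = Σ w_i (y_i − ȳ_w)²` with `w_i = 1/v_i` measures total
dispersion; its upper-tail chi-square probability at `df = k − 1` (`q_p`)
is the probability that the dispersion is within-study only. The
heterogeneity index `I² = 100 (Q − df)/Q` is clamped to 0 whenever
`Q ≤ df`, and exactly this clamp decides the model: fixed-effect
(inverse-variance mean) when `Q ≤ df`, DerSimonian–Laird random-effects
otherwise (`τ̂² = max(0, (Q − df)/C)`, `C = Σw − Σw²/Σw`, weights
`1/(v_i + τ̂²)`). The combined p-value is a two-sided Wald test of
effect/se against the standard normal. Both models' results are retained
on every result for audit. The significance screen keeps genes with
`p < 1e−7` and `|effect| > 1`, both strict, sorted by |effect| descending;
no multiple-testing correction is applied at this stage (the raw-p
threshold is itself extreme), though BH adjustment is available in the
enrichment machinery.

With `min_studies` (default 2) as the inclusion floor, genes measured in
fewer studies are skipped rather than erroring.

## Overlap and enrichment statistics

Gene symbols are canonicalized (trim, upper-case) everywhere before set
arithmetic. Two-list overlap is scored as the hypergeometric right tail
P(X ≥ observed) for drawing |B| genes from a stated universe containing
|A| marked genes — equivalently a right-tail Fisher exact test on the 2×2
in/out-of-A × in/out-of-B table; the odds ratio uses a 0.5 Haldane
correction only when a cell is zero. The universe size is an explicit
parameter (configurable default 20,000): published overlap p-values are
not reproducible without knowing the source database's universe, so the
percentage overlap, not the p-value, is the comparable quantity.

Enrichment is over-representation (hypergeometric right tail) of an
unranked query list against each GMT set, BH-adjusted across the
collection, significant at `fdr_p < q` (default q = 0.005), sorted by
(fdr_p, set_id) for determinism. Rank-based enrichment is out of scope
because the intended queries are short unranked lists. The shared-pathway
matrix counts, per gene pair, the significant sets containing both genes;
diagonals count sets per single gene.

## Moderator regression

Per gene, the per-study LFCs are regressed by OLS on total sample size
(n_case + n_control), study age (years) and country. Country, a
multi-level factor, is reference-coded and reported with a single partial
F-test p-value (full model vs. the model without the country block) — the
only way a 6-level factor yields one p-value per gene. Unweighted OLS is
the default, with an inverse-variance `weighted=True` option. A moderator
constant across the contributing studies is dropped and reported as
no-effect (p = 1); a constant response short-circuits to a no-effect
report for all factors; rank-deficient designs raise an error naming the
offending factor. Note the power ceiling: with 16 observations and ~9
parameters, a 0.5-log2 country shift is reliably detectable (≥80% of
replicates) only when per-study effect noise is small (σ² around 0.1 in
the generator's terms); at σ² = 0.5 unweighted power drops below 20%.

## Synthetic collections

The generator draws, per study, `log2 x ~ Normal(baseline_g + δ_gs·case,
σ²)` and emits anti-logged matrices; `δ_gs = true_lfc_g + Normal(0, τ²) +
country shift` is the realized study effect (the standard additive
random-effects generative model). Platform coverage is Bernoulli per gene
and study, so genes can be absent from some matrices, reproducing the
"measured in k of n studies" pattern of real collections. Defaults follow
the packaged 16-study thyroid-cancer registry: its per-study case/control
counts (totals 783/439), countries and study ages; n_genes = 2000,
baseline_log2 = 8 (typical array mid-range), σ² = 0.5 (log2-scale noise
SD ≈ 0.7, typical inter-sample variability on arrays), τ² = 0, full
coverage. The distributional form is a stand-in — real array data are not
exactly log-normal, have correlated genes, probe-level artifacts and batch
effects, none of which are simulated — so passing calibration tests
demonstrate correctness of the estimators under the stated model, not
robustness to everything real data can do.

Relation-table generation plants an exact post-filter overlap between two
disease gene sets and adds a configurable fraction of decoy rows that fail
the ≥3-reference/specific-polarity reliability filter. Per-study RNG
streams are spawned from `(seed, study_index)`, so single studies can be
regenerated in isolation and whole collections serialize byte-identically
under a fixed seed; the pipeline driver derives per-stage seeds from the
run seed by stage-name hashing.

## Numerical and design choices

- Probe/duplicate gene rows are collapsed by arithmetic mean on the linear
  scale (`max` available); silent scale auto-detection is deliberately
  avoided — matrices are linear unless flagged `is_log2`.
- A gene row containing a missing cell is treated as absent from that
  study rather than imputed.
- Dataset selection applies four registry predicates (human, RNA
  expression, total n ≥ 10, case/control design) and is idempotent.
- Boundary semantics are strict where thresholds are stated as strict:
  p < 1e−7, |LFC| > 1, I² = 0 at Q = df exactly.
- Tail probabilities are never computed by summation in the package
  itself (scipy's survival functions are used); exhaustive rational
  enumeration appears only in the test oracles.
- Simulation sizes in the calibration tests (2,000 null genes; 200
  replicate genes per recovery setting; 50 planted-recovery seeds) were
  chosen to keep Monte-Carlo error well inside the asserted bands while
  the full suite runs in a couple of minutes on one CPU.

## Known limitations

- DerSimonian–Laird with Wald intervals is mildly anticonservative for
  small k with very unequal variances; no Knapp–Hartung adjustment is
  offered.
- The within-study variance treats samples as independent and
  identically distributed within groups; paired designs are not modeled.
- The moderator regression treats the per-study LFC as an observed
  response, ignoring its sampling error unless `weighted=True`.
- Enrichment results depend strongly on the chosen universe; defaults
  (all genes in the collection) favor conservatism but are not a
  substitute for a curated universe.
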