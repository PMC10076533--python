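# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the `inversig` pipeline. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Disproportionality statistics

Each drug–event pair is summarised by a 2×2 table: `a` reports with the
drug and the event, `b` with the drug only, `c` with the event only, `d`
with neither; `n = a+b+c+d` and the expected count under independence is
`E = (a+b)(a+c)/n`. The counting unit is the unique (report, drug, event)
triplet — each deduplicated report contributes at most one count per pair.
Marginals are computed on the full filtered pair set, before any ICD-10
event exclusion; the event exclusions only gate which events can become the
target disease.

**ROR.** `ROR = ad/bc` with the Wald interval
`exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`. Any zero cell leaves the ROR
undefined (flag false); an optional Haldane–Anscombe +0.5 correction is off
by default. The conventional multiplier 1.96 is used rather than the exact
0.975 normal quantile, matching standard pharmacovigilance practice.

**IC.** `IC = log2((a+½)/(E+½))`, the +½ regularisation keeping zero-count
cells finite. Credible bounds are exact quantiles of the conjugate gamma
posterior `λ ~ Gamma(shape a+½, rate E+½)` (whose mean equals the point
estimate's ratio), on the log2 scale. The widely used two-term asymptotic
interval approximation was deliberately not made the default: the exact
quantile is testable against an independent numerical CDF inversion, and
the two definitions agree closely except at very small counts — exactly
where exactness matters for inverse signals.

**EBGM (MGPS).** The reporting ratio has a two-component gamma mixture
prior, `λ ~ p·Γ(α₁,β₁) + (1−p)·Γ(α₂,β₂)` (shape/rate). Marginally
`a` is a mixture of negative binomials; the five parameters are fitted by
maximum marginal likelihood with L-BFGS-B on log-transformed shapes/rates
and a logit-transformed weight, five seeded restarts, ftol 1e-8. The
posterior is the conjugate mixture of `Γ(αᵢ+a, βᵢ+E)`;
`EBGM = exp(E[ln λ|a])` via the digamma closed form per component, and the
5th/95th posterior percentiles (EB05, EBGM95) come from monotone bisection
on the mixture CDF, bracketed by the component quantiles. "Upper limit of
the 90% CI" is read as the 95th posterior percentile of a two-sided 90%
interval. No stratification is applied. Cells with `a = 0` participate in
the MGPS fit and in IC, but not in the ROR (zero cell).

**Inverse flags.** Strict inequalities: `ROR_UCI < 1`, `IC975 < 0`,
`EBGM95 < 1`. Undefined statistics never flag.

## Report preprocessing

- **Deduplication** keeps one report per case: the maximum of
  (event date, report version id), compared lexicographically — the
  tie-break on version id is our operationalisation of "most recent".
  The operation is idempotent and emits a sorted, deterministic order.
- **Filters**: primary-suspect drug rows only; the terms
  "drug ineffective" and "medication error" are removed (dropping reports
  left with no event); combination products are dropped. Combination
  detection is a heuristic on the normalised name — a `/`, `\`, `+` or
  `AND` separator between alphanumeric tokens, plus an optional curated
  list — because the report format has no structured ingredient field.
  The three filters touch disjoint fields and therefore commute.
- **Drug-name normalisation**: uppercase, whitespace collapse, trailing
  dosage tokens stripped. No ingredient-database resolution.
- **Event mapping**: a static two-column PT→ICD-10 table; chapters A, B
  (infectious) and R (symptoms/signs) are excluded from target-disease
  selection by default. Related event terms can be grouped onto one
  disease label through a synonym table supplied in configuration.

## Disease signature

Per study the matrix is brought to log2 scale when needed (max value > 50
heuristic) and median-centred per sample. Probe-level matrices collapse to
one row per gene by maximum interquartile range, ties to the smallest probe
id.

The per-study test is a moderated t: gene variances are shrunk toward a
common prior, `s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d)`, with `(d₀, s₀²)` estimated
by moment matching on the log sample variances under a scaled
inverse-chi-square prior (mean and variance of log s² have closed
digamma/trigamma forms; the trigamma equation is inverted numerically).
When the observed spread of log-variances does not exceed the pure sampling
spread, `d₀ = ∞` (all genes share s₀²); `d₀ = 0` recovers the ordinary
pooled t exactly, which is how the implementation is tested. The effect
size carried into the meta-analysis is Hedges' g (bias-corrected SMD); the
log2 fold change is tracked separately because the selection thresholds are
on fold change.

Studies combine under a fixed-effect model with inverse-variance weights
`w = 1/se²`: pooled effect `Σwθ/Σw`, `se = 1/√Σw`. The selection p-value is
the normal p of the pooled effect's z; Fisher's combined p over the
per-study moderated-t p-values is also reported, since "combining p values
and effect sizes" admits either reading. BH adjustment is applied once,
across all genes at the meta level. Signature thresholds default to the
asymmetric `p_adj < 0.001`, `log2fc > 1.5` (up) / `< −2.0` (down), with a
stricter ±2.5 "core" signature also emitted; both cuts are configurable.

## Reversal scoring

A drug profile is a strict rank permutation of the gene universe (rank 1 =
most up-regulated by the compound). Tied input values get average ranks and
are then ordered stably by gene id to restore a strict permutation. For a
gene set with sorted rank positions V(1)<…<V(s) in a universe of N:

    a = max_j ( j/s − V(j)/N ),  b = max_j ( V(j)/N − (j−1)/s ),
    ES = a if a ≥ b else −b

`RGES = ES_up − ES_down` when the two scores have opposite signs, else 0
(a profile that moves both sets the same way does not discriminate them).
A fully reversing profile approaches −2.

**sRGES.** Profiles are bucketed by dose (< 10 µM vs ≥) and time (< 24 h vs
≥); the (≥, ≥) bucket is the reference condition. For each non-reference
bucket a single global additive offset is estimated as the mean
within-compound difference to the reference bucket, subtracted before
averaging; the per-compound summary is a weighted mean with weight 1 for
reference profiles and w₀ = 0.5 otherwise. This deterministic two-class
offset scheme was chosen over per-compound regression because it is
estimable from few profiles per compound and exactly recoverable in
simulation. Cell lines are pooled by default; per-profile scores are
emitted for per-line inspection.

## Integration

Activity convention: lower ROR_UCI / IC975 / EBGM95 = stronger inverse
signal; lower sRGES = stronger reversal. The expected Spearman correlation
between sRGES and any activity value is therefore **positive**.

**Reversal genes.** One representative rank vector per compound (the
reference-condition profile, else the nearest by
(|log10 dose − 1|, |time − 24|) lexicographically). In each
leave-one-compound-out trial, each gene's ranks are Spearman-correlated
with the remaining compounds' activities (two-sided t approximation), with
BH-FDR across genes within the trial; a gene is a reversal gene iff its
adjusted p < 0.25 in **every** trial. The intersection is strict by
default; a fraction-of-trials relaxation is configurable. The per-gene
statistic is a design choice — the procedure's rank-based logic makes the
rank correlation the natural test. ROR-based activity is the default;
IC- and EBGM-based activities are supported.

**IC50.** Potency rows join by the 14-character InChIKey connectivity block
(full-key join configurable); median/min/max per compound are each
correlated with sRGES. Units are normalised to nM before summarising; rank
correlations are unaffected by the log transform used in plots.

## Synthetic-data generator

The generator defines the study conditions; every planted quantity is
emitted in truth tables and all outputs are byte-identical under a fixed
seed.

- **Reports** are a multinomial over (drug, event) cells:
  `p_ij ∝ p_drug(i)·p_event(j)·λ_ij`, so a planted pair's expectation is
  analytically `n·p_ij` and λ = 1 is the exact independence null.
  A duplicate fraction (default 0.1 in the study runs) re-emits cases as a
  second version with a later event date — exercising exactly the dedup
  rule — and a combination fraction (0.05) rewrites drug names as
  two-ingredient strings. In the end-to-end study each compound's lambda
  against the target event is `10^(−t)` for latent activity `t ~ U(0,1)`,
  so activities span inverse-signal strength over one decade.
- **Expression**: shared gene baselines ~N(7,1), per-study per-gene shifts
  ~N(0, 0.3), unit sample noise; planted genes shift case means by ±2.5
  SMD units (also ±2.5 log2fc since the residual sd is 1). The 2.5 default
  reflects the large fold changes of lesional-versus-normal skin
  signatures and clears the asymmetric −2.0 down threshold with margin;
  the study uses 6 studies of 20+20 and 12 up / 8 down planted genes in a
  978-gene universe.
- **Drug signatures**: disease up-genes draw offsets from the bottom of
  the list (down-genes from the top) via a truncated geometric whose
  offset scale is `0.1·N·(1−t)/t` positions (success probability
  `p = t/(t + 0.1·N·(1−t))`). Activity 0 gives exactly uniform ranks;
  activity 1 packs the sets into the exact extreme blocks; between the
  endpoints the shift is strictly monotone in t and — because the inverse
  CDF is monotone in p — pointwise monotone under common random numbers,
  which is how the RGES monotonicity property is tested. The 10% scale
  spreads planted ranks across the activity range instead of saturating at
  the list end, which is what makes rank–activity correlations
  informative. Collisions take the nearest free slot toward the intended
  end. Sub-reference conditions (dose < 10 µM or time < 24 h) attenuate
  the effective activity by 0.7, creating the additive condition offsets
  the sRGES summarisation estimates.
- **IC50**: `log10 IC50(nM) = 4 − 3·t + N(0, 0.3)`; compounds get 1–3
  assay rows to exercise the median/min/max summarisation. Identifiers are
  synthetic but format-valid (InChIKey-shaped 14-10-1 blocks, GSE/GSM-like
  ids) so parsers and joins are exercised.

What the generator does **not** emulate: real event-term vocabularies and
their hierarchies, correlated gene–gene expression structure, platform
effects beyond an additive study shift, signature values (ranks only), and
pharmacokinetic realism of potency. Passing tests therefore demonstrate
the pipeline's statistical machinery and its ability to recover planted
monotone structure — not performance on real databases, where reporting
biases, confounding by indication and vocabulary noise dominate.

## Scales, runtime and determinism

The study-scale run (100 compounds, 978 genes, 20 planted reversal genes,
300k reports, 6×(20+20) expression samples) was chosen to exercise every
stage with comfortably estimable statistics on a single CPU in well under a
minute; the demo configuration is a smaller variant of the same design.
Per-stage seeds derive from the master seed by hashing `"<seed>:<stage>"`
(reduced below 2³¹), so stages rerun in isolation reproducibly; all
outputs, including manifests, are byte-identical across reruns with the
same seed.

## Known limitations

- Combination-drug detection is name-heuristic; products whose names hide
  multiple ingredients pass through.
- The MGPS fit is unstratified; stratified expected counts are not
  implemented.
- No RxNorm/MedDRA vocabulary resolution; event grouping relies on a
  user-supplied synonym table.
- Fixed-effect meta-analysis only; between-study heterogeneity beyond the
  additive baseline shift is not modelled.
- The LOOCV trials are highly correlated (each omits one compound), so the
  all-trials intersection is only mildly more conservative than a single
  marginal test; under a global null it still selects a gene with
  probability up to the FDR level per dataset, as the permutation tests
  document.
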