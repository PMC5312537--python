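# Methods

## The problem

Tissue aging produces mostly *mild* molecular changes: in epidermal skin,
both metabolite levels and metabolic-gene expression shift by well under
two-fold between young (20–25 y) and old (55–66 y) donors. Individually
significant transcripts or metabolites are therefore hard to interpret: a
small expression change may or may not be functional. `metlocal` implements
an integrative analysis for matched metabolome + transcriptome cohorts that
asks a sharper question — does an enzyme's age-dependent expression change
leave a footprint on the metabolites *near it* in the metabolic network?

## Pipeline stages

### Metabolome

Input is an ions × samples intensity matrix from untargeted negative-mode
flow-injection MS, one m/z per ion (acquisition range 50–1000 m/z). Ions are
putatively annotated by exact mass against a user-supplied compound table,
considering the deprotonated ion [M−H]⁻ (−1.007276 Da) and the fluoride
adduct [M+F]⁻ (+18.998403 Da, from the NH₄F running buffer), at 0.001 Da
tolerance. Annotation is exact-mass only; isotopologue or cross-correlation
evidence is out of scope. Unannotated ions stay in every downstream
statistic as detected ions.

Intensities are quantile-normalized on the raw scale (removing per-sample
tissue-amount differences), then log2(x+1)-transformed. The order
(normalize, then log) is a package choice; the statistics can also be run on
raw intensities via `log_intensities: false`. Two per-ion analyses follow:

* Pearson correlation with donor age; significant at |ρ| > 0.25 and
  Storey q < 0.01 (strict inequalities).
* Welch (unpaired heteroscedastic) t-test old vs young with
  log2FC = mean(old) − mean(young); significant at |log2FC| > 0.1 and
  q < 0.05.

Constant ions have no defined correlation; they are excluded from the
multiple-testing family with a logged warning rather than imputed.

### Transcriptome

Microarray features flagged saturated or background-level in **at least
50 %** of samples (boundary inclusive) are removed, the rest are
quantile-normalized. Differential expression uses an ordinary per-feature
two-group linear model — the OLS group-indicator coefficient test, which is
algebraically the pooled-variance t-test (an identity the suite checks to
1e-10). Empirical-Bayes variance moderation (limma-style) is deliberately
**not** applied: it is the largest expected numeric divergence from analyses
that use it, but at cohort sizes of ~23 per group the moderation has little
leverage and the ordinary model keeps the statistic fully specified.
Significance: BH-adjusted p < 0.01 and |log2FC| > 0.25. Spearman correlation
of each feature with age is computed alongside because the locality hit
filter consumes it. When several probes share a gene symbol, the probe with
the highest mean expression represents the gene in the locality analysis.

### Pathway enrichment

Both omics use the same recursive nested-subset hypergeometric scheme.
Significant features are ranked best-first (metabolite ions by ascending q,
transcripts by ascending p). For each pathway, the hypergeometric upper
tail P(X ≥ PtwHits | TotalAllDetected, PtwAllDetected, TotalHits) is
evaluated on **every prefix** of the ranking — the single best feature, the
best two, … the full significant set — and the minimum over prefixes is the
pathway's p-value. Note the displayed overlap term of a hypergeometric test
is a point mass; a point mass is not a valid p-value, so the package uses
the upper tail by default and offers `pmf_only` for the literal single-term
variant. Pathway p-values get Storey q-values; enriched at q < 0.01.
Prefix minimization makes the procedure sensitive to strong signal
concentrated at the top of the ranking, at the cost of an optimistic bias
relative to a single fixed cutoff — the q-value correction is computed over
the per-pathway minima, as the procedure defines.

Backgrounds are all *detected* features (all tested ions / all retained
transcripts), not just annotated or metabolic ones; pathway membership is
intersected with the background before counting. For metabolites the
background counts ions, not unique compounds (an ion in any candidate
compound's pathway counts for that pathway).

### Network locality

The metabolic model is an undirected metabolite graph whose edges are
substrate–product pairs of enzymatic reactions ("main reaction pairs"),
plus an enzyme → incident-metabolite map. Measured ions are re-annotated to
the network's compounds; when several ions hit one compound the smallest
absolute mass error wins, and an ion hitting several compounds feeds each
(flagged ambiguous). Distances are D(i,m) = 1 + shortest path from
metabolite m to the nearest metabolite incident to enzyme i, so incident
metabolites sit at D = 1; unreachable metabolites carry zero weight.

The locality score of transcript t_i is

    S(t_i) = Σ_m D_{i,m}^{-2} (1 − p_{C_{i,m}}) |C_{i,m}|
             ───────────────────────────────────────────
             Σ_m D_{i,m}^{-2} (1 − p_{C_{i,m}})

with C_{i,m} the Spearman correlation between the transcript and metabolite
m across matched donors and p_{C_{i,m}} its p-value. S ∈ [0,1]; with a
single neighbor S = |C| exactly. Significance: K random permutations (default
10000) of the metabolite indices are applied to the columns of D — one
permutation per iteration, shared across transcripts, preserving each row's
distance multiset while breaking the distance↔correlation pairing.
Correlations are **not** recomputed under permutation; only the distance
weights move, exactly as the permuted-score formula prescribes. Then

    p(S(t_i)) = #{k : S_rand^k(t_i) ≥ S(t_i)} / K ,

reported as computed (a score above all K permutations gives p = 0 at
resolution 1/K; no pseudo-count is added). A per-row independent shuffle is
available via `scheme="per_row"`. The neighborhood radius d_max defaults to
unbounded — the D⁻² decay already bounds influence — and is configurable.

Hits are transcripts with p_locality < 0.05 **and** age-dependent
expression: gene–age Spearman p < 0.1 *or* BH-adjusted differential p < 0.1,
sorted by ascending locality p. The package bundles a 21-gene reference
table of published locality and age statistics for human epidermal aging
enzymes (`metlocal.datasets.load_reference_enzyme_stats`); all 21 rows pass
this filter, which the acceptance suite checks.

## Synthetic data: what it emulates, what it does not

`metlocal.simulate` generates the matched study structure end-to-end:
23+23 donors with integer ages in the two ranges, a connected random-tree
(+10 % extra edges) metabolite network of 120 compounds with unique
monoisotopic masses in [80, 900] Da separated by > 3× the annotation
tolerance, 40 enzymes incident to 1–3 metabolites, 200 genes and 150 ions.
Planted enzymes (default 8) get a ±1.0 log2 old-vs-young group effect; each
planted enzyme's distance-1 metabolites receive
sign · c · z_enzyme + √(1−c²) · ε on the log2 scale, so the enzyme–metabolite
correlation magnitude is ≈ c (default coupling c = 0.8, noise 0.2 log2
units). Ion m/z are [M−H]⁻ masses with ±0.0005 Da uniform error (an option
adds [M+F]⁻ ions); intensities are 2^log2-abundance, i.e. raw scale.
QC artifacts are spiked separately: chosen features get saturated /
background flags in a random ≥50 % of samples, so the QC filter removes
exactly the spiked set. All draws flow from one seed through named
substreams (cohort / network / omics / artifacts), so outputs are pure
functions of (config, seed) and changing one stage's draws never shifts
another's.

The generator does **not** emulate chromatography or ionization physics,
isotopologue patterns, probe-level microarray noise, covariates beyond age,
or realistic pathway topology. Passing tests therefore demonstrate that the
statistics and the locality machinery behave correctly under the declared
statistical structure — not that the pipeline's numeric output on real
cohorts would match any particular published count, which depends on
unreleased donor-level data.

Effect-size defaults are chosen for testability (the source analyses report
no effect sizes): coupling 0.8 / noise 0.2 gives strong but not trivial
planted signal, and coupling 0 gives an exact null for calibration.

## Numerical choices

* Storey q-values use a fixed λ = 0.5 (π₀ = min(1, #{p>λ}/((1−λ)n)));
  the smoother-based π₀ estimate is not implemented.
* Quantile-normalization ties receive the mean of the reference values over
  the tied ranks, so tied inputs stay tied. Idempotence holds exactly on
  tie-free data (checked to 1e-12).
* Spearman p-values use the t-approximation (appropriate for n ≈ 46);
  |ρ| = 1 maps to p = 0.
* Permuted-vs-real score comparisons use ≥ with a 1e-12 tolerance so exact
  ties (e.g. all-equal distances) count as exceedances, giving p = 1 in the
  fully degenerate case.
* All significance thresholds are strict inequalities, matching their
  published statement (an ion at |ρ| = 0.25 exactly is *not* significant).
* Degenerate inputs raise (`ConstantInputError`, inconsistent count errors)
  rather than propagating NaN/inf.

## Problem sizes used in the checks

The acceptance suite and `scripts/acceptance.py` run desk-scale versions of
the study: null calibration uses 5 cohorts × 200 enzymes × 150 metabolites
at K = 1000 permutations; planted recovery uses 10 cohorts × 20 planted
enzymes among 40, with 200 metabolites, at K = 1000. These sizes give the
permutation p-values 0.001 resolution and keep the whole suite in the
seconds-to-minutes range on one CPU.

## Known limitations

* No empirical-Bayes moderation (see above) and no batch correction or
  covariate adjustment; the intended design is a single-batch two-group
  cohort.
* Exact-mass-only annotation cannot separate isomers; ambiguity is flagged,
  not resolved.
* The locality permutation preserves each enzyme's distance multiset but,
  under the shared-column scheme, induces correlation between enzymes'
  p-values within one analysis; the per-row scheme trades that for slightly
  different null geometry.
* Storey's fixed-λ π₀ is unstable on very small families: with n of a few
  tests it can hit 0 (every q = 0) or exceed the smoother estimate
  (conservative q). The estimator is kept in its plain fixed-λ form;
  interpret q-values over small pathway families with care.
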