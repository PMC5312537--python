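# metlocal

Integrative metabolome–transcriptome analysis for aging-tissue cohorts, built
around a **network locality score**: a statistic that flags metabolic enzymes
whose age-dependent expression change has a functional footprint on the
metabolites surrounding them in the metabolic network.

## Who this is for

Groups with *matched* omics on the same donors — an untargeted metabolomics
ion-intensity matrix and a transcriptome expression matrix — who want to move
past lists of individually significant features. Age-related molecular
changes in tissues like epidermis are mild (mostly < 2-fold), so the
interesting question is not "which enzyme changed?" but "which enzyme's
change *did something* to metabolism?".

## The statistic

For an enzyme-coding transcript t_i, with C_{i,m} the Spearman correlation
between its expression and metabolite m across matched donors, p_{C_{i,m}}
its p-value, and D_{i,m} the network distance from the enzyme to the
metabolite (incident metabolites at D = 1):

```
         Σ_m D_{i,m}⁻² · (1 − p_{C_{i,m}}) · |C_{i,m}|
S(t_i) = ──────────────────────────────────────────────
         Σ_m D_{i,m}⁻² · (1 − p_{C_{i,m}})
```

S ∈ [0, 1] is a weighted mean of absolute correlations, dominated by nearby,
confidently estimated metabolites. Significance comes from K (default 10000)
random permutations of the distance-matrix columns — correlations stay
fixed, the distance↔metabolite pairing is broken — with
p = #{S_rand ≥ S}/K. Hits are enzymes with p < 0.05 whose expression is also
age-dependent (gene–age Spearman p < 0.1 or BH-adjusted differential
p < 0.1).

Around the score, the package implements the full pipeline: exact-mass ion
annotation ([M−H]⁻ / [M+F]⁻ at 0.001 Da), quantile normalization, Pearson
age correlation and Welch old-vs-young tests with Storey q-values,
transcript QC + differential expression with BH control, and a recursive
nested-subset hypergeometric pathway enrichment (best p over all
significance-ranked prefixes of the hit list). A synthetic-data module
generates matched cohorts with planted, network-localized age effects, so
everything is testable without external data. See `docs/methods.md` for the
full model description and design choices.

## Worked example

`examples/03_locality_scoring.py` simulates a 23+23-donor study (120
metabolites, 40 enzymes of which 8 carry a planted age effect with coupling
0.8 to their distance-1 metabolites), runs every stage and prints the run
summary:

```
enzymes_scored                         35
ions_annotated                         120
ions_correlation_significant           17
ions_differential_significant          18
locality_hits                          7
locality_significant                   8
transcripts_significant                8
planted enzymes recovered              7/8

locality hits (gene, S, p, rho_age, p_age, log2fc, adj_p):
  ENZ008       0.55 0 +0.77 3.79e-10 +1.10 7.78e-20
  ENZ015       0.52 0 +0.77 2.96e-10 +0.99 5.84e-19
  ...
```

Seven of the eight planted enzymes are recovered as locality hits: their
score S (weighted mean |Spearman| to nearby metabolites, here ≈ 0.5) beats
all or nearly all of 1000 random distance assignments (p ≤ 0.021), and their
expression clearly separates the age groups (|log2FC| ≈ 1, tiny adjusted p).
The eighth planted enzyme was removed by the QC filter on spiked array
artifacts — the pipeline only scores what survives QC. Counts elsewhere in
the summary show FDR control working: of 150 ions only the ~17–18 coupled to
planted enzymes reach significance.

The other examples run the generator (`01_simulate_cohort.py`) and the
metabolome stage with enrichment (`02_metabolome_age_statistics.py`).

A thin CLI wraps the same pipeline:

```sh
metlocal simulate --seed 1 --out study/
metlocal all --inputs study/ --permutations 1000 --seed 1 --out run/
metlocal report run/
```

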