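# effimine

Clinical efficacy mining and hub-gene discovery for
treatment-observational studies — built around the analysis chain of a
herbal-formula (XFC) study in rheumatoid arthritis, but reusable for any
cohort with a binary treatment exposure and pre/post laboratory markers.

## What it does

Hospital cohorts of treated patients rarely come with a designed
comparison, yet they carry a strong signal: after treatment, do
inflammation and coagulation markers (Hs-CRP, ESR, fibrinogen,
rheumatoid factor, …) move back toward their reference ranges, and is
that movement *associated with the treatment*? `effimine` implements the
full computational chain for that question, plus the transcriptomic
follow-up that asks *which genes* plausibly mediate the effect:

1. **Improvement coding and association rules** (`effimine.mining`).
   Each patient becomes a binary transaction: an exposure item (default
   `"XFC"`) and one `<marker>_improved` item per marker that moved in
   its beneficial direction.  A from-scratch level-wise Apriori mines
   treatment→improvement rules scored by

   - support(X→Y) = σ(X∪Y)/N,
   - confidence(X→Y) = σ(X∪Y)/σ(X),
   - lift(X→Y) = confidence(X→Y)/support(Y),

   where σ(·) counts records containing an item set and N is the record
   count.  A rule is *strong* when confidence > 60% and lift > 1.

2. **Random-walk fluctuation model of cumulative efficacy**
   (`effimine.walk`).  Per-patient outcomes ±1 in admission order define
   a walk y(l); the fluctuation function F²(l) = Var(Δy_l) over all
   overlapping windows and the scaling exponent α of F(l) ∼ l^α
   (memoryless null α = ½) quantify whether efficacy trends persist
   beyond chance.  Departure from α = ½ is tested by an exact
   permutation test.

3. **Hub-gene discovery** (`effimine.expression`, `effimine.network`,
   `effimine.enrichment`).  Two-group differential expression (Welch
   test, p < 0.05 and |log2FC| > 2), intersection with compound-target
   lists, degree/harmonic-closeness/betweenness centralities with
   top-k triple-intersection hub selection, maximal-clique-centrality
   core-gene scoring, single-gene ROC-AUC biomarker screening
   (candidate if AUC > 0.7), and hypergeometric over-representation
   against GMT gene-set catalogs.

4. **Synthetic data** (`effimine.synthetic`).  Seeded generators for
   every input — cohorts whose pre-treatment marker distributions are
   log-normals solved from published median/IQR summaries, ±1 outcome
   sequences in four serial-structure regimes, spiked expression
   matrices, networks with planted hubs, and gene-set catalogs — so the
   entire pipeline is testable offline with known ground truth.

## Worked example

```python
import effimine as em

specs = em.default_marker_specs()          # 8 markers with ranges + pre-treatment summaries
config = em.CohortConfig(
    n_patients=1283,
    effect_map={"Hs-CRP": (0.8, 0.5)},     # P(improve | treated), P(improve | untreated)
    noise_cv=0.05,
    seed=42,
)
cohort = em.gen_cohort(config, specs)
table = em.transactions_from_cohort(cohort, specs)
print(em.AssociationRuleMiner(table).fit(min_support=0.01).summary())
```

```
Association rules  (N=1283 records, 8 rules)
LHS             RHS  support_pct  confidence_pct  lift strength
XFC Hs-CRP_improved       39.283          81.029 1.195   strong
XFC    IgM_improved       28.137          58.039 0.997     weak
XFC    FBG_improved       27.825          57.395 0.979     weak
XFC    IgG_improved       27.592          56.913 1.021 moderate
XFC    PLT_improved       27.592          56.913 1.030 moderate
XFC    ESR_improved       27.358          56.431 1.015 moderate
XFC    IgA_improved       26.033          53.698 0.976     weak
XFC     RF_improved       25.409          52.412 0.938     weak
```

The planted Hs-CRP effect (80% improvement under treatment vs 50%
without) surfaces as the single *strong* rule: 81% of treated patients
improved (confidence), 39% of all records contain both items (support),
and treated patients improved 1.195× more often than the cohort
baseline (lift).  Markers with no planted effect hover at confidence
≈ 50–58% and lift ≈ 1.

```python
walk = em.EfficacyWalk.from_transactions(table, "Hs-CRP_improved")
print(em.FluctuationModel(walk).fit(test_null=True, n_shuffles=199, seed=42).summary())
```

```
Fluctuation analysis
  lags: [4, 6, 9, 13, 20, 29, 44, 65, 97, 144, 215, 320]
  F2:   3.462, 5.039, 7.178, 9.749, 13.42, 19.62, 31.9, 51.75, 87.13, 125.2, 139.1, 84.74
  alpha_hat = 0.4416  (se 0.0310; memoryless null alpha = 0.5)
  permutation test (199 shuffles): p = 0.8600, null not rejected
```

As expected for patients simulated independently, the efficacy walk is
memoryless: α̂ = 0.44 is indistinguishable from ½ (permutation
p = 0.86).

The same stages are available from the shell:

```bash
effimine simulate --n-patients 1283 --seed 42 --out cohort.csv
effimine mine --cohort cohort.csv --min-support 0.01
effimine run-all --seed 42 --outdir demo_run     # full pipeline + report.json
```

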