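# emtpath

EMT molecular subtyping of clear cell renal cell carcinoma (ccRCC), from
both ends of the assay spectrum: gene expression and routine H&E histology.

Epithelial–mesenchymal transition (EMT) stratifies ccRCC into an epithelial
(Epi) and a mesenchymal (Mes) subtype with different prognosis. `emtpath`
implements that stratification as a reusable, fully tested pipeline:

* **Molecular arm** — derive an EMT gene signature from a candidate set
  (e.g. the MSigDB hallmark EMT genes) by Pearson correlation with the
  canonical markers CDH1 (epithelial) and VIM / CDH2 / FN1 (mesenchymal);
  cluster samples into Epi/Mes with centered-correlation hierarchical
  clustering; score each sample on the EMT axis with a signed two-sample
  Kolmogorov–Smirnov statistic on within-sample ranks:

  ```
  D+ = max_t [F_mes(t) − F_epi(t)]⁺ ,  D− = max_t [F_epi(t) − F_mes(t)]⁺
  EMT score = D+ − D−  ∈ [−1, +1]      (+1 fully mesenchymal-like)
  ```

  plus Kaplan–Meier / log-rank survival comparison, a permutation test for
  mutation-frequency differences, Benjamini–Hochberg adjustment, and
  Ward/Jaccard clustering of dichotomized methylation (beta ≥ 0.3).

* **Imaging arm** — tile slides into non-overlapping 256×256 windows, drop
  tiles that are > 50 % near-white background (all channels ≥ 220),
  Macenko-normalize stains to a reference space, detect tumor tiles with a
  3-class classifier (necrosis / stroma / tumor), and classify tumor tiles
  Epi vs Mes with slide-wise k-fold cross-validation (all Epi slides kept,
  Mes slides downsampled 1:2, at most 600/300 tumor tiles per Epi/Mes
  slide). The slide call is the mean tile Mes probability (the "AI score",
  Mes if > 0.5), rendered as a spatial heatmap; class activation maps
  localize the morphology driving each call.

* **Synthetic data with planted truth** — every stage is testable offline:
  Gaussian expression cohorts with a planted marker-correlated signature,
  exponential survival with a configurable Mes hazard ratio, and H&E-like
  mini-slides rendered through an exact Beer–Lambert stain model (which
  makes the Macenko estimator's accuracy measurable to fractions of a
  degree). Mesenchymal tumor tiles carry denser nuclei than epithelial
  ones — the morphological signal the classifier must learn.

Training follows a transfer-learning contract: a frozen convolutional
backbone with global average pooling and a single softmax layer retrained
by SGD (learning rate 0.01). The default `small-cnn` backbone is a fixed,
seeded numpy feature extractor sized for CPUs; an Inception-V3 backbone
slot exists for torch-equipped environments.

## Worked example

```python
import emtpath as ep

# 1. a cohort with 63 planted EMT genes among 500
cohort = ep.synthetic.generate_expression_cohort(
    ep.CohortSpec(n_samples=200, n_genes=500, n_signature_genes=63,
                  effect_size=3.0, seed=3))

# 2. signature, subtypes, EMT scores
sig = ep.select_signature_genes(cohort.expression, cohort.expression.gene_ids)
sub = ep.orient_clusters(
    ep.cluster_subtypes(cohort.expression.subset_genes(sig.selected_genes)),
    cohort.expression)
scores = ep.compute_emt_score(cohort.expression, sig.epi_set, sig.mes_set)

n_mes = sum(1 for v in sub.labels.values() if v == "Mes")
print(f"selected {len(sig.selected_genes)} genes "
      f"({len(sig.epi_set)} epi / {len(sig.mes_set)} mes)")
print(f"subtypes: {n_mes} Mes / {len(sub.labels) - n_mes} Epi")
mes_mean = sum(scores.scores[s] for s, l in sub.labels.items() if l == "Mes") / n_mes
print(f"mean EMT score in Mes cluster: {mes_mean:+.2f}")

# 3. survival contrast between the called subtypes
surv = ep.synthetic.generate_survival(sub.labels, hazard_ratio=3.0, seed=0)
res = ep.log_rank_test(surv["time"], surv["event"], surv["group"])
print(f"log-rank chi2 = {res.statistic:.1f}, p = {res.p_value:.2e}")
```

prints

```
selected 63 genes (30 epi / 33 mes)
subtypes: 100 Mes / 100 Epi
mean EMT score in Mes cluster: +0.55
log-rank chi2 = 34.4, p = 4.49e-09
```

All 63 planted genes are recovered with no false selections; the Mes
cluster sits on the positive end of the EMT axis, and with a hazard ratio
of 3 the subtype split separates survival decisively.

The imaging arm end to end (synthetic slides → tiling → tumor detection →
slide-wise cross-validated Epi/Mes calls):

```python
result = ep.run_subtype_experiment(n_epi=20, n_mes=40, k=3, seed=0)
print(result.mean_slide_auc, result.fold_slide_auc)
```

A command-line interface mirrors the library:
`emtpath simulate expression|slides|survival`, `emtpath tile`,
`emtpath derive-signature`, `emtpath assign-subtypes`, `emtpath score-emt`,
`emtpath cluster-methylation`, `emtpath km`, `emtpath experiment`.

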