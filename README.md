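# mycstrat

Stratification of pancreatic cancer transcriptomes by MYC activity, and the
statistics that link that stratification to drug vulnerability.

A minority subtype of pancreatic ductal adenocarcinoma (PDAC) is driven by
hyperactive MYC, carries a worse prognosis, overlaps the squamous/basal-like
subtype, and is preferentially sensitive to perturbation of protein
homeostasis (proteasome inhibitors such as bortezomib). `mycstrat` implements
the computational workflow behind that kind of study as a tested, reusable
library for bioinformaticians:

- **Consensus signature classification** — samples are clustered on the genes
  of each of three MYC-target signatures (variance-scaled rows, Euclidean
  distance, Ward linkage); the cluster with the highest mean scaled signature
  expression is MYC-high, and samples called high by *all* signatures form
  the consensus MYC-high set.
- **GSEA from scratch** — signal-to-noise ranking
  s(g) = (μ⁺ − μ⁻)/(σ⁺ + σ⁻) with the Broad σ-floor, the weighted
  Kolmogorov–Smirnov running-sum enrichment score
  ES = max deviation of (P_hit − P_miss) with hit increments
  |s|^p / Σ_hits |s|^p, a phenotype- or gene-set-permutation null,
  NES = ES / mean(|null ES| of matching sign), and the tail-ratio FDR q over
  pooled normalized scores. BH/BY adjustment is available for the unweighted
  path.
- **Drug-screen statistics** — the single-dose hit rule
  (mean response in MYC-high lines) / (mean response in MYC-low lines) > 2
  with response = 100 − viability; 4PL dose-response fitting
  v(d) = bottom + (top − bottom)/(1 + (d/GI50)^hill) with relative and
  absolute GI50; normalized AUC over log dose; sensitivity-quartile
  phenotypes; GI50 cross-correlation.
- **Cohort statistics** — Kaplan–Meier curves, the two-group log-rank test,
  an exact two-sided Fisher test (probability-mass definition), and ΔΔCt
  qPCR quantification.
- **Synthetic data with planted truth** — cohorts with a known MYC-high
  fraction, overlapping signatures, exponential survival with a configured
  hazard ratio, subtype enrichment, screens with planted hits, and 4PL
  curves, so every stage is testable end-to-end without external data.

## Worked example

```python
from mycstrat.pipeline import PipelineConfig, run_full_analysis
from mycstrat.synthetic import ScreenSimConfig

cfg = PipelineConfig(
    screen=ScreenSimConfig(n_drugs=129, n_hits=10, replicate_cv=0.0),
    n_perm=1000,
    seed=12,
)
report = run_full_analysis(cfg)
```

Printed by `python examples/full_pipeline.py`:

```
cohort_a (n=80): consensus MYC-high = 8, precision = 1.00, recall = 1.00
cohort_b (n=150): consensus MYC-high = 15, precision = 1.00, recall = 1.00
signatures enriched (q<0.25) in both cohorts: ['MYC_TARGETS_DIRECT', 'MYC_TARGETS_V1', 'MYC_TARGETS_V2']
screen: 10 hits; exactly the planted set: True
survival log-rank p = 0.1146; subtype Fisher p = 0.0009
```

The consensus counts recover the planted 10% MYC-high fraction (8/80 and
15/150); exactly the three planted MYC signatures survive the cross-cohort
q < 0.25 intersection; the ratio > 2 rule recovers exactly the 10 planted
screen hits; and the MYC-high group shows the planted squamous-subtype
enrichment (survival separation at n=80 is underpowered in any single
cohort — see `docs/methods.md`).

The `examples/` directory has one short script per capability
(classification, GSEA, screen scoring, dose-response fitting, quartile
phenotypes, survival/subtype statistics, full pipeline). A thin CLI wraps
the same functions: `mycstrat simulate|classify|gsea|screen-score|stats|run`.

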