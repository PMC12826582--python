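# phenoanchor

Phenotype-anchored benchmark-concentration (BMC) analysis for developmental
toxicology: the package links morphological concentration-response curves in
larval zebrafish to per-gene transcriptomic dose-response models, so that the
genes disrupted *at or below* the concentration eliciting a phenotype can be
isolated, compared across chemicals, and functionally grouped.

It was built around a study design of 3 chemicals x 4 concentrations
(0, 0.133, 1.33, 13.3 µM) x 2 timepoints (48, 72 hpf) with 4 pooled-embryo
RNA-seq replicates per cell, plus 96-well morphology plates (12 concentrations,
n = 14 per concentration, n = 24 controls), and ships a synthetic-data
generator that emulates exactly this design with known ground truth, so every
stage is testable without external downloads.

## What it computes

**Morphology.** Each dichotomous endpoint (x-fin, edema, cranial, axis,
mortality, ...) is fit by maximum likelihood to a 3-parameter log-logistic
curve

    p(d) = g + (1 - g) / (1 + exp(-a - b·ln d)),    p(0) = g,

and summarized by the benchmark concentration at 20% extra risk,

    BMC₂₀ = exp((logit(0.2) - a) / b),

which is independent of the background rate `g`. A Fisher-exact / Holm
time-course test locates when each phenotype emerges.

**Transcriptomics.** Counts are filtered (≥5 reads in ≥2 samples, per
timepoint), TMM-normalized to log₂CPM, and screened for differential
expression with a negative-binomial Wald test (trend-shrunk dispersions,
BH-adjusted p ≤ 0.05, no fold-change cutoff). Genes DE at ≥1 concentration are
fit to six continuous dose-response families (Exp2–4, Linear, Poly2, Power);
the AIC-best model defines the gene's BMC as the smallest dose at which the
modeled mean departs from control by 1.35 residual SDs. A within-dose-group
bootstrap yields the 95% interval (BMCl, BMCu), and genes pass the
concentration-response cascade when the BMC is within the tested range,
BMCu/BMCl ≤ 40, and the best model is not the non-monotonic Poly2.

**Anchoring and networks.** Genes with BMC ≤ 1.33 µM (the lowest phenotype-
eliciting concentration) are phenotype-associated; removing genes with a
concentration response to either comparator chemical gives the
phenotype-unique set. These sets feed a right-tailed hypergeometric
enrichment over the expressed-gene universe and a Cohen's-kappa term network
(edges at κ ≥ 0.35, functional groups merged at ≥50% gene overlap, each group
labeled by its lowest-p term).

## Worked example

```python
import numpy as np
from phenoanchor import (AnalysisConfig, SimulationConfig, simulate_morphology,
                         simulate_counts, fit_endpoint_bmc,
                         model_chemical_timepoint, anchor_genes)

sim = SimulationConfig(seed=5, n_genes=2000, chemicals=("8-MBaP",),
                       timepoints=(48.0,))
fit = fit_endpoint_bmc(simulate_morphology(sim), "x-fin")
print(f"x-fin BMC20 = {fit.bmc_uM:.3f} uM")          # x-fin BMC20 = 0.242 uM

counts, manifest = simulate_counts(sim)
cfg = AnalysisConfig(seed=5)
records, de = model_chemical_timepoint(counts, "8-MBaP", 48.0, cfg, seed=5)
assoc = anchor_genes(records, cfg.anchor_concentration_uM)
print(len(records), "genes modeled,", sum(r.has_cr for r in records),
      "with a concentration response,", len(assoc), "anchored <= 1.33 uM")
# 89 genes modeled, 57 with a concentration response, 26 anchored <= 1.33 uM
```

The simulated x-fin plate has a true BMC₂₀ of 0.28 µM; the fitted 0.242 µM
recovers it to within plate-level sampling error (the median fit across 200
plate pairs is within a few percent of truth). The anchored set contains the genes whose expression is modeled
to be disrupted at or below the concentration that produces the phenotype.

A command-line interface mirrors the stages
(`phenoanchor simulate|morpho-bmc|timecourse|preprocess|de|gene-bmc|anchor|enrich|overlap|run-all`).

## Layout

- `src/phenoanchor/synthetic.py` — study-design generator with ground truth
- `src/phenoanchor/io.py` — morphology CSV, counts+metadata TSV, GMT
- `src/phenoanchor/morpho.py` — log-logistic fits, extra-risk BMC, Fisher/Holm
- `src/phenoanchor/preprocess.py` — filtering, TMM, log₂CPM, PCA, NB Wald DE
- `src/phenoanchor/genebmc.py` — six-family fits, AIC, SD-based BMC, bootstrap
- `src/phenoanchor/anchoring.py` — anchored/unique sets, Venn regions, joins
- `src/phenoanchor/enrichment.py` — hypergeometric terms, kappa network
- `src/phenoanchor/workflow.py` — end-to-end orchestration
- `docs/methods.md` — modeling assumptions, defaults, and limitations
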