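# dsbrepair

Genotype–phenotype analysis of DNA double-strand-break (DSB) repair in a
case–control design, built for biostatisticians and genetic
epidemiologists studying impaired DNA repair in autoimmune disease
(here: rheumatoid arthritis, RA).

The package links a *phenotype* — the per-subject efficiency of
repairing bleomycin-induced DSBs, measured with the comet assay — to a
*genotype* — SNPs in homologous-recombination (HRR) and non-homologous
end-joining (NHEJ) genes — and to the mRNA expression of seven DSB-repair
genes, and wraps the whole analysis in an interpretable decision-tree
classifier.

## The statistics at its core

* **Repair efficiency.** With the post-bleomycin damage set as 100%,
  `RepEff = 100 · (1 − t₁₂₀/t₀)` is the percent of induced damage
  removed after 120 min of recovery. Subjects are ranked into groups
  1–4 from the quartiles of the control arm's RepEff distribution
  (group 1 = highly efficient, group 4 = no repair).
* **Association.** Per-genotype and per-repair-group odds ratios
  `OR = ad/bc` with Woolf 95% intervals
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; binomial logistic regression
  fitted by iteratively reweighted least squares with Wald intervals;
  Mann–Whitney U (tie- and continuity-corrected normal p), the
  Hodges–Lehmann shift, and the Hosmer–Lemeshow calibration test.
* **Expression.** qPCR relative expression `fold = 2^−ΔCt`,
  `ΔCt = Ct_target − Ct_reference` (reference gene RPLP1), compared
  between arms on the fold scale.
* **Classification.** A from-scratch CART tree over categorical
  features `x = (x₁, …, x_p)` — `x₁` the repair rank coded 0–3,
  the rest genotypes — with equality tests `x_j = v`, Gini-impurity
  splitting, at most 20 splits, prediction
  `ŷ = Σ_{l∈L} label_l · I(x ∈ l)`, leave-one-out cross-validation
  (LOOCV), sequential forward/backward feature selection, and Chi2
  (−ln p), MRMR and ReliefF importance scores.

A synthetic-cohort generator, calibrated to the reference study's
published per-arm summaries (45 RA / 45 controls, 17-SNP panel, 2 × 4
repair-group table, per-arm median expression folds), makes every stage
testable without any external data and supports planting known odds
ratios for parameter-recovery checks.

## Worked example

```python
from dsbrepair import (default_config, generate_cohort_frame, score_cohort,
                       group_count_table, repeff_crude_ors, loocv)
from dsbrepair.association import format_or
from dsbrepair.pipeline import build_feature_matrix

cfg = default_config(seed=1)                 # 45 cases / 45 controls
frame = generate_cohort_frame(cfg)
scored = score_cohort(frame, mode="fixed")   # published group edges
counts = group_count_table(scored)
print(counts)
for r in repeff_crude_ors(counts, zero_cell="haldane"):
    print(f"{r.label} vs {r.reference_label}: OR {format_or(r)}")
X, y, names, _ = build_feature_matrix(frame, scored)
m = loocv(X[:, :1], y)                       # rank feature only
print(f"LOOCV accuracy {m.accuracy:.4f}  F1 {m.f1:.4f}")
```

prints

```
          1   2   3   4
control  10  11  13  11
case      3   0   2  40
group 2 vs group 1: OR 0.13 (0.01-2.84)
group 3 vs group 1: OR 0.51 (0.07-3.68)
group 4 vs group 1: OR 12.12 (2.84-51.81)
LOOCV accuracy 0.8222  F1 0.8333
```

The 2 × 4 table is one random cohort's arm-by-repair-group counts; RA
cases pile up in group 4 (no repair), so group-4 membership carries a
large RA odds ratio (here 12.1 with a wide Haldane-corrected Woolf
interval — single-cohort estimates of a large OR are noisy at n = 45
per arm), and a decision tree using only the repair rank already
classifies ~82% of subjects correctly in LOOCV on this draw.

A CLI mirrors the library (`dsbrepair simulate|score|associate|express|
tree|select|run`), writing every table as seed-stamped TSV plus a JSON
run manifest:

```sh
dsbrepair run --seed 1 --out results/run1
```

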