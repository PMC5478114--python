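# sigcore

Toolkit for interrogating signed prognostic gene-expression signatures,
built around the 17-gene **HTICS** signature (Her2-TIC-enriched
signature) for HER2+:ERα− breast cancer. It is aimed at computational
biologists who want to know not just *whether* a signature predicts
outcome but *which genes and pathways carry that power*: the package
classifies samples, evaluates survival separation, exhaustively sweeps
every gene subset of a signature, extracts co-occurrence "core" genes,
finds correlated substitute genes, and benchmarks everything against
composition-matched random-signature nulls.

## The methods in brief

**SSM classification.** For signature genes with directions
*I<sub>n</sub>* ∈ {+1, −1} and median-centered log2 expression
*X<sub>n</sub>*,

&nbsp;&nbsp;&nbsp;&nbsp;SSM = Σ *I<sub>n</sub>* · *X<sub>n</sub>* / |*X<sub>n</sub>*| ÷ Σ |*I<sub>n</sub>*| ∈ [−1, 1],

i.e. the average agreement between each gene's above/below-median state
and its expected direction. Samples with SSM ≥ 0 are a *match*; match
vs no-match groups are compared by Kaplan–Meier curves,
Gehan–Breslow–Wilcoxon p, and Cox proportional-hazards HR (Efron ties).
A fast observed/expected estimator HR ≈ (O₁/E₁)/(O₂/E₂), with expected
events from the log-rank risk tables, powers the large sweeps.

**HER2 amplicon calling.** A sample is HER2+ when more than 2-fold
elevation over the per-gene cohort median is seen in ≥ 3 of the five
co-amplified genes ERBB2, STARD3, PERLD1, GRB7, C17orf37; agreement
with IHC labels is reported as PPV/sensitivity/specificity, Cohen's κ
and Fisher's exact p.

**Sub-signature sweep and cores.** A k-gene signature has 2^k − 1
non-empty subsets (131,071 for k = 17). Each subset is scored on an MFS
and an OS cohort and called significant at p < 0.05 on both. Pair-wise
co-occurrence percentages over the significant subsets are thresholded
at mean + 1 SD; genes pairing with ≥ 2 partners form **Core1**.
Repeating this on the top-performing subsets (HR ≥ the full signature
on both endpoints) with an above-median frequency filter gives
**Core2**; the **Core** is their intersection (the shipped reference
lists intersect in the six genes Chaf1b, Scrn1, Npy, Ccr2, CD74, Nrp1).

**Null models.** Random signatures with the target's composition (same
number of up and down genes) are drawn from the expression universe;
the empirical false detection rate (eFDR) is the fraction with HR
strictly above the target's over many permutations.

**Synthetic cohorts.** A generator plants all of the above —
pathway-blocked correlated expression, a signature-driven
proportional-hazards survival time with uniform censoring, an amplicon
amplification subpopulation with noisy IHC labels — so the entire
pipeline is testable without downloading any cohort.

## Worked example

```python
import sigcore as sc

cfg = sc.SyntheticConfig(n_samples=300, beta=3.0, seed=1)
expr, clinical, truth = sc.generate_cohort(cfg)
res = sc.evaluate_signature(expr, clinical, cfg.signature, endpoint="MFS")
```

Running `python examples/score_and_survival.py` prints:

```
samples: 150 match / 150 no-match
Cox HR (match vs no-match): 4.87  95% CI 3.25-7.30
Cox p = 1.85e-14; Wilcoxon p = 2.19e-16
O/E hazard ratio (fast estimator): 4.67
```

The cohort planted a signature-driven hazard (`beta=3.0` per unit risk
score); SSM splits the 300 samples into match/no-match groups whose
Cox hazard ratio of 4.87 recovers that planted risk separation, and
the O/E estimator agrees with the full Cox fit within a few percent.

The other scripts in `examples/` demonstrate amplicon calling, the full
131,071-subset sweep with core extraction, substitute discovery,
null-model ranking, and the end-to-end pipeline with its
reproducibility manifest. A thin CLI mirrors the library:
`sigcore simulate | score | amplicon | survival | roc | loo | combos |
core | substitute | null | efdr | run-all`.

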