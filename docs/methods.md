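# Methods notes

## Scope and model

`sigcore` analyses *signed* gene signatures: ordered gene lists with a
direction I_n ∈ {+1, −1} (expected up or down in high-risk samples) and
a pathway label per gene. The package's reference signature is the
17-gene HTICS (8 up, 9 down; pathways Cell Cycle ×4, Immune Response
×8, Cell Migration ×3, Homeostasis ×1, Glycan Metabolism ×1), shipped
with its Core1/Core2/Core subsets, the five-gene HER2 amplicon list and
a partial table of documented substitute genes. Any signature supplied
as a TSV (gene, direction, pathway) works the same way.

## SSM scoring conventions

SSM = Σ I_n·sign(X_n) / (number of signature genes scored), where X_n
is the median-centered log2 expression. Two conventions are ours, made
where the defining rule is silent:

* **Exact-median values** (X_n = 0): the term X_n/|X_n| is undefined; we
  score it 0 while keeping the gene in the denominator. This is
  conservative (neutral evidence) and keeps scores comparable across
  samples. For an odd number of samples every gene has exactly one such
  sample per cohort.
* **Missing signature genes** are dropped after case-insensitive symbol
  matching and shrink the denominator, preserving the [−1, 1] range.
  No ortholog lookup is attempted — mouse/human bridging relies on
  case-folded shared symbols, which keeps the package download-free.

Match is SSM ≥ 0 (a zero score is a match). For odd signature sizes SSM
cannot be exactly 0 when no gene sits at its median, so direction
flipping swaps the groups exactly; tests exploit this symmetry.

## Survival estimators

* **Cox PH** (lifelines, Efron ties) is the reported estimator, with
  Wald CI/p. Groups without events make the partial likelihood
  monotone; such fits are flagged non-estimable rather than raised.
* **O/E hazard ratio** HR ≈ (O₁/E₁)/(O₂/E₂) with expected events from
  the unweighted log-rank risk tables, plus the log-rank χ² p. This is
  the estimator used inside the 131,071-subset sweep and the
  permutation loops. The implementation computes O/E/V for *many*
  group assignments in one vectorised pass (suffix sums of a
  mask-by-sample boolean matrix evaluated at the unique event times),
  which is what makes 10⁵–10⁶ evaluations per cohort feasible on one
  CPU. Single-grouping calls are thin wrappers over the same pass, so
  sweep records and direct calls agree bit-for-bit. O/E agrees with
  Cox asymptotically (cross-checked by simulation at large n; within
  ~5% at n = 2000).
* **Wilcoxon p** is the Gehan–Breslow weighted log-rank (weights =
  number at risk), via lifelines.
* Follow-up times of 0 are shifted to 0.01 months rather than dropped.
  The 36-month ROC horizon never truncates survival fits.

## ROC

Outcomes are encoded into four ordered aggressiveness categories around
a 36-month horizon ("within" inclusive): censored after, censored
within, progressed after, progressed within. AUC treats progression
(categories 3–4) as truth and is the tie-corrected Mann–Whitney rank
statistic; the curve is an empirical threshold sweep. No binormal
model is fitted, so AUCs can differ slightly from binormal-fit tools on
identical data.

## Sweep, significance and core extraction

Subsets are bit-masks over the signature's entry order. Significance
requires p < α (default 0.05) on **both** the MFS and OS cohorts; with
the O/E estimator the p is the log-rank χ², with the Cox estimator the
Wald p. Degenerate subsets (everyone matches) get NaN HR/p and are
never significant; the sweep never aborts.

Pair-wise co-occurrence is the percentage of significant subsets
containing both genes of a pair — a symmetric joint frequency. The
partnering threshold is mean + 1 SD over the k(k−1)/2 pairs (sample
SD); partners are counted with strict >. Core1 = genes with ≥ 2
partners. The "top" set for Core2 is: significant subsets with HR ≥
margin × the full signature's HR on both endpoints (margin default
1.0, configurable because the comparable-or-better criterion admits
readings); Core2 additionally requires strictly above-median appearance
frequency, so exactly uniform frequencies select nothing. Core =
Core1 ∩ Core2, ordered and signed as in the parent signature.
Reported cores should be re-evaluated with the full Cox fit; the
O/E estimator is for the sweep interior.

## Substitutes

For each signature gene the substitute is the candidate with maximal
signed Pearson r across samples (|r| by flag; ties broken toward the
alphabetically first candidate). By default assignments are unique —
greedy in descending correlation order — so replacing all genes yields
a valid signature; per-gene unconstrained argmax is available with
`unique=False`. Substitutes inherit the replaced gene's direction even
when anti-correlated (flagged). The correlation matrix is whatever
expression the caller supplies; the platform the signature was derived
from is the natural choice, but nothing assumes it.

## Null models

Random signatures match the target's composition (n_up, n_down),
sampled uniformly without replacement from the universe (default: all
genes in the matrix; the target's own genes are *not* excluded, by
flag they can be). eFDR = fraction of draws with HR strictly greater
than the target's; a flag additionally requires the draw's p < 0.05.
Rank = 1 + that count (ties rank the target first). Non-evaluable
draws count as HR = 1 and are logged. Draws, hence eFDR, are fully
determined by (seed, universe, n_perm).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not any particular platform:

* log2 expression is N(7, 1) per gene; genes sharing a pathway block
  load on a latent factor giving exact pairwise correlation
  `block_rho` (default 0.5) with unit marginal variance. Each block
  carries `extra_per_block` (default 10) non-signature members — the
  candidate pool for substitute discovery. Remaining genes are
  independent noise.
* the risk score z is the mean of I_n × standardized expression over
  the *informative* signature genes; survival is exponential with
  hazard `baseline_hazard · exp(beta · z)` (defaults 0.01/month,
  censoring U(0, 120) months ⇒ ~40% events at beta = 0) — the simplest
  model satisfying proportional hazards.
* a fraction `frac_her2` (default 0.25) of samples get +log2(U(4, 8))
  on the five amplicon genes; the IHC label flips with
  `ihc_error_rate`. Amplicon genes carry reduced residual noise
  (sd 0.25), reflecting copy-number-dominated expression; this makes
  strong planted gains cleanly separable, which the caller's
  perfect-recovery tests rely on.
* the truth record stores z, the true amplification status, the planted
  match split and its implied hazard ratio, so recovery tests need no
  re-derivation. The planted match split is the SSM match of the
  *informative* sub-signature: when only some genes carry signal, the
  full-signature split is a noisy readout of z whose group contrast
  saturates, and the informative subset is the meaningful ground truth.

`calibrate_beta` inverts the beta → group-HR mapping by bracketed
bisection on one large deterministic cohort (default n = 6000), with
the Cox estimand defining the target by default. The mapping saturates
(the match split cannot separate groups beyond what the score noise
allows); an unreachable target returns the bracket edge with a warning
rather than diverging.

Passing tests on these cohorts shows the machinery recovers what was
planted under correct model assumptions; it does not certify behaviour
under platform effects, batch structure, non-proportional hazards or
informative censoring, none of which the generator models.

## Study conditions used by the test suite and acceptance script

* Parameter recovery: n = 300 per cohort, ~40–45% events, beta
  calibrated to a group HR of 5 with all 17 genes informative; Cox HR
  measured over 100 seeded cohorts. The sampling SD of the log-HR at
  ~130 events is ≈ 0.20, so roughly 90% of estimates land in
  [3.5, 7.0]; the same check at n = 400 with ~50% events (~200 events,
  SD ≈ 0.15) reaches 95% and is tested in the survival module.
* Core recovery: 6 informative + 11 non-informative signature genes,
  n = 400 per endpoint, `block_rho = 0`. Independence is essential to
  the design: with correlated blocks the "noise" signature genes
  inherit signal from their informative block-mates and the
  informative/noise contrast the experiment is about disappears.
* Null sanity: no-signal cohorts (beta = 0), a random
  composition-matched target, 200 permutations; the eFDR is uniform on
  {0, 1/200, …, 1} so its mean over seeds is ~0.5.
* The acceptance script scales seed counts down (25 Cox cohorts, 5
  sweeps, 1000 permutations) to keep a full run under a minute; the
  test suite uses the larger counts above.

## Known limitations

* Two-group Cox only; no multivariate adjustment for clinical
  covariates.
* Empirical ROC only; no confidence bands on AUC.
* Gene matching is symbol-based; probes and orthologs are out of scope.
* The O/E estimator is undefined when a group has no expected events;
  inside sweeps such subsets are flagged, outside they raise.
* NanoString normalisation fixes each sample's control-gene geometric
  mean to the across-sample mean of those geometric means; rescaling
  one sample therefore changes the common target slightly (all samples
  shift by one global factor), though relative structure is exactly
  preserved.
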