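"""Expression-based HER2 status from the five-gene amplicon.

ERBB2 sits in a co-amplified chromosome-17 block together with STARD3,
PERLD1, GRB7 and C17orf37; joint over-expression of the block is a
reliable surrogate for a positive HER2 IHC/FISH result when no
pathology labels ship with a cohort.  A sample is called HER2+ when
strictly more than ``fold_cutoff``-fold elevation over the per-gene
median is seen in at least ``min_genes`` of the amplicon genes
(defaults: 2-fold, 3 of 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .resources import load_amplicon_genes


@dataclass
class AmpliconConfig:
    amplicon_genes: list[str] = field(default_factory=load_amplicon_genes)
    fold_cutoff: float = 2.0
    min_genes: int = 3

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1:
            raise ValueError("fold_cutoff must be > 1")
        if self.min_genes > len(self.amplicon_genes):
            raise ValueError("min_genes exceeds number of amplicon genes")


@dataclass
class AmpliconCall:
    fold_change: pd.DataFrame  # linear fold vs per-gene median, genes x samples
    n_elevated: pd.Series | None = None
    her2_call: pd.Series | None = None


@dataclass
class ConcordanceReport:
    table: pd.DataFrame  # 2x2, call x IHC
    ppv: float
    sensitivity: float
    specificity: float
    concordance_rate: float
    kappa: float
    fisher_p: float


def amplicon_fold_changes(
    expr: ExpressionMatrix, cfg: AmpliconConfig | None = None, per_cohort: bool = False
) -> AmpliconCall:
    """Linear fold change of each amplicon gene vs its median.

    Input is log2 scale; fold = 2^(x − median).  Medians are taken over
    the pooled sample set by default (``per_cohort`` switches to
    within-cohort medians).  Missing amplicon genes raise, listing them.
    """
    cfg = cfg or AmpliconConfig()
    lookup = {g.casefold(): g for g in expr.gene_ids}
    rows = [lookup.get(g.casefold()) for g in cfg.amplicon_genes]
    missing = [g for g, r in zip(cfg.amplicon_genes, rows) if r is None]
    if missing:
        raise KeyError(f"amplicon genes absent from matrix: {missing}")
    sub = expr.values.loc[rows]
    if per_cohort:
        centered = []
        for _, samples in expr.cohorts.groupby(expr.cohorts):
            block = sub[samples.index]
            centered.append(block.sub(block.median(axis=1), axis=0))
        delta = pd.concat(centered, axis=1)[sub.columns]
    else:
        delta = sub.sub(sub.median(axis=1), axis=0)
    fc = np.power(2.0, delta)
    fc.index = cfg.amplicon_genes
    return AmpliconCall(fold_change=fc)


def call_her2(call: AmpliconCall, cfg: AmpliconConfig | None = None) -> AmpliconCall:
    """HER2+ when > fold_cutoff elevation in ≥ min_genes amplicon genes.

    The cutoff is strict: a fold of exactly ``fold_cutoff`` does not
    count as elevated.
    """
    cfg = cfg or AmpliconConfig()
    n_elev = (call.fold_change > cfg.fold_cutoff).sum(axis=0)
    call.n_elevated = n_elev.rename("n_elevated")
    call.her2_call = (n_elev >= cfg.min_genes).rename("her2_call")
    return call


def concordance(calls, ihc) -> ConcordanceReport:
    """Agreement of expression-based calls with binary IHC labels.

    Returns the 2x2 table plus PPV, sensitivity, specificity,
    concordance rate, Cohen's kappa and a two-sided Fisher's exact p.
    Requires at least one sample in each IHC class.
    """
    from sklearn.metrics import cohen_kappa_score

    calls = np.asarray(calls, dtype=bool)
    ihc = np.asarray(ihc, dtype=bool)
    if calls.shape != ihc.shape:
        raise ValueError("calls and ihc must align")
    if ihc.all() or (~ihc).all():
        raise ValueError("degenerate table: an IHC class is empty")
    tp = int((calls & ihc).sum())
    fp = int((calls & ~ihc).sum())
    fn = int((~calls & ihc).sum())
    tn = int((~calls & ~ihc).sum())
    table = pd.DataFrame(
        [[tp, fp], [fn, tn]],
        index=pd.Index(["call+", "call-"], name="amplicon"),
        columns=pd.Index(["ihc+", "ihc-"], name="ihc"),
    )
    n = tp + fp + fn + tn
    kappa = 1.0 if (fp == 0 and fn == 0) else float(cohen_kappa_score(ihc, calls))
    return ConcordanceReport(
        table=table,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        concordance_rate=(tp + tn) / n,
        kappa=kappa,
        fisher_p=float(stats.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")[1]),
    )
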