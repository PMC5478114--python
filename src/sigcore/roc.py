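"""Outcome encoding and empirical ROC/AUC.

Survival outcomes are folded into four ordered aggressiveness
categories around a horizon (36 months by default): 1 = disease-free
past the horizon, 2 = disease-free but censored within it, 3 =
progressed after it, 4 = progressed within it.  For AUC the binary
truth is progression (categories 3–4) vs disease-free (1–2); the
4-level code is kept for ordinal analyses.

AUC is the tie-corrected Mann–Whitney rank statistic — the fraction of
(positive, negative) pairs ranked concordantly, ties counted ½ — and
the curve is an empirical threshold sweep, not a binormal fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ROCResult:
    ratings: np.ndarray
    truth: np.ndarray
    curve_points: pd.DataFrame  # columns fpr, tpr
    auc: float


def encode_outcome(times, events, horizon: float = 36.0) -> np.ndarray:
    """Four-category aggressiveness code; "within" is inclusive (≤)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival time")
    cat = np.where(
        events == 1,
        np.where(times <= horizon, 4, 3),
        np.where(times <= horizon, 2, 1),
    )
    return cat


def outcome_truth(categories: np.ndarray) -> np.ndarray:
    """Binary truth for ROC: progressed (3, 4) vs disease-free (1, 2)."""
    return np.asarray(categories) >= 3


def auc_rank(ratings, truth) -> ROCResult:
    """Rank (Mann–Whitney) AUC with tie correction plus the ROC curve.

    Raises when a truth class is absent.
    """
    ratings = np.asarray(ratings, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both truth classes must be present")
    ranks = stats.rankdata(ratings)
    auc = (ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # threshold sweep over descending unique ratings
    order = np.argsort(-ratings, kind="stable")
    r_sorted = ratings[order]
    t_sorted = truth[order]
    tps = np.cumsum(t_sorted)
    fps = np.cumsum(~t_sorted)
    last_of_value = np.flatnonzero(np.r_[np.diff(r_sorted) != 0, True])
    tpr = np.r_[0.0, tps[last_of_value] / n_pos]
    fpr = np.r_[0.0, fps[last_of_value] / n_neg]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return ROCResult(ratings=ratings, truth=truth, curve_points=curve, auc=float(auc))
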