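"""Two-group survival comparison: Kaplan–Meier, Wilcoxon p, hazard ratios.

Two hazard-ratio estimators are exposed:

* :func:`cox_hr` — the reported estimator: a two-group Cox
  proportional-hazards fit (Efron ties) with Wald CI and p.
* :func:`oe_hr` — the fast observed/expected estimator
  HR ≈ (O₁/E₁)/(O₂/E₂) with expected event counts from the log-rank
  risk tables.  It agrees with Cox asymptotically and is what the
  exhaustive sub-signature sweep and the permutation null loops use,
  where 10⁵–10⁶ group assignments must be evaluated.

The heart of the module is :func:`logrank_counts`, which computes the
log-rank O/E/variance triplet for *many* candidate group assignments at
once (an M x n boolean matrix) with a single pass over the risk tables.
All single-grouping functions are thin wrappers over it, so a sweep and
a direct per-signature call are guaranteed to agree bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix, GeneSignature, median_center

MIN_TIME_MONTHS = 0.01  # zero follow-up times are shifted here, not dropped


# ---------------------------------------------------------------------------
# vectorised log-rank machinery


@dataclass
class PreparedSurvival:
    """Time-sorted survival arrays plus unique-event-time risk tables."""

    order: np.ndarray          # argsort of the input times
    times: np.ndarray          # sorted
    events: np.ndarray         # sorted, 0/1
    event_cols: np.ndarray     # sorted positions with an event
    seg_starts: np.ndarray     # reduceat boundaries over event_cols (ties grouped)
    risk_idx: np.ndarray       # first sorted position with time >= each event time
    n_at_risk: np.ndarray      # overall at-risk count per unique event time
    d: np.ndarray              # events per unique event time

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def total_events(self) -> int:
        return int(self.d.sum())


def prepare_survival(times, events) -> PreparedSurvival:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival time")
    times = np.where(times <= 0, MIN_TIME_MONTHS, times)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    ev = np.flatnonzero(e == 1)
    te = t[ev]
    seg = np.flatnonzero(np.r_[True, np.diff(te) > 0]) if len(te) else np.array([], int)
    ut = te[seg] if len(te) else np.array([])
    risk_idx = np.searchsorted(t, ut, side="left")
    d = (
        np.add.reduceat(np.ones(len(ev)), seg).astype(int)
        if len(ev)
        else np.array([], int)
    )
    return PreparedSurvival(order, t, e, ev, seg, risk_idx, len(t) - risk_idx, d)


def logrank_counts(
    prep: PreparedSurvival, groups: np.ndarray, chunk: int = 8192
) -> dict[str, np.ndarray]:
    """Log-rank O/E/V for many group assignments at once.

    Parameters
    ----------
    prep
        Output of :func:`prepare_survival`.
    groups
        Boolean array of shape (M, n) or (n,); True marks group 1
        membership ("match"), in the *original* (unsorted) sample order.

    Returns
    -------
    dict with arrays of length M: ``O1, E1, V`` (group-1 observed and
    expected events, hypergeometric variance), plus scalars ``D``
    (total events) and per-row ``n1`` (group-1 sizes).
    """
    groups = np.atleast_2d(np.asarray(groups, dtype=bool))
    if groups.shape[1] != prep.n:
        raise ValueError("groups shape does not match sample count")
    m = groups.shape[0]
    O1 = np.empty(m)
    E1 = np.empty(m)
    V = np.empty(m)
    n1 = groups.sum(axis=1)
    nk = prep.n_at_risk.astype(float)
    dk = prep.d.astype(float)
    hyper = dk * (nk - dk) / np.maximum(nk - 1.0, 1.0)
    for lo in range(0, m, chunk):
        g = groups[lo : lo + chunk][:, prep.order]
        gf = np.ascontiguousarray(g, dtype=np.float64)
        # suffix sums give group-1 at-risk counts at any sorted position
        at_risk = np.flip(np.cumsum(np.flip(gf, axis=1), axis=1), axis=1)
        if len(prep.risk_idx):
            n1k = at_risk[:, prep.risk_idx]
            d1k = np.add.reduceat(gf[:, prep.event_cols], prep.seg_starts, axis=1)
            frac = n1k / nk
            O1[lo : lo + chunk] = d1k.sum(axis=1)
            E1[lo : lo + chunk] = frac @ dk
            V[lo : lo + chunk] = (frac * (1.0 - frac)) @ hyper
        else:
            O1[lo : lo + chunk] = 0.0
            E1[lo : lo + chunk] = 0.0
            V[lo : lo + chunk] = 0.0
    return {"O1": O1, "E1": E1, "V": V, "D": prep.total_events, "n1": n1}


def oe_hr_from_counts(o1: float, e1: float, o2: float, e2: float) -> float:
    """(O₁/E₁)/(O₂/E₂); raises on zero expected counts."""
    if e1 <= 0 or e2 <= 0:
        raise ValueError("expected event count is zero; HR non-estimable")
    if o2 == 0:
        return np.inf if o1 > 0 else np.nan
    return (o1 / e1) / (o2 / e2)


def oe_hr_many(prep: PreparedSurvival, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (HR, log-rank p) for many group assignments.

    Non-estimable rows (a group empty or with zero expected events)
    come back as NaN rather than raising, so exhaustive sweeps never
    abort.
    """
    c = logrank_counts(prep, groups)
    O1, E1, V, D = c["O1"], c["E1"], c["V"], c["D"]
    O2, E2 = D - O1, D - E1
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (O1 / E1) / (O2 / E2)
        chi2 = (O1 - E1) ** 2 / V
    p = stats.chi2.sf(chi2, df=1)
    bad = (E1 <= 0) | (E2 <= 0) | (V <= 0)
    hr = np.where(bad, np.nan, hr)
    p = np.where(bad, np.nan, p)
    return hr, p


def oe_hr(times, events, groups) -> float:
    """Observed/expected hazard ratio for one grouping (group 1 vs 2)."""
    prep = prepare_survival(times, events)
    c = logrank_counts(prep, np.asarray(groups, dtype=bool))
    return oe_hr_from_counts(c["O1"][0], c["E1"][0], c["D"] - c["O1"][0], c["D"] - c["E1"][0])


def logrank_p(times, events, groups) -> float:
    """Two-sided unweighted log-rank p for one grouping."""
    prep = prepare_survival(times, events)
    _, p = oe_hr_many(prep, np.asarray(groups, dtype=bool))
    return float(p[0])


# ---------------------------------------------------------------------------
# single-grouping estimators (lifelines-backed)


def km_estimate(times, events, groups) -> dict[object, pd.DataFrame]:
    """Product-limit survival curve per group (right censoring).

    Returns, per group label, a frame with columns ``time`` and
    ``survival`` (right-continuous step function starting at 1).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    curves: dict[object, pd.DataFrame] = {}
    for label in pd.unique(groups):
        sel = groups == label
        if sel.sum() == 0:
            raise ValueError(f"group {label!r} has no samples")
        kmf = KaplanMeierFitter()
        kmf.fit(np.where(times[sel] <= 0, MIN_TIME_MONTHS, times[sel]), events[sel])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return curves


def wilcoxon_test(times, events, groups) -> float:
    """Gehan–Breslow–Wilcoxon p (log-rank weighted by number at risk)."""
    from lifelines.statistics import multivariate_logrank_test

    groups = np.asarray(groups)
    if len(pd.unique(groups)) != 2:
        raise ValueError("wilcoxon_test needs exactly two groups")
    times = np.where(np.asarray(times, dtype=float) <= 0, MIN_TIME_MONTHS, times)
    res = multivariate_logrank_test(times, groups, events, weightings="wilcoxon")
    return float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci: tuple[float, float]
    p: float
    estimable: bool = True
    reason: str = ""


def cox_hr(times, events, groups) -> CoxResult:
    """Two-group Cox PH fit; HR for group True vs False (Efron ties).

    When a group has no events the partial likelihood is monotone and
    the HR is flagged non-estimable instead of crashing.
    """
    from lifelines import CoxPHFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=bool)
    for label, sel in (("group 1", g), ("group 2", ~g)):
        if sel.sum() == 0 or events[sel].sum() == 0:
            return CoxResult(np.nan, (np.nan, np.nan), np.nan, False, f"no events in {label}")
    df = pd.DataFrame(
        {
            "time": np.where(times <= 0, MIN_TIME_MONTHS, times),
            "event": events,
            "group": g.astype(float),
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # convergence failure on degenerate data
            return CoxResult(np.nan, (np.nan, np.nan), np.nan, False, str(exc))
    row = cph.summary.loc["group"]
    return CoxResult(
        hr=float(np.exp(row["coef"])),
        ci=(float(np.exp(row["coef lower 95%"])), float(np.exp(row["coef upper 95%"]))),
        p=float(row["p"]),
    )


# ---------------------------------------------------------------------------
# signature-level evaluation


@dataclass
class SubtypeFilter:
    """Patient-subset filter applied before scoring.

    ``her2_source`` selects where the HER2 call comes from: recorded
    IHC labels or the expression-based five-gene amplicon caller.
    """

    require_her2: bool = False
    require_er_negative: bool = False
    her2_source: str = "ihc"  # "ihc" | "amplicon"


@dataclass
class SurvivalComparison:
    """Match vs no-match survival comparison for one signature."""

    evaluable: bool
    reason: str = ""
    groups: pd.Series | None = None
    n_match: int = 0
    n_nomatch: int = 0
    km_curves: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    wilcoxon_p: float = np.nan
    hr: float = np.nan
    hr_ci: tuple[float, float] = (np.nan, np.nan)
    cox_p: float = np.nan
    oe_components: dict = field(default_factory=dict)
    oe_hr: float = np.nan
    ssm: pd.Series | None = None


def _subtype_samples(
    expr: ExpressionMatrix, clin: pd.DataFrame, flt: SubtypeFilter
) -> list[str]:
    keep = pd.Series(True, index=clin.index)
    if flt.require_her2:
        if flt.her2_source == "ihc":
            keep &= clin["her2_ihc"] == "positive"
        elif flt.her2_source == "amplicon":
            from .amplicon import AmpliconConfig, amplicon_fold_changes, call_her2

            call = call_her2(amplicon_fold_changes(expr, AmpliconConfig()), AmpliconConfig())
            keep &= call.her2_call.reindex(clin.index).fillna(False).astype(bool)
        else:
            raise ValueError(f"unknown her2_source {flt.her2_source!r}")
    if flt.require_er_negative:
        keep &= clin["er_status"] == "negative"
    return list(clin.index[keep])


def evaluate_signature(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    signature: GeneSignature,
    subtype: SubtypeFilter | None = None,
    endpoint: str | None = None,
    per_cohort_centering: bool = True,
    already_centered: bool = False,
) -> SurvivalComparison:
    """Filter → center → SSM → KM + Wilcoxon + Cox, end to end.

    Returns a structured non-evaluable result (rather than raising)
    when the filtered cohort has fewer than two samples in either SSM
    group.
    """
    from .ssm import ssm_scores

    clin = clinical.df.set_index("sample")
    samples = [s for s in expr.sample_ids if s in clin.index]
    clin = clin.loc[samples]
    if endpoint is not None:
        clin = clin[clin["endpoint"] == endpoint]
    if subtype is not None:
        sub_expr = expr.subset_samples(list(clin.index))
        clin = clin.loc[_subtype_samples(sub_expr, clin, subtype)]
    if len(clin) == 0:
        return SurvivalComparison(False, "no samples after filtering")
    work = expr.subset_samples(list(clin.index))
    if not already_centered:
        work = median_center(work, per_cohort=per_cohort_centering)
    res = ssm_scores(work, signature)
    groups = res.match
    n1, n0 = int(groups.sum()), int((~groups).sum())
    if n1 < 2 or n0 < 2:
        return SurvivalComparison(
            False, f"degenerate SSM split (match={n1}, no-match={n0})", groups=groups, ssm=res.ssm
        )
    t = clin["time_months"].to_numpy(dtype=float)
    e = clin["event"].to_numpy(dtype=int)
    g = groups.to_numpy()
    prep = prepare_survival(t, e)
    counts = logrank_counts(prep, g)
    o1, e1 = float(counts["O1"][0]), float(counts["E1"][0])
    o2, e2 = counts["D"] - o1, counts["D"] - e1
    cox = cox_hr(t, e, g)
    try:
        oe = oe_hr_from_counts(o1, e1, o2, e2)
    except ValueError:
        oe = np.nan
    return SurvivalComparison(
        evaluable=True,
        groups=groups,
        n_match=n1,
        n_nomatch=n0,
        km_curves=km_estimate(t, e, np.where(g, "match", "no-match")),
        wilcoxon_p=wilcoxon_test(t, e, g),
        hr=cox.hr,
        hr_ci=cox.ci,
        cox_p=cox.p,
        oe_components={"O": (o1, o2), "E": (e1, e2)},
        oe_hr=oe,
        ssm=res.ssm,
    )
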