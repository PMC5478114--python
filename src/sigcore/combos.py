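"""Exhaustive sub-signature sweep and core-gene extraction.

A k-gene signed signature has 2^k − 1 non-empty gene subsets (131,071
for k = 17).  Each subset is itself a signature: its SSM match/no-match
split is evaluated for a hazard ratio and p-value on a metastasis-free
survival (MFS) cohort and an overall survival (OS) cohort, and called
*significant* when p < α on both endpoints.

Core extraction then asks which genes "travel together" through the
significant subsets: the pair-wise co-occurrence matrix (percentage of
significant subsets containing both genes of a pair) is thresholded at
mean + 1 SD of the off-diagonal pairs, and genes that pair with ≥ 2
partners above that threshold form Core1.  Repeating the analysis on
the top-performing subsets (HR ≥ the full signature on both endpoints)
with an additional above-median frequency filter gives Core2; the Core
is their intersection.

The sweep is fully vectorised: per endpoint a k x n matrix of signed
per-gene scores I_n·sign(X_n) is built once, subset SSM splits follow
from a bit-matrix product, and hazard ratios come from the grouped
log-rank machinery in :mod:`sigcore.survival`.  The O/E estimator is
the default inside the sweep; reported cores should be re-evaluated
with the full Cox fit afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSignature, median_center
from .ssm import ssm_scores
from .survival import PreparedSurvival, cox_hr, oe_hr_many, prepare_survival

logger = logging.getLogger(__name__)

MAX_ENUM_GENES = 24
RECORD_COLUMNS = ["mask", "size", "hr_mfs", "p_mfs", "hr_os", "p_os", "significant"]


def enumerate_combinations(signature: GeneSignature | int) -> Iterator[int]:
    """Yield every non-empty gene-subset bit-mask exactly once.

    Bit i of a mask selects entry i of the signature; there are
    2^k − 1 masks.  Refuses k > 24 (pre-select a subset first).
    """
    k = signature if isinstance(signature, int) else len(signature)
    if k < 1:
        raise ValueError("need at least one gene")
    if k > MAX_ENUM_GENES:
        raise ValueError(
            f"k={k} would enumerate {2**k - 1:,} subsets; pre-select at most {MAX_ENUM_GENES} genes"
        )
    return iter(range(1, 2**k))


@dataclass
class PreparedEndpoint:
    """One endpoint cohort reduced to sweep-ready arrays."""

    gene_scores: np.ndarray  # k x n, entries in {-1, 0, +1}
    prep: PreparedSurvival
    n_samples: int


def prepare_endpoint(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    signature: GeneSignature,
    endpoint: str | None = None,
    per_cohort_centering: bool = True,
    already_centered: bool = False,
) -> PreparedEndpoint:
    """Center, score and time-sort one cohort for the sweep."""
    clin = clinical.df.set_index("sample")
    if endpoint is not None:
        clin = clin[clin["endpoint"] == endpoint]
    samples = [s for s in expr.sample_ids if s in clin.index]
    clin = clin.loc[samples]
    work = expr.subset_samples(samples)
    if not already_centered:
        work = median_center(work, per_cohort=per_cohort_centering)
    res = ssm_scores(work, signature)
    if list(res.per_gene_score.index) != signature.genes:
        # keep mask bit order aligned with the signature as given
        missing = [g for g in signature.genes if g not in set(res.per_gene_score.index)]
        raise KeyError(f"signature genes absent from cohort: {missing}")
    scores = res.per_gene_score.to_numpy(dtype=np.float64)
    prep = prepare_survival(
        clin["time_months"].to_numpy(dtype=float), clin["event"].to_numpy(dtype=int)
    )
    return PreparedEndpoint(scores, prep, len(samples))


def _mask_bits(masks: np.ndarray, k: int) -> np.ndarray:
    return ((masks[:, None] >> np.arange(k)) & 1).astype(np.float64)


def _sweep_endpoint(
    ep: PreparedEndpoint, masks: np.ndarray, estimator: str, chunk: int
) -> tuple[np.ndarray, np.ndarray]:
    k = ep.gene_scores.shape[0]
    hr = np.empty(len(masks))
    p = np.empty(len(masks))
    for lo in range(0, len(masks), chunk):
        mk = masks[lo : lo + chunk]
        bits = _mask_bits(mk, k)
        groups = (bits @ ep.gene_scores) >= 0.0  # SSM >= 0 per subset
        if estimator == "oe":
            hr[lo : lo + chunk], p[lo : lo + chunk] = oe_hr_many(ep.prep, groups)
        elif estimator == "cox":
            t = np.empty(ep.prep.n)
            t[ep.prep.order] = ep.prep.times
            e = np.empty(ep.prep.n, dtype=int)
            e[ep.prep.order] = ep.prep.events
            for j, g in enumerate(groups):
                res = cox_hr(t, e, g)
                hr[lo + j], p[lo + j] = res.hr, res.p
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        if (lo // chunk) % 4 == 0:
            logger.info("combination sweep: %d / %d masks", min(lo + chunk, len(masks)), len(masks))
    return hr, p


def evaluate_all(
    expr_mfs: ExpressionMatrix,
    clin_mfs: ClinicalTable,
    expr_os: ExpressionMatrix,
    clin_os: ClinicalTable,
    signature: GeneSignature,
    alpha: float = 0.05,
    hr_estimator: str = "oe",
    per_cohort_centering: bool = True,
    already_centered: bool = False,
    masks: Iterable[int] | None = None,
    chunk: int = 4096,
) -> pd.DataFrame:
    """Evaluate every gene subset on both endpoints.

    Returns a frame with one row per mask: ``mask, size, hr_mfs, p_mfs,
    hr_os, p_os, significant`` (significant ⇔ p < α on *both*
    endpoints).  Subsets whose SSM split is degenerate on a cohort get
    NaN HR/p there and are never significant; the sweep does not abort.
    The frame's ``attrs["genes"]`` records the bit order.
    """
    ep_mfs = prepare_endpoint(
        expr_mfs, clin_mfs, signature, None, per_cohort_centering, already_centered
    )
    ep_os = prepare_endpoint(
        expr_os, clin_os, signature, None, per_cohort_centering, already_centered
    )
    k = len(signature)
    mask_arr = (
        np.fromiter(enumerate_combinations(k), dtype=np.int64, count=2**k - 1)
        if masks is None
        else np.asarray(list(masks), dtype=np.int64)
    )
    hr_mfs, p_mfs = _sweep_endpoint(ep_mfs, mask_arr, hr_estimator, chunk)
    hr_os, p_os = _sweep_endpoint(ep_os, mask_arr, hr_estimator, chunk)
    size = _mask_bits(mask_arr, k).sum(axis=1).astype(int)
    with np.errstate(invalid="ignore"):
        significant = (p_mfs < alpha) & (p_os < alpha)
    records = pd.DataFrame(
        {
            "mask": mask_arr,
            "size": size,
            "hr_mfs": hr_mfs,
            "p_mfs": p_mfs,
            "hr_os": hr_os,
            "p_os": p_os,
            "significant": np.where(np.isnan(p_mfs) | np.isnan(p_os), False, significant),
        }
    )
    records.attrs["genes"] = list(signature.genes)
    return records


def records_to_tsv(records: pd.DataFrame, path, genes: Sequence[str] | None = None) -> None:
    """Write a sweep table with human-readable gene lists per mask."""
    genes = list(genes or records.attrs.get("genes", []))
    out = records.copy()
    if genes:
        k = len(genes)
        out.insert(
            0,
            "genes",
            ["+".join(g for i, g in enumerate(genes) if (m >> i) & 1) for m in out["mask"]],
        )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pair-wise co-occurrence and cores


@dataclass
class PairwiseStats:
    cooccurrence: pd.DataFrame  # k x k, % of records containing both genes
    mean_overlap: float
    sd_overlap: float
    threshold: float  # mean + 1 SD
    partner_count: pd.Series
    gene_frequency: pd.Series  # % of records containing each gene
    n_records: int


def partner_threshold(mean_overlap: float, sd_overlap: float) -> float:
    """Pairing threshold: 1 SD above the mean pair-overlap percentage."""
    return mean_overlap + sd_overlap


def pairwise_cooccurrence(
    records: pd.DataFrame, genes: Sequence[str] | None = None
) -> PairwiseStats:
    """Pair-wise co-occurrence percentages over a set of subset records.

    ``cooccurrence[i, j]`` is the percentage of records whose mask
    contains both gene i and gene j.  The mean and SD are taken over
    the k(k−1)/2 off-diagonal pairs; the partnering threshold is
    mean + 1 SD, and a gene's ``partner_count`` is the number of other
    genes it exceeds the threshold with (strict >).
    """
    genes = list(genes or records.attrs.get("genes", []))
    if not genes:
        raise ValueError("gene order unknown; pass genes=")
    if len(records) == 0:
        raise ValueError("no records")
    bits = _mask_bits(records["mask"].to_numpy(dtype=np.int64), len(genes))
    counts = bits.T @ bits
    pct = 100.0 * counts / len(records)
    k = len(genes)
    iu = np.triu_indices(k, 1)
    mean = float(pct[iu].mean())
    sd = float(pct[iu].std(ddof=1)) if len(iu[0]) > 1 else 0.0
    thr = partner_threshold(mean, sd)
    off = pct - np.diag(np.diag(pct))
    partner = (off > thr).sum(axis=1)
    return PairwiseStats(
        cooccurrence=pd.DataFrame(pct, index=genes, columns=genes),
        mean_overlap=mean,
        sd_overlap=sd,
        threshold=thr,
        partner_count=pd.Series(partner, index=genes, name="partner_count"),
        gene_frequency=pd.Series(np.diag(pct), index=genes, name="gene_frequency"),
        n_records=len(records),
    )


def select_core1(stats: PairwiseStats, min_partners: int = 2) -> list[str]:
    """Genes that pair with ≥ min_partners others above the threshold."""
    keep = stats.partner_count >= min_partners
    return list(stats.partner_count.index[keep])


def select_top(
    records: pd.DataFrame, reference: pd.Series | tuple[float, float], margin: float = 1.0
) -> pd.DataFrame:
    """Significant subsets scoring at least as well as the reference.

    ``reference`` is the full-signature record (or an ``(hr_mfs,
    hr_os)`` pair); a subset qualifies when significant and its HR is
    ≥ margin x reference on *both* endpoints.
    """
    if isinstance(reference, pd.Series):
        ref_mfs, ref_os = float(reference["hr_mfs"]), float(reference["hr_os"])
    else:
        ref_mfs, ref_os = map(float, reference)
    sel = (
        records["significant"]
        & (records["hr_mfs"] >= margin * ref_mfs)
        & (records["hr_os"] >= margin * ref_os)
    )
    top = records[sel].copy()
    top.attrs["genes"] = records.attrs.get("genes", [])
    return top


def select_core2(
    top_records: pd.DataFrame,
    genes: Sequence[str] | None = None,
    min_partners: int = 2,
) -> list[str]:
    """Core2: partnered genes with strictly above-median frequency.

    Runs the pair-wise analysis on the top record set and keeps genes
    with ``partner_count ≥ min_partners`` whose appearance frequency is
    strictly greater than the median frequency (so exactly uniform
    frequencies select nothing).
    """
    stats = pairwise_cooccurrence(top_records, genes)
    med = float(stats.gene_frequency.median())
    keep = (stats.partner_count >= min_partners) & (stats.gene_frequency > med)
    return list(stats.gene_frequency.index[keep])


@dataclass
class CoreResult:
    core1: list[str]
    core2: list[str]
    core: list[str]
    stats1: PairwiseStats | None = None
    stats2: PairwiseStats | None = None


def intersect_cores(
    core1: Iterable[str], core2: Iterable[str], parent: GeneSignature | None = None
) -> list[str] | GeneSignature:
    """Core = Core1 ∩ Core2, ordered (and signed) as in the parent."""
    inter = set(core1) & set(core2)
    if parent is None:
        return sorted(inter)
    return parent.subset([g for g in parent.genes if g in inter], name="core")


def extract_cores(
    records: pd.DataFrame,
    genes: Sequence[str] | None = None,
    min_partners: int = 2,
    margin: float = 1.0,
) -> CoreResult:
    """Full Core1/Core2/Core extraction from a sweep record table."""
    genes = list(genes or records.attrs.get("genes", []))
    sig_records = records[records["significant"]].copy()
    sig_records.attrs["genes"] = genes
    if len(sig_records) == 0:
        raise ValueError("no significant records; cannot extract cores")
    stats1 = pairwise_cooccurrence(sig_records, genes)
    core1 = select_core1(stats1, min_partners)
    full_mask = (1 << len(genes)) - 1
    ref_rows = records[records["mask"] == full_mask]
    if len(ref_rows):
        reference = ref_rows.iloc[0]
    else:
        reference = (float(sig_records["hr_mfs"].max()), float(sig_records["hr_os"].max()))
    top = select_top(records, reference, margin)
    if len(top) == 0:
        return CoreResult(core1, [], [], stats1, None)
    stats2 = pairwise_cooccurrence(top, genes)
    core2 = select_core2(top, genes, min_partners)
    core = [g for g in genes if g in set(core1) & set(core2)]
    return CoreResult(core1, core2, core, stats1, stats2)


# ---------------------------------------------------------------------------
# pathway-level views


def pathway_coverage(
    records: pd.DataFrame, signature: GeneSignature
) -> tuple[list[set[str]], pd.DataFrame]:
    """Pathways represented in each record, plus summary frequencies.

    Returns (per-record pathway sets, summary frame).  The summary has
    one row per pathway with the fraction of records containing it, and
    ``attrs["n_pathways_distribution"]`` tallies how many pathways each
    record covers.
    """
    if any(p == "" for p in signature.pathways):
        raise ValueError("every signature gene needs a pathway label")
    genes = records.attrs.get("genes", signature.genes)
    pw = {g: p for g, p in zip(signature.genes, signature.pathways)}
    per_record: list[set[str]] = []
    for m in records["mask"]:
        present = {pw[g] for i, g in enumerate(genes) if (m >> i) & 1}
        per_record.append(present)
    all_pw = list(dict.fromkeys(signature.pathways))
    frac = {
        p: (sum(p in s for s in per_record) / len(per_record) if len(per_record) else np.nan)
        for p in all_pw
    }
    summary = pd.DataFrame({"pathway": all_pw, "fraction_of_records": [frac[p] for p in all_pw]})
    counts = pd.Series([len(s) for s in per_record]).value_counts().sort_index()
    summary.attrs["n_pathways_distribution"] = counts.to_dict()
    return per_record, summary


def leave_one_pathway_out(signature: GeneSignature, pathway: str) -> GeneSignature:
    """Signature minus every gene of one pathway."""
    if pathway not in set(signature.pathways):
        raise KeyError(f"pathway {pathway!r} not in signature")
    keep = [e.gene for e in signature.entries if e.pathway != pathway]
    if not keep:
        raise ValueError("removing this pathway leaves no genes")
    return signature.subset(keep, name=f"{signature.name}-minus-{pathway}")
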