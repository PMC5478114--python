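"""Substitute-gene discovery and substituted signatures.

For each signature gene, the substitute is the candidate gene whose
expression profile correlates best (signed Pearson r, ties broken
alphabetically) across samples — typically computed on the platform
the signature was derived from.  Substitutes inherit the replaced
gene's direction, which lets a full or partial replacement signature
(an "alternative" signature) be scored exactly like the original.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature
from .roc import auc_rank
from .ssm import ssm_scores


@dataclass
class SubstitutionMap:
    """One substitute per signature gene.

    ``table`` columns: gene, substitute, r, pathway (substitute's),
    same_pathway, anticorrelated (flagged when the best candidate has
    r < 0 yet inherits the original direction).
    """

    table: pd.DataFrame

    def substitute_for(self, gene: str) -> str:
        row = self.table[self.table["gene"] == gene]
        if len(row) == 0:
            raise KeyError(f"no substitution entry for {gene!r}")
        return str(row["substitute"].iloc[0])


def substitution_map_from_table(df: pd.DataFrame) -> SubstitutionMap:
    """Build a map from a (gene, substitute[, ...]) table."""
    out = pd.DataFrame(
        {
            "gene": df["gene"].astype(str),
            "substitute": df["substitute"].astype(str),
            "r": df["r"] if "r" in df else np.nan,
            "pathway": df.get("substitute_pathway", df.get("pathway", "")),
            "same_pathway": df.get("same_pathway", np.nan),
            "anticorrelated": False,
        }
    )
    return SubstitutionMap(out.reset_index(drop=True))


def find_substitutes(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    candidates: Sequence[str],
    pathway_map: Mapping[str, str] | None = None,
    absolute: bool = False,
    unique: bool = True,
) -> SubstitutionMap:
    """Best-correlated candidate for every signature gene.

    Correlations are Pearson r across the samples of ``expr``;
    ``absolute=True`` ranks by |r| instead of signed r.  Candidates
    that are themselves signature genes are excluded.  Needs ≥ 3
    samples.

    With ``unique=True`` (default) no candidate substitutes for two
    genes: assignments are made greedily in descending correlation
    order, so a full replacement signature stays a valid signature.
    ``unique=False`` gives each gene its overall best candidate.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    sig_genes = [g for g in signature.genes if g in set(expr.gene_ids)]
    missing = set(signature.genes) - set(sig_genes)
    if missing:
        raise KeyError(f"signature genes absent from matrix: {sorted(missing)}")
    cand = sorted(set(candidates) - set(signature.genes))  # alphabetical => tie-break
    missing_c = set(cand) - set(expr.gene_ids)
    if missing_c:
        raise KeyError(f"candidate genes absent from matrix: {sorted(missing_c)[:5]}")
    X = expr.values.loc[sig_genes].to_numpy(dtype=float)
    Y = expr.values.loc[cand].to_numpy(dtype=float)

    def standardize(a: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        return np.divide(a, sd, out=np.zeros_like(a), where=sd > 0)

    r = (standardize(X) @ standardize(Y).T) / X.shape[1]
    score = np.abs(r) if absolute else r
    if unique:
        if len(cand) < len(sig_genes):
            raise ValueError("fewer candidates than signature genes; cannot assign uniquely")
        work = score.copy()
        best = np.empty(len(sig_genes), dtype=int)
        for _ in range(len(sig_genes)):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            best[i] = j
            work[i, :] = -np.inf
            work[:, j] = -np.inf
    else:
        best = np.argmax(score, axis=1)  # argmax takes first => alphabetical tie-break
    pw = pathway_map or {}
    sig_pw = {g: p for g, p in zip(signature.genes, signature.pathways)}
    rows = []
    for i, g in enumerate(sig_genes):
        sub = cand[best[i]]
        rows.append(
            {
                "gene": g,
                "substitute": sub,
                "r": float(r[i, best[i]]),
                "pathway": pw.get(sub, ""),
                "same_pathway": bool(pw.get(sub, "")) and pw.get(sub) == sig_pw.get(g),
                "anticorrelated": bool(r[i, best[i]] < 0),
            }
        )
    return SubstitutionMap(pd.DataFrame(rows))


def apply_substitution(
    signature: GeneSignature,
    submap: SubstitutionMap,
    genes_to_replace: Iterable[str] | str = "all",
    name: str | None = None,
) -> GeneSignature:
    """Replace some or all signature genes by their substitutes.

    Substitutes inherit the replaced gene's direction (and pathway
    label when the map carries none).
    """
    targets = set(signature.genes) if genes_to_replace == "all" else set(genes_to_replace)
    unknown = targets - set(signature.genes)
    if unknown:
        raise KeyError(f"not signature genes: {sorted(unknown)}")
    entries = []
    for e in signature.entries:
        if e.gene in targets:
            sub = submap.substitute_for(e.gene)  # raises on missing entry
            row = submap.table[submap.table["gene"] == e.gene].iloc[0]
            pathway = str(row["pathway"]) or e.pathway
            entries.append(replace(e, gene=sub, pathway=pathway))
        else:
            entries.append(e)
    suffix = "alt" if genes_to_replace == "all" else "m"
    return GeneSignature(entries, name or f"{signature.name}-{suffix}")


def score_agreement(
    centered: ExpressionMatrix, sig_a: GeneSignature, sig_b: GeneSignature
) -> tuple[float, float]:
    """How closely two signatures score the same samples.

    Returns (Pearson r between the per-sample SSM scores, AUC treating
    sig_a's match call as truth and sig_b's SSM as rating).  ``expr``
    must be median-centered.  Degenerate (constant) scores give NaN r.
    """
    a = ssm_scores(centered, sig_a)
    b = ssm_scores(centered, sig_b)
    sa, sb = a.ssm.to_numpy(), b.ssm.reindex(a.ssm.index).to_numpy()
    if np.std(sa) == 0 or np.std(sb) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(sa, sb)[0, 1])
    truth = a.match.to_numpy()
    if truth.all() or (~truth).all():
        auc = np.nan
    else:
        auc = auc_rank(sb, truth).auc
    return r, auc
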