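"""Score for Signature Match (SSM) classification.

For a signed signature with directions I_n ∈ {+1, −1} and a
median-centered expression matrix X, each gene contributes
I_n · sign(X_n) to a sample's score; the SSM is the sum of those
contributions divided by the number of signature genes scored, so it
lies in [−1, 1].  A sample at exactly the cohort median for a gene
(X_n = 0) contributes 0 but stays in the denominator — neutral
evidence, keeping scores comparable across samples.  Samples with
SSM ≥ 0 are called a *match* for the signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature, map_gene_ids


@dataclass
class SSMResult:
    """Per-sample SSM scores and match calls.

    ``per_gene_score`` is a (signature genes x samples) frame with
    entries in {−1, 0, +1}; ``ssm`` the per-sample score in [−1, 1];
    ``match`` the binary call (ssm ≥ 0); ``effective_weight`` the
    number of genes with a non-zero contribution per sample;
    ``denominator`` the fixed per-signature weight (genes present).
    """

    per_gene_score: pd.DataFrame
    ssm: pd.Series
    match: pd.Series
    effective_weight: pd.Series
    denominator: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ssm.index)


def ssm_scores(centered: ExpressionMatrix, signature: GeneSignature) -> SSMResult:
    """Score every sample against a signed signature.

    ``centered`` must already be median-centered (see
    :func:`sigcore.io.median_center`).  Signature genes absent from the
    matrix are dropped (case-insensitive match); they reduce the
    denominator, preserving the [−1, 1] range.  Raises ``ValueError``
    when no signature gene is present.
    """
    sig, _ = map_gene_ids(signature, centered)
    x = centered.values.loc[sig.genes].to_numpy(dtype=float)
    scores = sig.directions[:, None] * np.sign(x)
    denom = len(sig)
    ssm = scores.sum(axis=0) / denom
    per_gene = pd.DataFrame(
        scores.astype(int), index=sig.genes, columns=centered.sample_ids
    )
    ssm_s = pd.Series(ssm, index=centered.sample_ids, name="ssm")
    return SSMResult(
        per_gene_score=per_gene,
        ssm=ssm_s,
        match=classify_match(ssm_s),
        effective_weight=pd.Series(
            (scores != 0).sum(axis=0), index=centered.sample_ids, name="effective_weight"
        ),
        denominator=denom,
    )


def classify_match(ssm: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Match call: SSM ≥ 0 (a zero score counts as a match)."""
    if isinstance(ssm, pd.Series):
        return (ssm >= 0).rename("match")
    return np.asarray(ssm) >= 0
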