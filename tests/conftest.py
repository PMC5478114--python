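import numpy as np
import pandas as pd
import pytest

from sigcore.io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSignature,
    SignatureEntry,
)


def make_expr(rows: dict[str, list[float]], samples: list[str] | None = None,
              cohorts: list[str] | None = None) -> ExpressionMatrix:
    """Small expression matrix from {gene: values}."""
    n = len(next(iter(rows.values())))
    samples = samples or [f"s{i + 1}" for i in range(n)]
    df = pd.DataFrame(rows, index=samples).T
    coh = pd.Series(cohorts, index=samples) if cohorts else None
    return ExpressionMatrix(df.astype(float), coh)


def make_signature(entries: list[tuple], name: str = "sig") -> GeneSignature:
    """Signature from (gene, direction[, pathway]) tuples."""
    return GeneSignature(
        [SignatureEntry(g, d, rest[0] if rest else "") for g, d, *rest in entries],
        name,
    )


def make_clinical(samples, times, events, endpoint="MFS", cohort="c1",
                  her2=None, er=None) -> ClinicalTable:
    n = len(samples)
    return ClinicalTable(pd.DataFrame({
        "sample": samples,
        "cohort": cohort,
        "endpoint": endpoint,
        "time_months": times,
        "event": events,
        "her2_ihc": her2 if her2 is not None else ["unknown"] * n,
        "er_status": er if er is not None else ["unknown"] * n,
    }))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_gene_signature():
    return make_signature([("A", 1), ("B", -1)])
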