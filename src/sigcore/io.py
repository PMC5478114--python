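"""Cohort containers and I/O.

Everything downstream operates on three light containers:

* :class:`ExpressionMatrix` — log2 expression, genes x samples, with a
  cohort label per sample.
* :class:`ClinicalTable` — one row per sample with survival endpoint,
  follow-up time (months), event flag and receptor status.
* :class:`GeneSignature` — an ordered, signed gene list (direction
  ``+1`` for genes expected up in high-risk samples, ``-1`` for down)
  with a pathway annotation per gene.

Tables are plain tab-separated text.  Expression files have a first
column of gene symbols and a header row of sample identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "sample",
    "cohort",
    "endpoint",
    "time_months",
    "event",
    "her2_ihc",
    "er_status",
]


class FormatError(ValueError):
    """A table does not have the expected layout."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples).

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
        Values are log2-scale, finite floats.
    cohorts
        Series mapping sample id -> cohort label, aligned with the
        columns of ``values``.  Defaults to a single cohort ``"cohort"``.
    platform
        Free-text platform tag.
    """

    values: pd.DataFrame
    cohorts: pd.Series | None = None
    platform: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids after loading: {list(dup)[:5]}")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float)).all():
            raise ValueError("expression values must be finite")
        if self.cohorts is None:
            self.cohorts = pd.Series("cohort", index=self.values.columns)
        else:
            self.cohorts = self.cohorts.reindex(self.values.columns)
            if self.cohorts.isna().any():
                missing = self.cohorts.index[self.cohorts.isna()]
                raise ValueError(f"samples without cohort label: {list(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.cohorts[list(samples)], self.platform
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical outcome table.

    ``df`` has columns ``sample, cohort, endpoint, time_months, event,
    her2_ihc, er_status``.  ``event`` is 1 for metastasis (MFS) or death
    (OS), 0 for censoring; ``her2_ihc``/``er_status`` take values
    ``positive``/``negative``/``unknown``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        df = self.df
        if (df["time_months"].astype(float) < 0).any():
            raise ValueError("time_months must be non-negative")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        bad = set(df["endpoint"].unique()) - {"MFS", "OS"}
        if bad:
            raise ValueError(f"unknown endpoint labels: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample"])

    def aligned_to(self, samples: Sequence[str]) -> pd.DataFrame:
        """Rows reindexed to ``samples`` (error on absentees)."""
        sub = self.df.set_index("sample").reindex(list(samples))
        if sub["time_months"].isna().any():
            missing = sub.index[sub["time_months"].isna()]
            raise KeyError(f"samples without clinical rows: {list(missing)[:5]}")
        return sub


@dataclass(frozen=True)
class SignatureEntry:
    gene: str
    direction: int
    pathway: str = ""


@dataclass
class GeneSignature:
    """Ordered signed gene list with pathway annotation."""

    entries: list[SignatureEntry]
    name: str = "signature"

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in signature")
        for e in self.entries:
            if e.direction not in (1, -1):
                raise ValueError(f"direction must be +1/-1, got {e.direction}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    @property
    def directions(self) -> np.ndarray:
        return np.array([e.direction for e in self.entries], dtype=int)

    @property
    def pathways(self) -> list[str]:
        return [e.pathway for e in self.entries]

    @property
    def n_up(self) -> int:
        return int((self.directions == 1).sum())

    @property
    def n_down(self) -> int:
        return int((self.directions == -1).sum())

    def direction_of(self, gene: str) -> int:
        for e in self.entries:
            if e.gene == gene:
                return e.direction
        raise KeyError(gene)

    def subset(self, genes: Iterable[str], name: str | None = None) -> "GeneSignature":
        keep = set(genes)
        entries = [e for e in self.entries if e.gene in keep]
        if not entries:
            raise ValueError("subset removes every gene")
        return GeneSignature(entries, name or f"{self.name}-subset")

    def subset_mask(self, mask: int, name: str | None = None) -> "GeneSignature":
        """Subset by bit-mask over entry positions (bit i = entry i)."""
        entries = [e for i, e in enumerate(self.entries) if (mask >> i) & 1]
        if not entries:
            raise ValueError("empty mask")
        return GeneSignature(entries, name or f"{self.name}-{mask:x}")

    def flipped(self) -> "GeneSignature":
        return GeneSignature(
            [replace(e, direction=-e.direction) for e in self.entries],
            f"{self.name}-flipped",
        )


@dataclass
class NanoCountTable:
    """Raw count table (targets + control genes) x samples."""

    counts: pd.DataFrame
    control_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.control_genes:
            raise ValueError("control_genes must be non-empty")
        missing = set(self.control_genes) - set(self.counts.index)
        if missing:
            raise ValueError(f"control genes absent from table: {missing}")


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples expression TSV.

    First column holds gene symbols, the header row sample ids.
    Duplicate gene rows are collapsed by per-sample maximum (keeps the
    strongest probe signal); the collapsed count is logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty or headerless file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        num[col] = converted
    if num.isna().any().any():
        row = num.index[num.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in row {row!r}")
    n_dup = int(num.index.duplicated().sum())
    if n_dup:
        num = num.groupby(level=0, sort=False).max()
        logger.info("collapsed %d duplicate gene rows in %s", n_dup, path.name)
    return ExpressionMatrix(num)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "cohort": str})
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.df.to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "direction"} <= set(df.columns):
        raise FormatError(f"{path}: signature file needs 'gene' and 'direction' columns")
    entries = [
        SignatureEntry(r.gene, int(r.direction), getattr(r, "pathway", "") or "")
        for r in df.itertuples()
    ]
    return GeneSignature(entries, name or Path(path).stem)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": sig.genes,
            "direction": ["+1" if d > 0 else "-1" for d in sig.directions],
            "pathway": sig.pathways,
        }
    ).to_csv(path, sep="\t", index=False)


def read_nanostring(path: str | Path, control_genes: Sequence[str] | None = None) -> NanoCountTable:
    """Read a NanoString-style count table.

    Layout: first column ``gene``, optional second column ``is_control``
    (0/1), remaining columns per-sample counts.  When ``is_control`` is
    absent, ``control_genes`` must be given.
    """
    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", index_col=0)
    if "is_control" in df.columns:
        controls = list(df.index[df["is_control"].astype(int) == 1])
        df = df.drop(columns="is_control")
    else:
        if control_genes is None:
            raise FormatError("no is_control column and no control_genes given")
        controls = list(control_genes)
    return NanoCountTable(df.astype(float), controls)


# ---------------------------------------------------------------------------
# transforms


def median_center(expr: ExpressionMatrix, per_cohort: bool = False) -> ExpressionMatrix:
    """Subtract each gene's median (optionally within each cohort).

    The output is the centered matrix X_n consumed by SSM scoring: a
    positive entry means the gene is above its (cohort) median in that
    sample.  Even sample counts use the mid-point median, so centering
    is idempotent only for odd counts.
    """
    vals = expr.values
    if per_cohort:
        parts = []
        for _, samples in expr.cohorts.groupby(expr.cohorts):
            block = vals[samples.index]
            parts.append(block.sub(block.median(axis=1), axis=0))
        out = pd.concat(parts, axis=1)[vals.columns]
    else:
        out = vals.sub(vals.median(axis=1), axis=0)
    return ExpressionMatrix(out, expr.cohorts, expr.platform)


def pool_cohorts(
    pairs: Sequence[tuple[ExpressionMatrix, ClinicalTable]]
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Pool cohorts on their common genes.

    Sample ids are made unique with a ``cohort:`` prefix; cohort labels
    are preserved so pooled analyses can still center per cohort.
    """
    if not pairs:
        raise ValueError("nothing to pool")
    genes: pd.Index = pairs[0][0].values.index
    for expr, _ in pairs[1:]:
        genes = genes[genes.isin(expr.values.index)]
    if len(genes) == 0:
        raise ValueError("empty gene intersection across cohorts")
    blocks, cohort_labels, clin_rows = [], [], []
    for i, (expr, clin) in enumerate(pairs):
        labels = expr.cohorts.astype(str)
        prefix = labels + ":"
        # disambiguate if the same cohort label appears in several inputs
        prefix = prefix.radd(f"p{i}|") if len(pairs) > 1 else prefix
        block = expr.values.loc[genes].copy()
        block.columns = [prefix[s] + s for s in block.columns]
        blocks.append(block)
        cohort_labels.append(
            pd.Series((f"p{i}|" if len(pairs) > 1 else "") + labels.values, index=block.columns)
        )
        cdf = clin.df.copy()
        cdf["cohort"] = (f"p{i}|" if len(pairs) > 1 else "") + cdf["cohort"].astype(str)
        cdf["sample"] = cdf["cohort"] + ":" + cdf["sample"].astype(str)
        clin_rows.append(cdf)
    pooled = ExpressionMatrix(pd.concat(blocks, axis=1), pd.concat(cohort_labels))
    return pooled, ClinicalTable(pd.concat(clin_rows, ignore_index=True))


def nanostring_normalize(tbl: NanoCountTable) -> ExpressionMatrix:
    """Control-gene normalisation of raw counts, then log2(count + 1).

    Each sample is rescaled so that the geometric mean of its control
    genes equals the across-sample arithmetic mean of those geometric
    means (the usual housekeeping normalisation for count panels).
    """
    ctrl = tbl.counts.loc[tbl.control_genes]
    if (ctrl <= 0).any().any():
        bad = ctrl.columns[(ctrl <= 0).any(axis=0)][0]
        raise ValueError(f"zero/negative control count in sample {bad!r}")
    geo = np.exp(np.log(ctrl).mean(axis=0))
    target = geo.mean()
    scale = target / geo
    scaled = tbl.counts.mul(scale, axis=1)
    return ExpressionMatrix(np.log2(scaled + 1.0), platform="nanostring")


def map_gene_ids(
    signature: GeneSignature, expr: ExpressionMatrix
) -> tuple[GeneSignature, dict]:
    """Case-insensitively match signature genes to matrix rows.

    Matched entries are renamed to the matrix's spelling; unmatched
    genes are dropped and listed in the report.  No ortholog lookup is
    attempted — mouse/human bridging relies on shared symbols.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    lookup: dict[str, str] = {}
    for g in expr.gene_ids:
        lookup.setdefault(g.casefold(), g)
    matched, unmatched = [], []
    for e in signature.entries:
        hit = lookup.get(e.gene.casefold())
        if hit is None:
            unmatched.append(e.gene)
        else:
            matched.append(SignatureEntry(hit, e.direction, e.pathway))
    if not matched:
        raise ValueError("no signature gene matches the expression matrix")
    report = {
        "n_matched": len(matched),
        "n_unmatched": len(unmatched),
        "unmatched": unmatched,
        "renamed": {
            a.gene: b.gene
            for a, b in zip([e for e in signature.entries if e.gene not in unmatched], matched)
            if a.gene != b.gene
        },
    }
    if unmatched:
        logger.info("map_gene_ids: dropped %d unmatched genes: %s", len(unmatched), unmatched)
    return GeneSignature(matched, signature.name), report
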