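"""Synthetic cohorts with the structure the analysis assumes.

The generator plants everything the pipeline is meant to detect:

* **Pathway-blocked expression** — log2 values are N(7, 1) per gene;
  genes sharing a pathway block load on a common latent factor so any
  within-block pair correlates at ``block_rho`` (equicorrelated,
  marginal variance exactly 1).  Each block also carries a configurable
  number of non-signature member genes, which is what gives the
  substitute-gene search same-pathway candidates to find.
* **Signature-driven survival** — a risk score z (mean of
  I_n x standardized expression over the *informative* signature
  genes) drives an exponential proportional-hazards event time with
  hazard ``baseline_hazard * exp(beta * z)`` and uniform censoring on
  (0, censor_max_months].
* **A HER2 amplicon subpopulation** — a fraction of samples get a
  +log2(U(fold range)) shift on the five amplicon genes; the recorded
  IHC label is the true amplification status flipped with a given
  error rate.  Amplicon genes carry reduced residual noise
  (``amplicon_sd``), reflecting copy-number-dominated expression, so
  strong planted gains are cleanly separable.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSignature,
    write_clinical,
    write_expression,
    write_signature,
)
from .resources import load_amplicon_genes, load_htics

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    n_samples: int = 300
    n_genes: int = 2000
    signature: GeneSignature | None = None  # defaults to the 17-gene HTICS
    informative_genes: list[str] | None = None  # defaults to all signature genes
    block_rho: float = 0.5
    beta: float = 1.0
    baseline_hazard: float = 0.01  # events per month at z = 0
    censor_max_months: float = 120.0
    frac_her2: float = 0.25
    amplicon_fold_range: tuple[float, float] = (4.0, 8.0)
    amplicon_sd: float = 0.25
    ihc_error_rate: float = 0.0
    extra_per_block: int = 10
    endpoint: str = "MFS"
    cohort: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signature is None:
            self.signature = load_htics()
        if self.informative_genes is None:
            self.informative_genes = list(self.signature.genes)
        extra = set(self.informative_genes) - set(self.signature.genes)
        if extra:
            raise ValueError(f"informative genes not in signature: {sorted(extra)}")
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must be in [0, 1)")
        if not (0 <= self.frac_her2 <= 1):
            raise ValueError("frac_her2 must be in [0, 1]")
        if min(self.amplicon_fold_range) <= 1:
            raise ValueError("amplicon folds must be > 1")
        if min(self.baseline_hazard, self.censor_max_months, self.ihc_error_rate) < 0:
            raise ValueError("rates must be non-negative")


def _gene_layout(cfg: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    """Full gene list plus gene -> pathway-block membership."""
    sig = cfg.signature
    amplicon = load_amplicon_genes()
    block_of: dict[str, str] = {
        g: p for g, p in zip(sig.genes, sig.pathways) if p
    }
    genes = list(sig.genes) + [g for g in amplicon if g not in sig.genes]
    for pathway in dict.fromkeys(p for p in sig.pathways if p):
        slug = pathway.replace(" ", "")
        for i in range(cfg.extra_per_block):
            name = f"{slug}.X{i + 1}"
            genes.append(name)
            block_of[name] = pathway
    n_noise = cfg.n_genes - len(genes)
    genes += [f"NOISE{i + 1}" for i in range(max(n_noise, 0))]
    return genes, block_of


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """One cohort: expression, clinical outcomes and a truth record.

    The truth record carries the risk score ``z``, the true
    amplification status, the planted match split (SSM of the planted
    signature on the median-centered matrix) and the implied hazard
    ratio between the planted match groups, so parameter-recovery
    tests need no re-derivation.
    """
    rng = np.random.default_rng(cfg.seed)
    sig = cfg.signature
    genes, block_of = _gene_layout(cfg)
    samples = [f"{cfg.cohort}{i + 1:04d}" for i in range(cfg.n_samples)]
    n, p = cfg.n_samples, len(genes)

    blocks = list(dict.fromkeys(block_of.values()))
    factors = {b: rng.standard_normal(n) for b in blocks}
    eps = rng.standard_normal((p, n))
    amplicon = set(load_amplicon_genes())
    x = np.empty((p, n))
    sq_r, sq_1r = np.sqrt(cfg.block_rho), np.sqrt(1.0 - cfg.block_rho)
    for i, g in enumerate(genes):
        if g in amplicon:
            x[i] = 7.0 + cfg.amplicon_sd * eps[i]
        elif g in block_of:
            x[i] = 7.0 + sq_r * factors[block_of[g]] + sq_1r * eps[i]
        else:
            x[i] = 7.0 + eps[i]

    gidx = {g: i for i, g in enumerate(genes)}
    inf = cfg.informative_genes
    dirs = np.array([sig.direction_of(g) for g in inf], dtype=float)
    z = (dirs[:, None] * (x[[gidx[g] for g in inf]] - 7.0)).mean(axis=0)

    hazard = cfg.baseline_hazard * np.exp(np.clip(cfg.beta * z, -50.0, 50.0))
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, cfg.censor_max_months, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    her2_true = rng.random(n) < cfg.frac_her2
    lo, hi = cfg.amplicon_fold_range
    amp_rows = [gidx[g] for g in load_amplicon_genes()]
    gains = np.log2(rng.uniform(lo, hi, size=(len(amp_rows), n)))
    for r, row in enumerate(amp_rows):
        x[row] = x[row] + np.where(her2_true, gains[r], 0.0)
    flip = rng.random(n) < cfg.ihc_error_rate
    her2_label = her2_true ^ flip

    expr = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=samples),
        pd.Series(cfg.cohort, index=samples),
        platform="synthetic",
    )
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "sample": samples,
                "cohort": cfg.cohort,
                "endpoint": cfg.endpoint,
                "time_months": time,
                "event": event,
                "her2_ihc": np.where(her2_label, "positive", "negative"),
                "er_status": "negative",
            }
        )
    )

    from .io import median_center
    from .ssm import ssm_scores

    # the planted risk group is the match split of the *informative*
    # sub-signature (identical to the full signature when all genes
    # carry signal)
    planted_sig = sig if set(inf) == set(sig.genes) else sig.subset(inf, name="planted")
    match = ssm_scores(median_center(expr), planted_sig).match
    zs = pd.Series(z, index=samples)
    if match.any() and (~match).any():
        group_hr = float(np.exp(cfg.beta * (zs[match].mean() - zs[~match].mean())))
    else:
        group_hr = np.nan
    truth = {
        "z": zs,
        "her2_true": pd.Series(her2_true, index=samples),
        "match": match,
        "group_hr": group_hr,
        "beta": cfg.beta,
        "informative_genes": list(inf),
        "block_of": block_of,
        "event_fraction": float(event.mean()),
    }
    return expr, clin, truth


def calibrate_beta(
    cfg: SyntheticConfig,
    target_group_hr: float,
    n_calib: int = 6000,
    tol: float = 0.02,
    max_iter: int = 12,
    estimator: str = "cox",
) -> float:
    """Hazard coefficient giving a desired match/no-match group HR.

    The group-level hazard ratio implied by a continuous planted risk
    score has no closed form (the match split and within-group score
    spread both matter), so the mapping beta -> group HR is measured on
    a single large simulated cohort (O/E estimator) and inverted by
    bisection; the calibration draw uses a seed derived from the config
    seed and is deterministic.  ``estimator`` picks which estimand
    defines the "true" group HR (Cox by default, so the target is the
    large-sample Cox value; "oe" is faster for permutation-scale use).
    """
    from .survival import cox_hr, oe_hr

    def group_hr(beta: float) -> float:
        trial = SyntheticConfig(
            n_samples=n_calib,
            n_genes=len(_gene_layout(cfg)[0]),
            signature=cfg.signature,
            informative_genes=cfg.informative_genes,
            block_rho=cfg.block_rho,
            beta=beta,
            baseline_hazard=cfg.baseline_hazard,
            censor_max_months=cfg.censor_max_months,
            frac_her2=0.0,
            extra_per_block=cfg.extra_per_block,
            seed=(cfg.seed * 1_000_003 + 17) % (2**31 - 1),
        )
        expr, clin, truth = generate_cohort(trial)
        g = truth["match"].to_numpy()
        t = clin.df["time_months"].to_numpy()
        e = clin.df["event"].to_numpy()
        return cox_hr(t, e, g).hr if estimator == "cox" else oe_hr(t, e, g)

    target = np.log(target_group_hr)
    # group HR is monotone in beta but saturates (the match split is a
    # noisy readout of z), so bracket on a geometric grid then bisect
    lo, f_lo = 0.0, -target
    hi = max(target, 0.5)
    f_hi = np.log(group_hr(hi)) - target
    n_expand = 0
    while f_hi < 0 and n_expand < 8:
        lo, f_lo = hi, f_hi
        hi *= 2.0
        f_hi = np.log(group_hr(hi)) - target
        n_expand += 1
    if f_hi < 0:
        logger.warning(
            "calibrate_beta: target group HR %.2f unreachable; returning beta=%.2f "
            "(group HR %.2f)",
            target_group_hr,
            hi,
            np.exp(f_hi + target),
        )
        return float(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = np.log(group_hr(mid)) - target
        if abs(f_mid) < tol:
            lo = hi = mid
            break
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    beta = 0.5 * (lo + hi)
    logger.info("calibrate_beta: beta=%.4f for target group HR %.3f", beta, target_group_hr)
    return float(beta)


def write_fixture_suite(
    out_dir: str | Path, seed: int = 0, cfg: SyntheticConfig | None = None
) -> dict[str, Path]:
    """Emit a paired MFS/OS cohort plus signature/pathway/candidate files.

    The file set is sufficient to run every pipeline stage end-to-end
    and is byte-identical for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = cfg or SyntheticConfig()
    files: dict[str, Path] = {}
    for endpoint, offset in (("MFS", 0), ("OS", 1)):
        c = SyntheticConfig(
            n_samples=base.n_samples,
            n_genes=base.n_genes,
            signature=base.signature,
            informative_genes=base.informative_genes,
            block_rho=base.block_rho,
            beta=base.beta,
            baseline_hazard=base.baseline_hazard,
            censor_max_months=base.censor_max_months,
            frac_her2=base.frac_her2,
            amplicon_fold_range=base.amplicon_fold_range,
            amplicon_sd=base.amplicon_sd,
            ihc_error_rate=base.ihc_error_rate,
            extra_per_block=base.extra_per_block,
            endpoint=endpoint,
            cohort=f"SIM{endpoint}",
            seed=(seed * 2 + offset) % (2**31 - 1),
        )
        expr, clin, truth = generate_cohort(c)
        files[f"expr_{endpoint.lower()}"] = out / f"expression_{endpoint.lower()}.tsv"
        files[f"clinical_{endpoint.lower()}"] = out / f"clinical_{endpoint.lower()}.tsv"
        write_expression(expr, files[f"expr_{endpoint.lower()}"])
        write_clinical(clin, files[f"clinical_{endpoint.lower()}"])
        if endpoint == "MFS":
            block_of = truth["block_of"]
            sig = c.signature
            candidates = [g for g in block_of if g not in set(sig.genes)]
            files["candidates"] = out / "candidates.tsv"
            pd.DataFrame({"gene": candidates}).to_csv(files["candidates"], sep="\t", index=False)
            files["pathways"] = out / "pathways.tsv"
            pd.DataFrame(
                {"gene": list(block_of), "pathway": list(block_of.values())}
            ).to_csv(files["pathways"], sep="\t", index=False)
    files["signature"] = out / "signature.tsv"
    write_signature(base.signature, files["signature"])
    from .resources import load_core

    files["core_signature"] = out / "core_signature.tsv"
    write_signature(load_core(), files["core_signature"])
    files["amplicon"] = out / "amplicon_genes.tsv"
    pd.DataFrame({"gene": load_amplicon_genes()}).to_csv(files["amplicon"], sep="\t", index=False)
    return files
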