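"""End-to-end analysis runner with a reproducibility manifest.

``run_full_analysis`` wires the stages together on one MFS cohort and
one OS cohort: subtype filter → SSM scoring → survival + ROC →
leave-one-pathway-out table → exhaustive combination sweep →
Core1/Core2/Core extraction → substitute discovery → substituted
signature evaluation → composition-matched null ranking + eFDR.  The
output is a single JSON report plus per-stage TSVs and a manifest with
input checksums, seeds and timings; identical inputs and seed give
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combos import (
    evaluate_all,
    extract_cores,
    leave_one_pathway_out,
    pathway_coverage,
    records_to_tsv,
)
from .io import median_center, read_clinical, read_expression, read_signature
from .nulls import empirical_fdr, rank_against_null
from .roc import auc_rank, encode_outcome, outcome_truth
from .ssm import ssm_scores
from .substitution import apply_substitution, find_substitutes, score_agreement
from .survival import SubtypeFilter, evaluate_signature


@dataclass
class RunManifest:
    command: str
    config: dict
    config_hash: str
    input_checksums: dict
    seed: int
    version: str
    timings_s: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stage_status: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _survival_block(res) -> dict:
    if not res.evaluable:
        return {"evaluable": False, "reason": res.reason}
    return {
        "evaluable": True,
        "n_match": res.n_match,
        "n_nomatch": res.n_nomatch,
        "hr": res.hr,
        "hr_ci": list(res.hr_ci),
        "cox_p": res.cox_p,
        "wilcoxon_p": res.wilcoxon_p,
        "oe_hr": res.oe_hr,
    }


def run_full_analysis(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run every stage on the cohorts named in ``config``.

    Config keys: ``expr_mfs, clinical_mfs, expr_os, clinical_os,
    signature`` (file paths), optional ``candidates, pathways`` (for
    substitution), ``seed``, ``alpha``, ``n_null``, ``n_perm``,
    ``subtype`` ({require_her2, require_er_negative, her2_source}).
    Stage failures are recorded in the manifest and downstream stages
    that depend on them are skipped with a reason.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    paths = {
        k: Path(config[k])
        for k in ("expr_mfs", "clinical_mfs", "expr_os", "clinical_os", "signature")
    }
    for k, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"config entry {k!r}: no such file {p}")
    for k in ("candidates", "pathways"):
        if k in config:
            paths[k] = Path(config[k])
    manifest = RunManifest(
        command="run-all",
        config={k: str(v) for k, v in config.items()},
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        input_checksums={k: _sha256(p) for k, p in paths.items()},
        seed=seed,
        version=__version__,
    )
    report: dict = {"seed": seed}
    t0 = time.perf_counter()

    expr_mfs = read_expression(paths["expr_mfs"])
    clin_mfs = read_clinical(paths["clinical_mfs"])
    expr_os = read_expression(paths["expr_os"])
    clin_os = read_clinical(paths["clinical_os"])
    signature = read_signature(paths["signature"])
    subtype = SubtypeFilter(**config["subtype"]) if "subtype" in config else None
    manifest.timings_s["load"] = time.perf_counter() - t0

    def stage(name):
        def wrap(fn):
            t = time.perf_counter()
            try:
                fn()
                manifest.stage_status[name] = "ok"
            except Exception as exc:  # recorded, downstream skipped
                manifest.stage_status[name] = f"failed: {exc}"
                report[name] = {"error": str(exc)}
            manifest.timings_s[name] = round(time.perf_counter() - t, 3)

        return wrap

    @stage("ssm")
    def _ssm():
        res = ssm_scores(median_center(expr_mfs, per_cohort=True), signature)
        tbl = pd.DataFrame({"sample": res.sample_ids, "ssm": res.ssm, "match": res.match})
        tbl.to_csv(out / "ssm_mfs.tsv", sep="\t", index=False)
        report["ssm"] = {
            "n_samples": len(res.sample_ids),
            "n_match": int(res.match.sum()),
            "mean_ssm": float(res.ssm.mean()),
        }

    @stage("survival")
    def _survival():
        blocks = {}
        for label, (e, c) in {
            "MFS": (expr_mfs, clin_mfs),
            "OS": (expr_os, clin_os),
        }.items():
            res = evaluate_signature(e, c, signature, subtype=subtype, endpoint=label)
            blocks[label] = _survival_block(res)
            if res.evaluable:
                pd.concat(
                    [df.assign(group=g) for g, df in res.km_curves.items()]
                ).to_csv(out / f"km_{label.lower()}.tsv", sep="\t", index=False)
        report["survival"] = blocks

    @stage("roc")
    def _roc():
        res = evaluate_signature(expr_mfs, clin_mfs, signature, subtype=subtype, endpoint="MFS")
        if not res.evaluable:
            raise RuntimeError(f"survival stage non-evaluable: {res.reason}")
        clin = clin_mfs.df.set_index("sample").loc[res.ssm.index]
        cats = encode_outcome(clin["time_months"], clin["event"])
        roc = auc_rank(res.ssm.to_numpy(), outcome_truth(cats))
        roc.curve_points.to_csv(out / "roc_mfs.tsv", sep="\t", index=False)
        report["roc"] = {"auc_mfs": roc.auc, "horizon_months": 36.0}

    @stage("leave_one_pathway_out")
    def _loo():
        rows = []
        for pathway in dict.fromkeys(p for p in signature.pathways if p):
            reduced = leave_one_pathway_out(signature, pathway)
            res = evaluate_signature(
                expr_mfs, clin_mfs, reduced, subtype=subtype, endpoint="MFS"
            )
            rows.append(
                {
                    "pathway_removed": pathway,
                    "n_genes": len(reduced),
                    "hr_mfs": res.hr if res.evaluable else np.nan,
                    "cox_p": res.cox_p if res.evaluable else np.nan,
                }
            )
        loo = pd.DataFrame(rows)
        loo.to_csv(out / "leave_one_pathway_out.tsv", sep="\t", index=False)
        report["leave_one_pathway_out"] = loo.to_dict("records")

    records = {}

    @stage("combinations")
    def _combos():
        rec = evaluate_all(
            expr_mfs, clin_mfs, expr_os, clin_os, signature, alpha=alpha, hr_estimator="oe"
        )
        records["records"] = rec
        records_to_tsv(rec[rec["significant"]], out / "significant_combinations.tsv")
        report["combinations"] = {
            "n_total": len(rec),
            "n_significant": int(rec["significant"].sum()),
            "mean_significant_size": float(rec.loc[rec["significant"], "size"].mean())
            if rec["significant"].any()
            else np.nan,
        }

    @stage("cores")
    def _cores():
        if "records" not in records:
            raise RuntimeError("combination sweep unavailable")
        rec = records["records"]
        cores = extract_cores(rec)
        _, summary = pathway_coverage(rec[rec["significant"]], signature)
        report["cores"] = {
            "core1": cores.core1,
            "core2": cores.core2,
            "core": cores.core,
            "pairwise_mean_pct": cores.stats1.mean_overlap,
            "pairwise_sd_pct": cores.stats1.sd_overlap,
            "pairwise_threshold_pct": cores.stats1.threshold,
            "pathway_fractions": summary.set_index("pathway")[
                "fraction_of_records"
            ].to_dict(),
        }
        with open(out / "cores.json", "w") as fh:
            json.dump(report["cores"], fh, indent=2)

    submaps = {}

    @stage("substitution")
    def _subst():
        if "candidates" not in paths:
            raise RuntimeError("no candidate gene list configured")
        cand = list(pd.read_csv(paths["candidates"], sep="\t")["gene"])
        pw = {}
        if "pathways" in paths:
            pdf = pd.read_csv(paths["pathways"], sep="\t")
            pw = dict(zip(pdf["gene"], pdf["pathway"]))
        smap = find_substitutes(expr_mfs, signature, cand, pw)
        submaps["map"] = smap
        smap.table.to_csv(out / "substitutes.tsv", sep="\t", index=False)
        report["substitution"] = {
            "n_mapped": len(smap.table),
            "same_pathway_fraction": float(smap.table["same_pathway"].mean()),
            "mean_r": float(smap.table["r"].mean()),
        }

    @stage("substituted_signatures")
    def _alt():
        if "map" not in submaps:
            raise RuntimeError("substitution map unavailable")
        alt = apply_substitution(signature, submaps["map"], "all", name="alt")
        centered = median_center(expr_mfs, per_cohort=True)
        r, auc = score_agreement(centered, signature, alt)
        res = evaluate_signature(expr_mfs, clin_mfs, alt, subtype=subtype, endpoint="MFS")
        report["substituted_signatures"] = {
            "alt_vs_original_r": r,
            "alt_vs_original_auc": auc,
            "alt_mfs": _survival_block(res),
        }

    @stage("null_models")
    def _nulls():
        n_null = int(config.get("n_null", 1000))
        n_perm = int(config.get("n_perm", 1000))
        nd = empirical_fdr(
            expr_mfs, clin_mfs, signature, n_perm=n_perm, seed=seed, hr_estimator="oe"
        )
        ranked = rank_against_null(nd.target_hr, nd.null_hrs[:n_null])
        pd.DataFrame({"null_hr": nd.null_hrs}).to_csv(
            out / "null_hrs.tsv", sep="\t", index=False
        )
        report["null_models"] = {
            "target_oe_hr": nd.target_hr,
            "rank_among_nulls": ranked.rank,
            "n_perm": nd.n_draws,
            "n_better": nd.n_better,
            "efdr": nd.efdr,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    manifest.outputs = sorted(p.name for p in out.iterdir())
    with open(out / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
    return report
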