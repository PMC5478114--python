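"""Run every stage end-to-end from files, with a reproducibility manifest.

Writes a synthetic fixture suite (paired MFS/OS cohorts plus signature,
candidate and pathway files), then runs the full pipeline: SSM ->
survival + ROC -> leave-one-pathway-out -> combination sweep -> cores
-> substitutes -> alternative-signature evaluation -> null models.
"""

import json
import tempfile
from pathlib import Path

import sigcore as sc

work = Path(tempfile.mkdtemp(prefix="sigcore-demo-"))
files = sc.write_fixture_suite(work / "fixtures", seed=7,
                               cfg=sc.SyntheticConfig(n_samples=200, beta=2.5))

config = {
    "expr_mfs": str(files["expr_mfs"]),
    "clinical_mfs": str(files["clinical_mfs"]),
    "expr_os": str(files["expr_os"]),
    "clinical_os": str(files["clinical_os"]),
    "signature": str(files["signature"]),
    "candidates": str(files["candidates"]),
    "pathways": str(files["pathways"]),
    "seed": 7,
    "n_perm": 500,
}
report = sc.run_full_analysis(config, work / "out")

print("stages:", ", ".join(k for k in report if k != "seed"))
print("MFS hazard ratio:", round(report["survival"]["MFS"]["hr"], 2))
print("significant subsets:", report["combinations"]["n_significant"])
print("core genes:", report["cores"]["core"])
print("eFDR:", report["null_models"]["efdr"])
print("full report:", work / "out" / "report.json")
print(json.dumps(report["leave_one_pathway_out"], indent=2))

# The manifest (out/manifest.json) records input checksums, the seed
# and per-stage timings; identical inputs reproduce the report byte
# for byte.
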