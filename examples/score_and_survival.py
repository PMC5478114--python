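"""Score a cohort with the 17-gene HTICS signature and compare survival.

Builds a synthetic cohort with a planted signature-driven hazard,
computes per-sample SSM scores, and contrasts the match vs no-match
groups by Kaplan-Meier, the Gehan-Breslow-Wilcoxon test and a Cox
hazard ratio.
"""

import sigcore as sc

cfg = sc.SyntheticConfig(n_samples=300, beta=3.0, seed=1)
expr, clinical, truth = sc.generate_cohort(cfg)

res = sc.evaluate_signature(expr, clinical, cfg.signature, endpoint="MFS")

print(f"samples: {res.n_match} match / {res.n_nomatch} no-match")
print(f"Cox HR (match vs no-match): {res.hr:.2f}  95% CI {res.hr_ci[0]:.2f}-{res.hr_ci[1]:.2f}")
print(f"Cox p = {res.cox_p:.2e}; Wilcoxon p = {res.wilcoxon_p:.2e}")
print(f"O/E hazard ratio (fast estimator): {res.oe_hr:.2f}")

# An HR well above 1 means SSM-match patients progress faster: the
# signature separates the planted high-risk group from the rest.
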