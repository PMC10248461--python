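"""Step 2: verify a TMB cutoff on overall survival.

Fits Cox proportional-hazards models (adjusted for age, sex, panel
version and cancer type) for TMB-high vs TMB-low under the universal
10 mut/Mb cutoff and under per-cancer 80th-percentile cutoffs, scans the
Wald Z statistic over cutoffs, and compares discrimination.
"""

import numpy as np

from tmbcut import CutoffPolicy, SimConfig, compare_cindex, fit_cox, z_scan
from tmbcut.synthetic_data import simulate_cohort, simulate_survival

cfg = SimConfig()  # plants HR 0.58 for TMB >= 10 mut/Mb
clinical, tmb, _ = simulate_cohort(cfg, seed=3, n_types=8, per_type=250)
surv = simulate_survival(clinical, tmb, cfg, seed=3)

universal = CutoffPolicy("universal", 10.0)
percentile = CutoffPolicy("percentile", 0.80)

res_u = fit_cox(surv, universal)
res_p = fit_cox(surv, percentile)
print(f"universal 10 mut/Mb : HR {res_u.hr:.2f} "
      f"[{res_u.ci_low:.2f}, {res_u.ci_high:.2f}], C-index {res_u.c_index:.3f}")
print(f"80th percentile     : HR {res_p.hr:.2f} "
      f"[{res_p.ci_low:.2f}, {res_p.ci_high:.2f}], C-index {res_p.c_index:.3f}")

curve, bp = z_scan(surv, np.arange(1.0, 16.0))
print(f"\nWald-Z scan breakpoint: {bp.breakpoint:g} mut/Mb "
      f"(|Z| peaks where the planted effect threshold sits)")

cmp_res = compare_cindex(surv, universal, percentile, n_boot=200, seed=0)
print(f"C-index difference: {cmp_res.delta:+.4f} (bootstrap p = {cmp_res.p:.2f})")
print(
    "\nAn HR below 1 means TMB-high patients on immunotherapy live longer;"
    "\nthe two cutoff policies discriminate similarly, but the universal"
    "\ncutoff labels a different share of each cancer type TMB-high."
)
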