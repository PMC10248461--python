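"""Step 1: scan universal TMB cutoffs against response rates.

For each candidate cutoff, each cancer type's TMB-high fraction is
correlated (weighted least squares) with its objective response rate to
anti-PD-(L)1 monotherapy; the Chow test then finds the structural knee
of the R-vs-cutoff curve — the optimal universal cutoff.
"""

import numpy as np

from tmbcut import SimConfig, TrialSummary, chow_breakpoint, scan
from tmbcut.synthetic_data import simulate_cohort, simulate_orr

cfg = SimConfig()  # plants the true cutoff at 10 mut/Mb
clinical, tmb, truth = simulate_cohort(cfg, seed=7)
trials_df = simulate_orr(clinical, tmb, cfg, seed=7)

trials = [
    TrialSummary(r.cancer_type, int(r.n_trial), float(r.orr))
    for r in trials_df.itertuples()
]
merged = clinical[["sample_id", "cancer_type"]].merge(tmb, on="sample_id")
tmb_by_type = {
    ct: sub["tmb"].to_numpy() for ct, sub in merged.groupby("cancer_type")
}

curve = scan(tmb_by_type, trials)
bp = chow_breakpoint(curve.cutoffs, curve.statistic)

print("cutoff  R_TMB-ORR")
for c, r in zip(curve.cutoffs, curve.statistic):
    bar = "#" * int(max(r, 0) * 40)
    print(f"{c:5.0f}   {r:+.3f}  {bar}")
print(f"\nChow breakpoint: {bp.breakpoint:g} mut/Mb (p = {bp.p_value:.2e})")
print(f"planted truth:   {truth.true_cutoff:g} mut/Mb")
print(
    "\nThe correlation climbs while the cutoff sweeps through the bulk of"
    "\nthe TMB distributions and plateaus once only hypermutated tumors"
    "\nremain above it; the knee of that curve is the inferred cutoff."
)
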