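# tmbcut

Inference and validation of a **universal tumor-mutational-burden (TMB)
cutoff** for predicting benefit from anti-PD-(L)1 immunotherapy, with an
in-silico assessment of how well alternative gene panels reproduce the
resulting TMB-high classification.

TMB — somatic mutations per megabase of sequenced territory — is a
pan-cancer biomarker of response to immune-checkpoint blockade, but every
panel vendor and study draws the TMB-high line differently. `tmbcut`
implements a three-step procedure for choosing and defending one line:

1. **Cutoff scan (cancer-type level).** For a candidate cutoff *c*, compute
   each cancer type's TMB-high fraction `p_high(c)` and regress the pooled
   objective response rate (ORR) on it by weighted least squares, with
   weights `sqrt(n_cohort · n_trial)` (the geometric mean of the TMB-cohort
   and trial sample sizes). The association strength is
   `R = sign(slope) · sqrt(R²)`. Sweeping *c* over a grid gives a curve
   R(*c*); the **Chow test** — an F-test comparing one pooled regression
   line against two segment-wise lines at each candidate split —
   locates its structural knee, taken as the optimal universal cutoff.
2. **Survival verification (patient level).** Cox proportional-hazards
   models adjusted for age, sex, panel version and cancer type estimate the
   hazard ratio (HR) of TMB-high vs TMB-low overall survival; the Wald
   Z = β/SE is scanned over cutoffs and the Chow test applied again. The
   universal cutoff is compared against per-cancer 80th-percentile cutoffs
   via HRs, Harrell's C-index (paired bootstrap), a TMB-by-cancer-type
   interaction test and a microsatellite-stable-only sensitivity analysis.
3. **Panel concordance (in silico).** Random gene panels over a
   (size × shared-gene-fraction) grid are drawn from a gene universe; each
   panel's TMB uses its own summed gene territory, and agreement of
   TMB-high calls with the reference panel is scored by **Cohen's κ**
   (κ > 0.80 = almost perfect). A paired t-test quantifies the
   whole-exome-vs-panel TMB offset that motivates a lower WES cutoff.

A synthetic-data module generates cohorts with planted ground truth (a true
cutoff, a true hazard ratio, panel-gene mutation-rate enrichment), so the
whole pipeline is testable without any external download. Users with real
data supply MAF-dialect mutation tables, clinical/survival TSVs, trial
summary TSVs and plain-text panel gene lists; the file formats are
documented in the module docstrings and exercised by the bundled examples.

## Worked example

```python
import numpy as np
from tmbcut import SimConfig, TrialSummary, scan, chow_breakpoint
from tmbcut.synthetic_data import simulate_cohort, simulate_orr

cfg = SimConfig()                       # plants a true cutoff of 10 mut/Mb
clinical, tmb, truth = simulate_cohort(cfg, seed=7)
trials_df = simulate_orr(clinical, tmb, cfg, seed=7)

trials = [TrialSummary(r.cancer_type, int(r.n_trial), float(r.orr))
          for r in trials_df.itertuples()]
merged = clinical[["sample_id", "cancer_type"]].merge(tmb, on="sample_id")
tmb_by_type = {ct: s["tmb"].to_numpy()
               for ct, s in merged.groupby("cancer_type")}

curve = scan(tmb_by_type, trials)
bp = chow_breakpoint(curve.cutoffs, curve.statistic)
print(bp.breakpoint)                    # 10.0
print(round(curve.statistic.max(), 3))  # 0.833 — peak weighted R
```

The scan output for this seed rises from R ≈ 0.3 at low cutoffs to a
plateau of ≈ 0.8 around 10 mut/Mb, and the Chow breakpoint lands on the
planted cutoff: raising the cutoff stops improving the ORR association
exactly where the hypermutated subpopulation begins. The `examples/`
directory has one narrative script per capability (`01_simulate_bundle`,
`02_cutoff_scan`, `03_survival_verification`, `04_panel_concordance`);
each prints the numbers it computes and a line on what they mean.

A thin CLI wraps the same pipeline:

```bash
tmbcut simulate --seed 1 --outdir bundle/
tmbcut run-all --clinical bundle/clinical.tsv --tmb bundle/tmb.tsv \
    --trials bundle/trials.tsv --survival bundle/survival.tsv \
    --maf bundle/maf.tsv --universe bundle/universe.tsv \
    --reference-panel bundle/panel_reference.txt --outdir out/
```

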