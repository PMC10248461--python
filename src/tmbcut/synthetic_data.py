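"""Synthetic oncology cohorts with planted ground truth.

Every analysis stage in this package — the cancer-type-level ORR scan, the
patient-level survival verification and the in-silico panel resampling —
can be exercised without any external download by generating data whose
statistical structure matches the assumptions of the analysis:

* per-cancer-type TMB distributions made of a sub-threshold bulk
  (truncated lognormal) and a hypermutated component supported above a
  planted *true cutoff*, so that the cutoff is a real boundary of
  clinico-biological impact and therefore recoverable;
* objective response rates linearly linked to each type's TMB-high
  fraction at that cutoff;
* exponential overall-survival times whose hazard is multiplied by a
  planted hazard ratio for TMB-high patients;
* gene-resolved exomes with Poisson per-gene mutation counts in which
  panel genes carry enriched mutation rates.

All generators are pure functions of (config, seed).  The planted truth
is emitted alongside each dataset as a :class:`SimTruth`; analysis
modules never consume it — it exists only so tests can check recovery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel_concordance import GeneUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimExome",
    "simulate_cohort",
    "simulate_orr",
    "simulate_survival",
    "simulate_exome",
    "simulate_bundle",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    TMB model (per cancer type t): a fraction ``f_t`` of samples is
    hypermutated with TMB = true_cutoff + Exp(hyper_tail_scale); the rest
    carry bulk TMB from LogNormal(mu_t, bulk_sigma) truncated below the
    true cutoff, with median exp(mu_t) drawn per type from
    ``bulk_median_range``.  ``f_t`` is drawn from ``hyper_frac_range``.
    ORR per type is ``orr_intercept + orr_slope * p_high + noise`` clamped
    to [0, 1], where p_high is the type's TMB-high fraction at the true
    cutoff.  Survival is exponential with the hazard multiplied by
    ``hr_true`` for TMB >= true_cutoff.
    """

    # cohort structure
    n_cancer_types: int = 25
    samples_per_type: int = 500
    # TMB mixture
    true_cutoff: float = 10.0
    bulk_median_range: tuple[float, float] = (4.0, 9.5)
    bulk_sigma: float = 0.40
    hyper_frac_range: tuple[float, float] = (0.05, 0.30)
    hyper_tail_scale: float = 4.0  # mut/Mb above the cutoff
    # MSI labelling
    msi_h_prob_hyper: float = 0.35
    msi_h_prob_bulk: float = 0.01
    # demographics
    age_mean: float = 62.0
    age_sd: float = 12.0
    age_missing_frac: float = 0.02
    male_frac: float = 0.55
    panel_versions: tuple[str, ...] = ("v1", "v2", "v3")
    panel_version_probs: tuple[float, ...] = (0.2, 0.3, 0.5)
    # ORR link (Step 1)
    orr_intercept: float = 0.05
    orr_slope: float = 0.5
    orr_noise_sd: float = 0.03
    n_trial_range: tuple[int, int] = (100, 600)
    # survival (Step 2)
    hr_true: float = 0.58
    baseline_hazard: float = 0.06  # events per month
    censoring_frac: float = 0.25
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.3
    # gene-resolved exome (Step 3)
    n_genes: int = 2000
    gene_length_mean_mb: float = 0.0025
    gene_length_sigma: float = 0.5
    gene_rate_shape: float = 0.3  # gamma shape of per-gene rates
    mean_wes_tmb: float = 6.5  # expected nonsynonymous WES TMB, mut/Mb
    sample_factor_sigma: float = 0.8  # per-sample lognormal dispersion
    ref_panel_size: int = 400
    panel_enrichment: float = 1.35
    n_samples_exome: int = 500
    variant_class_probs: tuple[tuple[str, float], ...] = (
        ("Missense_Mutation", 0.58),
        ("Silent", 0.18),
        ("Nonsense_Mutation", 0.06),
        ("Splice_Site", 0.04),
        ("Frame_Shift_Del", 0.04),
        ("Frame_Shift_Ins", 0.03),
        ("In_Frame_Del", 0.02),
        ("In_Frame_Ins", 0.01),
        ("3'UTR", 0.04),
    )

    def __post_init__(self) -> None:
        if self.bulk_sigma <= 0 or self.hr_true <= 0:
            raise ValueError("bulk_sigma and hr_true must be positive")
        for frac in (
            self.censoring_frac,
            self.age_missing_frac,
            self.msi_h_prob_hyper,
            self.msi_h_prob_bulk,
            *self.hyper_frac_range,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth, written next to every dataset.

    Consumed only by tests and recovery checks, never by analysis code.
    """

    true_cutoff: float
    hr_true: float
    per_type_prop_high: dict[str, float] = field(default_factory=dict)
    panel_enrichment: float | None = None
    orr_slope: float | None = None
    orr_intercept: float | None = None


def write_truth(truth: SimTruth, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2, sort_keys=True))


def read_truth(path) -> SimTruth:
    return SimTruth(**json.loads(Path(path).read_text()))


def _rng(seed, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _truncated_lognormal_below(
    rng: np.random.Generator, mu: float, sigma: float, upper: float, size: int
) -> np.ndarray:
    """Lognormal(mu, sigma) conditioned on values < upper (inverse CDF)."""
    zmax = stats.norm.cdf((np.log(upper) - mu) / sigma)
    u = rng.uniform(0.0, zmax, size)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _type_names(n: int) -> list[str]:
    return [f"CT{i + 1:02d}" for i in range(n)]


def simulate_cohort(
    config: SimConfig, seed: int, n_types: int | None = None, per_type: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate clinical and per-sample TMB tables for a pan-cancer cohort.

    Returns ``(clinical, tmb, truth)``: a clinical table (one primary
    sample per patient, with age/sex/panel-version/MSI columns), a TMB
    table (sample_id, panel, tmb) and the planted truth.  Deterministic
    under (config, seed).
    """
    n_types = config.n_cancer_types if n_types is None else n_types
    per_type = config.samples_per_type if per_type is None else per_type
    cut = config.true_cutoff
    clin_rows, tmb_rows = [], []
    truth = SimTruth(
        true_cutoff=cut,
        hr_true=config.hr_true,
        orr_slope=config.orr_slope,
        orr_intercept=config.orr_intercept,
    )
    for t, ct in enumerate(_type_names(n_types)):
        rng = _rng(seed, 1, t)
        f_hyper = rng.uniform(*config.hyper_frac_range)
        mu = rng.uniform(*(np.log(config.bulk_median_range)))
        hyper = rng.random(per_type) < f_hyper
        tmb = _truncated_lognormal_below(rng, mu, config.bulk_sigma, cut, per_type)
        tmb[hyper] = cut + rng.exponential(config.hyper_tail_scale, hyper.sum())
        msi_p = np.where(hyper, config.msi_h_prob_hyper, config.msi_h_prob_bulk)
        msi = np.where(rng.random(per_type) < msi_p, "MSI-H", "MSS")
        age = rng.normal(config.age_mean, config.age_sd, per_type).clip(18, 95)
        age_missing = rng.random(per_type) < config.age_missing_frac
        sex = np.where(rng.random(per_type) < config.male_frac, "M", "F")
        pv = rng.choice(
            config.panel_versions, size=per_type, p=config.panel_version_probs
        )
        truth.per_type_prop_high[ct] = float(np.mean(tmb >= cut))
        ids = np.arange(1, per_type + 1)
        sids = np.char.add(f"{ct}-S", np.char.zfill(ids.astype(str), 4))
        clin_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sids,
                    "patient_id": np.char.add(
                        f"{ct}-P", np.char.zfill(ids.astype(str), 4)
                    ),
                    "cancer_type": ct,
                    "sample_type": "primary",
                    "age": np.where(age_missing, np.nan, np.round(age, 1)),
                    "sex": sex,
                    "panel_version": pv,
                    "msi_status": msi,
                }
            )
        )
        tmb_rows.append(
            pd.DataFrame(
                {"sample_id": sids, "panel": "synthetic-panel", "tmb": tmb}
            )
        )
    if not clin_rows:
        cols_c = ["sample_id", "patient_id", "cancer_type", "sample_type",
                  "age", "sex", "panel_version", "msi_status"]
        return (pd.DataFrame(columns=cols_c),
                pd.DataFrame(columns=["sample_id", "panel", "tmb"]), truth)
    return (
        pd.concat(clin_rows, ignore_index=True),
        pd.concat(tmb_rows, ignore_index=True),
        truth,
    )


def simulate_orr(
    clinical: pd.DataFrame, tmb: pd.DataFrame, config: SimConfig, seed: int
) -> pd.DataFrame:
    """Trial-summary table whose ORR is linearly linked to the TMB-high
    fraction at the planted cutoff (then clamped to [0, 1])."""
    if clinical.empty:
        raise ValueError("cohort is empty")
    rng = _rng(seed, 2)
    merged = clinical[["sample_id", "cancer_type"]].merge(tmb, on="sample_id")
    rows = []
    n_clamped = 0
    for ct, sub in merged.groupby("cancer_type", sort=True):
        p_high = float(np.mean(sub["tmb"] >= config.true_cutoff))
        raw = (
            config.orr_intercept
            + config.orr_slope * p_high
            + rng.normal(0.0, config.orr_noise_sd)
        )
        orr = float(np.clip(raw, 0.0, 1.0))
        n_clamped += raw != orr
        rows.append(
            {
                "cancer_type": ct,
                "n_trial": int(rng.integers(*config.n_trial_range)),
                "orr": orr,
            }
        )
    if n_clamped:
        logger.warning("simulate_orr: %d of %d ORR values clamped to [0, 1]",
                       n_clamped, len(rows))
    return pd.DataFrame(rows)


def simulate_survival(
    clinical: pd.DataFrame, tmb: pd.DataFrame, config: SimConfig, seed: int
) -> pd.DataFrame:
    """Survival table with a planted TMB-high hazard ratio.

    Event times are exponential (or Weibull behind a config switch) with
    the hazard multiplied by ``hr_true`` for samples at or above the true
    cutoff.  Censoring is independent of the event process: censor times
    are Uniform(0, L), with the window L solved so the expected censored
    fraction equals ``censoring_frac``.
    """
    merged = clinical.merge(tmb[["sample_id", "tmb"]], on="sample_id")
    if merged.empty:
        raise ValueError("cohort has no TMB values")
    rng = _rng(seed, 3)
    n = len(merged)
    lam = config.baseline_hazard * np.where(
        merged["tmb"].to_numpy() >= config.true_cutoff, config.hr_true, 1.0
    )
    if config.survival_model == "exponential":
        t_event = rng.exponential(1.0 / lam)
    elif config.survival_model == "weibull":
        k = config.weibull_shape
        # proportional-hazards Weibull: S(t) = exp(-(lam * t)^k scaled)
        t_event = (rng.exponential(1.0, n) / lam) ** (1.0 / k)
    else:
        raise ValueError(f"unknown survival_model {config.survival_model!r}")
    if config.censoring_frac <= 0.0:
        t_obs, event = t_event, np.ones(n, dtype=int)
    else:
        window = _censor_window(t_event, config.censoring_frac)
        c = rng.uniform(0.0, window, n)
        event = (t_event <= c).astype(int)
        t_obs = np.minimum(t_event, c)
    out = merged.copy()
    out["os_months"] = np.round(t_obs, 3)
    out["os_event"] = event
    return out


def _censor_window(t_event: np.ndarray, target: float) -> float:
    """Window L such that censoring at Uniform(0, L) removes the target
    fraction of events in expectation: mean(min(T, L)) / L = target."""
    lo, hi = 1e-9, float(t_event.max()) * 1e3 + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.minimum(t_event, mid).mean() / mid)
        if frac > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class SimExome:
    """A gene-resolved synthetic exome: universe, counts, MAF, panel."""

    universe: GeneUniverse
    counts: pd.DataFrame  # samples x genes, total mutation counts
    maf: pd.DataFrame  # MAF-dialect table with variant classes
    panel_genes: list[str]  # genes designated panel members (enriched)


def simulate_exome(config: SimConfig, seed: int, n_samples: int | None = None) -> SimExome:
    """Per-sample per-gene Poisson mutation counts plus a MAF.

    Gene mutation rates are heavy-tailed gamma draws scaled so the
    expected nonsynonymous whole-exome TMB equals ``mean_wes_tmb``;
    a per-sample lognormal factor (mean 1) creates between-tumor TMB
    dispersion; genes designated panel members get rates multiplied by
    ``panel_enrichment`` — the mechanism by which panels run hotter than
    whole-exome TMB.  Variant classes are multinomial per mutation.
    """
    n_samples = config.n_samples_exome if n_samples is None else n_samples
    rng = _rng(seed, 4)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    lengths = rng.lognormal(
        np.log(config.gene_length_mean_mb) - config.gene_length_sigma**2 / 2,
        config.gene_length_sigma,
        config.n_genes,
    )
    base = rng.gamma(config.gene_rate_shape, 1.0, config.n_genes) * lengths
    # scale so E[nonsynonymous WES TMB] = mean_wes_tmb
    classes, probs = zip(*config.variant_class_probs)
    nonsyn_share = sum(
        p
        for c, p in config.variant_class_probs
        if c not in ("Silent", "3'UTR")
    )
    base *= config.mean_wes_tmb * lengths.sum() / (base.sum() * nonsyn_share)
    panel_idx = rng.choice(config.n_genes, size=config.ref_panel_size, replace=False)
    rate = base.copy()
    rate[panel_idx] *= config.panel_enrichment
    sample_ids = [f"WES-S{i + 1:04d}" for i in range(n_samples)]
    factors = rng.lognormal(
        -config.sample_factor_sigma**2 / 2, config.sample_factor_sigma, n_samples
    )
    counts = rng.poisson(np.outer(factors, rate))
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=genes)
    counts_df.index.name = "sample_id"
    counts_df.columns.name = "gene"
    # expand to MAF rows with multinomial variant classes
    s_idx, g_idx = np.nonzero(counts)
    reps = counts[s_idx, g_idx]
    flat_s = np.repeat(s_idx, reps)
    flat_g = np.repeat(g_idx, reps)
    vclass = rng.choice(len(classes), size=len(flat_s), p=probs)
    maf = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": np.array(sample_ids)[flat_s],
            "Hugo_Symbol": np.array(genes)[flat_g],
            "Variant_Classification": np.array(classes)[vclass],
        }
    )
    universe = GeneUniverse(
        genes=genes, length_mb=lengths, mutation_rate=rate / lengths
    )
    return SimExome(
        universe=universe,
        counts=counts_df,
        maf=maf,
        panel_genes=[genes[i] for i in sorted(panel_idx)],
    )


def simulate_bundle(config: SimConfig, seed: int, outdir) -> dict[str, str]:
    """Write a complete synthetic input bundle to a directory.

    Emits clinical.tsv, tmb.tsv, trials.tsv, survival.tsv, maf.tsv,
    universe.tsv, panel_reference.txt and truth.json; returns a name ->
    path map.  Byte-identical under identical (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical, tmb, truth = simulate_cohort(config, seed)
    trials = simulate_orr(clinical, tmb, config, seed)
    # the survival cohort emulates a smaller immunotherapy-treated series
    surv_clin, surv_tmb, _ = simulate_cohort(
        config, seed + 1, n_types=8, per_type=250
    )
    survival = simulate_survival(surv_clin, surv_tmb, config, seed)
    exome = simulate_exome(config, seed)
    truth.panel_enrichment = config.panel_enrichment

    paths = {}

    def _write(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=kw.pop("index", False), **kw)
        paths[name.split(".")[0]] = str(p)

    _write("clinical.tsv", clinical)
    _write("tmb.tsv", tmb)
    _write("trials.tsv", trials)
    _write("survival.tsv", survival)
    _write("maf.tsv", exome.maf)
    _write("universe.tsv", exome.universe.to_frame())
    panel_path = outdir / "panel_reference.txt"
    panel_path.write_text("\n".join(exome.panel_genes) + "\n")
    paths["panel_reference"] = str(panel_path)
    truth_path = outdir / "truth.json"
    write_truth(truth, truth_path)
    paths["truth"] = str(truth_path)
    return paths
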