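"""End-to-end orchestration of the three-step cutoff analysis.

Step 1 scans candidate universal TMB cutoffs against cancer-type-level
response rates and locates the Chow breakpoint; Step 2 verifies the
candidate cutoff on patient-level survival; Step 3 quantifies how well
alternative and randomly sampled gene panels reproduce the TMB-high
classification.  Each step reads validated TSV inputs, writes TSV tables
and a JSON report carrying a config echo, input checksums and a schema
version, and never mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cutoff_scan, panel_concordance, survival_verify, tmb_core

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = ["RunConfig", "run_step1", "run_step2", "run_step3", "run_all"]


@dataclass
class RunConfig:
    """Inputs, parameters and output location for a pipeline run."""

    outdir: str
    # input paths
    clinical: str | None = None
    tmb: str | None = None
    trials: str | None = None
    survival: str | None = None
    maf: str | None = None
    universe: str | None = None
    reference_panel: str | None = None
    # step 1
    scan_grid: tuple[float, ...] = tuple(np.arange(1.0, 21.0))
    min_cohort: int = 30
    min_trial: int = 10
    # step 2
    cutoff: float | None = None  # None -> use step 1's breakpoint
    percentile: float = 0.80
    z_grid: tuple[float, ...] = tuple(np.arange(1.0, 16.0))
    n_boot: int = 200
    # step 3
    reference_territory_mb: float | None = None  # None -> summed gene lengths
    panel_sizes: tuple[int, ...] = (100, 250, 400)
    shared_fracs: tuple[float, ...] = (0.5, 0.8, 1.0)
    n_rep: int = 50
    wes_cutoff: float = 8.0
    seed: int = 0
    plots: bool = False  # write PNG figures next to the TSV outputs

    def validate(self, require: tuple[str, ...]) -> None:
        """Fail before any computation if a required input is missing."""
        for name in require:
            path = getattr(self, name)
            if path is None:
                raise ValueError(f"run config is missing required input {name!r}")
            if not Path(path).is_file():
                raise FileNotFoundError(f"input file for {name!r} not found: {path}")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    for key, val in echo.items():
        if isinstance(val, tuple):
            echo[key] = list(val)
    return echo


def _write_report(config: RunConfig, name: str, payload: dict, inputs: dict) -> dict:
    report = {
        "schema_version": SCHEMA_VERSION,
        "step": name,
        "config": _config_echo(config),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
        **payload,
    }
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{name}_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    )
    return report


def _plot_curve(x, y, breakpoint_x, xlabel, ylabel, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(x, y, marker="o", ms=3)
    ax.axvline(breakpoint_x, ls="--", color="crimson", label=f"breakpoint {breakpoint_x:g}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_grid_heatmap(grid_df: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = grid_df.pivot(index="shared_frac", columns="size", values="mean_kappa")
    fig, ax = plt.subplots(figsize=(5, 3.6))
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xlabel("panel size (genes)")
    ax.set_ylabel("shared gene fraction")
    fig.colorbar(im, ax=ax, label="mean Cohen's kappa")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _load_tmb_by_type(config: RunConfig) -> dict[str, np.ndarray]:
    clinical = pd.read_csv(config.clinical, sep="\t")
    tmb = pd.read_csv(config.tmb, sep="\t")
    merged = clinical[["sample_id", "cancer_type"]].merge(tmb, on="sample_id")
    return {
        str(ct): sub["tmb"].to_numpy(float)
        for ct, sub in merged.groupby("cancer_type", sort=True)
    }


def run_step1(config: RunConfig) -> dict:
    """Cutoff scan: weighted ORR correlation per cutoff + Chow breakpoint."""
    config.validate(("clinical", "tmb", "trials"))
    tmb_by_type = _load_tmb_by_type(config)
    trials_df = pd.read_csv(config.trials, sep="\t")
    trials = [
        cutoff_scan.TrialSummary(str(r.cancer_type), int(r.n_trial), float(r.orr))
        for r in trials_df.itertuples()
    ]
    curve = cutoff_scan.scan(
        tmb_by_type,
        trials,
        grid=np.asarray(config.scan_grid),
        min_cohort=config.min_cohort,
        min_trial=config.min_trial,
    )
    bp = cutoff_scan.chow_breakpoint(curve.cutoffs, curve.statistic)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scan_df = pd.DataFrame(
        {
            "cutoff": curve.cutoffs,
            "r": curve.statistic,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
        }
    )
    chow_df = pd.DataFrame({"candidate": bp.candidates, "chow_f": bp.f_stats})
    scan_df.to_csv(out / "step1_scan.tsv", sep="\t", index=False)
    chow_df.to_csv(out / "step1_chow.tsv", sep="\t", index=False)
    if config.plots:
        _plot_curve(
            curve.cutoffs,
            curve.statistic,
            bp.breakpoint,
            "TMB cutoff (mut/Mb)",
            "weighted R (ORR vs TMB-high fraction)",
            out / "step1_scan.png",
        )
    i_bp = int(np.searchsorted(curve.cutoffs, bp.breakpoint))
    payload = {
        "breakpoint": bp.breakpoint,
        "chow_p_value": bp.p_value,
        "f_max": None if np.isinf(bp.f_max) else bp.f_max,
        "infinite_f": bp.infinite_f,
        "r_at_breakpoint": float(curve.statistic[i_bp]),
        "r_peak": float(np.max(curve.statistic)),
        "r_ci_at_breakpoint": [
            float(curve.ci_low[i_bp]),
            float(curve.ci_high[i_bp]),
        ],
        "n_cancer_types": len(tmb_by_type),
    }
    return _write_report(
        config,
        "step1",
        payload,
        {"clinical": config.clinical, "tmb": config.tmb, "trials": config.trials},
    )


def _cox_payload(res: survival_verify.CoxResult) -> dict:
    return {
        "hr": res.hr,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "z": res.z,
        "p": res.p,
        "c_index": res.c_index,
        "n": res.n,
        "n_events": res.n_events,
    }


def run_step2(config: RunConfig, cutoff: float | None = None) -> dict:
    """Survival verification of the universal cutoff vs the percentile policy."""
    config.validate(("survival",))
    df = survival_verify.read_survival(config.survival)
    cutoff = (
        cutoff
        if cutoff is not None
        else (config.cutoff if config.cutoff is not None else 10.0)
    )
    universal = survival_verify.CutoffPolicy("universal", cutoff)
    percentile = survival_verify.CutoffPolicy("percentile", config.percentile)

    fit_uni = survival_verify.fit_cox(df, universal)
    fit_pct = survival_verify.fit_cox(df, percentile)
    curve, bp = survival_verify.z_scan(df, np.asarray(config.z_grid))
    cmp_c = survival_verify.compare_cindex(
        df, universal, percentile, n_boot=config.n_boot, seed=config.seed
    )
    inter_p = survival_verify.interaction_test(df, universal)
    forest = survival_verify.subgroup_hrs(df, universal)
    mss = survival_verify.mss_sensitivity(df, universal)

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cutoff": curve.cutoffs, "z": curve.statistic}).to_csv(
        out / "step2_zscan.tsv", sep="\t", index=False
    )
    forest.to_csv(out / "step2_forest.tsv", sep="\t", index=False)
    if config.plots:
        _plot_curve(
            curve.cutoffs,
            -curve.statistic,  # display convention: protective effect rises
            bp.breakpoint,
            "TMB cutoff (mut/Mb)",
            "-Z (Wald, TMB-high coefficient)",
            out / "step2_zscan.png",
        )

    # the Z-scan's own breakpoint may differ from the cutoff under test;
    # report the adjusted fit at that recovered threshold as well
    fit_at_bp = (
        fit_uni
        if bp.breakpoint == cutoff
        else survival_verify.fit_cox(
            df, survival_verify.CutoffPolicy("universal", bp.breakpoint)
        )
    )

    payload = {
        "cutoff": cutoff,
        "universal": _cox_payload(fit_uni),
        "percentile": _cox_payload(fit_pct),
        "universal_at_breakpoint": _cox_payload(fit_at_bp),
        "breakpoint": bp.breakpoint,
        "chow_p_value": bp.p_value,
        "cindex_delta": cmp_c.delta,
        "cindex_p": cmp_c.p,
        "interaction_p": inter_p if np.isfinite(inter_p) else None,
        "mss_only": _cox_payload(mss),
    }
    return _write_report(config, "step2", payload, {"survival": config.survival})


def run_step3(config: RunConfig, cutoff: float | None = None) -> dict:
    """Panel-concordance simulation against the reference panel."""
    config.validate(("maf", "universe", "reference_panel"))
    cutoff = (
        cutoff
        if cutoff is not None
        else (config.cutoff if config.cutoff is not None else 10.0)
    )
    universe = panel_concordance.GeneUniverse.from_frame(
        pd.read_csv(config.universe, sep="\t")
    )
    ref_genes = tmb_core.read_panel_genes(config.reference_panel)
    territory = (
        config.reference_territory_mb
        if config.reference_territory_mb is not None
        else universe.territory(sorted(ref_genes & set(universe.genes)))
    )
    reference = tmb_core.PanelDefinition(
        name="reference",
        genes=ref_genes,
        territory_mb=territory,
        pipeline=tmb_core.MSK_STYLE_FILTER,
    )
    mutations = tmb_core.read_maf(config.maf)
    counts = tmb_core.mutation_count_matrix(mutations, reference.pipeline)
    counts = counts.reindex(columns=universe.genes, fill_value=0)

    cells = panel_concordance.concordance_grid(
        counts,
        universe,
        reference,
        sizes=config.panel_sizes,
        shared_fracs=config.shared_fracs,
        n_rep=config.n_rep,
        cutoff=cutoff,
        seed=config.seed,
    )
    grid_df = panel_concordance.grid_summary(cells)

    wes = tmb_core.PanelDefinition(
        name="wes",
        genes=frozenset(universe.genes),
        territory_mb=universe.total_territory_mb,
        pipeline=reference.pipeline,
    )
    wes_tmb = tmb_core.tmb_from_counts(counts, wes)
    ref_tmb = tmb_core.tmb_from_counts(counts, reference)
    diff = panel_concordance.paired_diff(wes_tmb.to_numpy(), ref_tmb.to_numpy())
    kappa_same_cutoff = panel_concordance.kappa(
        wes_tmb.to_numpy() >= cutoff, ref_tmb.to_numpy() >= cutoff
    )
    kappa_adjusted = panel_concordance.wes_adjusted_cutoff_check(
        wes_tmb.to_numpy(),
        ref_tmb.to_numpy(),
        wes_cutoff=config.wes_cutoff,
        panel_cutoff=cutoff,
    )

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    grid_df.to_csv(out / "step3_grid.tsv", sep="\t", index=False)
    if config.plots and not grid_df.empty:
        _plot_grid_heatmap(grid_df, out / "step3_grid.png")

    payload = {
        "cutoff": cutoff,
        "grid": grid_df.to_dict(orient="records"),
        "wes_vs_reference": {
            "mean_diff": diff.mean_diff,
            "ci_low": diff.ci_low,
            "ci_high": diff.ci_high,
            "t_stat": diff.t_stat,
            "p": diff.p,
            "n": diff.n,
        },
        "kappa_wes_same_cutoff": kappa_same_cutoff,
        "kappa_wes_adjusted_cutoff": kappa_adjusted,
        "wes_cutoff": config.wes_cutoff,
    }
    return _write_report(
        config,
        "step3",
        payload,
        {
            "maf": config.maf,
            "universe": config.universe,
            "reference_panel": config.reference_panel,
        },
    )


def run_all(config: RunConfig) -> dict:
    """Chain the three steps; Step 1's breakpoint feeds Steps 2 and 3
    unless a cutoff is set explicitly in the config."""
    config.validate(
        ("clinical", "tmb", "trials", "survival", "maf", "universe", "reference_panel")
    )
    report1 = run_step1(config)
    cutoff = config.cutoff if config.cutoff is not None else report1["breakpoint"]
    report2 = run_step2(config, cutoff=cutoff)
    report3 = run_step3(config, cutoff=cutoff)
    combined = {
        "schema_version": SCHEMA_VERSION,
        "step": "all",
        "cutoff_used": cutoff,
        "step1": report1,
        "step2": report2,
        "step3": report3,
    }
    (Path(config.outdir) / "combined_report.json").write_text(
        json.dumps(combined, indent=2, sort_keys=True, allow_nan=True)
    )
    return combined
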