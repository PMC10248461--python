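"""In-silico gene-panel concordance of TMB-high classification.

Targeted panels estimate TMB from roughly one megabase of sequence; how
well a given panel reproduces the TMB-high calls of a reference panel
depends on its size and on the fraction of genes it shares with the
reference.  This module emulates fixed panels and randomly sampled panels
over a (panel size x shared-gene-fraction) grid, computes each panel's
TMB under a pipeline counting rule, and quantifies agreement of TMB-high
calls with the reference via Cohen's Kappa.  It also measures the paired
whole-exome-vs-panel TMB difference that motivates using a lower cutoff
for whole-exome sequencing (WES) than for panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tmb_core import PanelDefinition, PipelineFilter, tmb_from_counts

logger = logging.getLogger(__name__)

__all__ = [
    "GeneUniverse",
    "ConcordanceCell",
    "PairedDiff",
    "DEFAULT_SIZES",
    "DEFAULT_SHARED_FRACS",
    "build_fixed_panels",
    "shared_fraction",
    "sample_random_panel",
    "kappa",
    "concordance_grid",
    "paired_diff",
    "wes_adjusted_cutoff_check",
]

DEFAULT_SIZES = tuple(range(50, 501, 50))
DEFAULT_SHARED_FRACS = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class GeneUniverse:
    """The gene space panels are drawn from (a WES-style universe).

    Per gene: callable length in Mb and the expected mutations per sample
    (the latter is used by the synthetic exome generator).
    """

    genes: list[str]
    length_mb: np.ndarray
    mutation_rate: np.ndarray

    def __post_init__(self) -> None:
        self.length_mb = np.asarray(self.length_mb, dtype=float)
        self.mutation_rate = np.asarray(self.mutation_rate, dtype=float)
        if not (len(self.genes) == len(self.length_mb) == len(self.mutation_rate)):
            raise ValueError("genes, length_mb and mutation_rate must align")
        if np.any(self.length_mb <= 0):
            raise ValueError("gene lengths must be positive")
        if np.any(self.mutation_rate < 0):
            raise ValueError("mutation rates must be nonnegative")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def territory(self, genes: Sequence[str]) -> float:
        """Summed callable length (Mb) of a gene subset."""
        return float(sum(self.length_mb[self._index[g]] for g in genes))

    @property
    def total_territory_mb(self) -> float:
        return float(self.length_mb.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "length_mb": self.length_mb, "rate": self.mutation_rate}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneUniverse":
        return cls(
            genes=df["gene"].astype(str).tolist(),
            length_mb=df["length_mb"].to_numpy(float),
            mutation_rate=df["rate"].to_numpy(float),
        )


@dataclass
class ConcordanceCell:
    """One (panel size x shared fraction) cell of the resampling grid."""

    panel_size: int
    shared_frac: float
    kappas: np.ndarray
    frac_above_080: float

    def __post_init__(self) -> None:
        self.kappas = np.asarray(self.kappas, dtype=float)
        if np.any((self.kappas < -1 - 1e-12) | (self.kappas > 1 + 1e-12)):
            raise ValueError("kappa values must lie in [-1, 1]")


@dataclass(frozen=True)
class PairedDiff:
    mean_diff: float
    ci_low: float
    ci_high: float
    t_stat: float
    p: float
    n: int


def shared_fraction(panel: PanelDefinition, reference: PanelDefinition) -> float:
    """Fraction of the panel's genes also present in the reference panel."""
    return len(panel.genes & reference.genes) / len(panel.genes)


def build_fixed_panels(
    gene_lists: Mapping[str, Sequence[str]],
    territories: Mapping[str, float],
    pipelines: Mapping[str, PipelineFilter],
    reference_name: str | None = None,
) -> list[PanelDefinition]:
    """Assemble named fixed panels and report sharing with the reference.

    ``gene_lists`` maps panel name to its gene symbols (already read from
    one-symbol-per-line files); duplicates are removed with a warning and
    an empty list is fatal.  Each panel gets its own territory (Mb) and
    pipeline filter.  If ``reference_name`` is given, the shared-gene
    fraction of every panel against it is logged.
    """
    panels = []
    for name, symbols in gene_lists.items():
        symbols = [s.strip() for s in symbols if s.strip()]
        unique = frozenset(symbols)
        if not unique:
            raise ValueError(f"panel {name!r}: gene list is empty")
        if len(unique) < len(symbols):
            logger.warning(
                "panel %s: removed %d duplicate symbol(s)",
                name,
                len(symbols) - len(unique),
            )
        panels.append(
            PanelDefinition(
                name=name,
                genes=unique,
                territory_mb=float(territories[name]),
                pipeline=pipelines[name],
            )
        )
    if reference_name is not None:
        ref = next(p for p in panels if p.name == reference_name)
        for p in panels:
            logger.info(
                "panel %s: %d genes, shared fraction vs %s = %.3f",
                p.name,
                len(p.genes),
                reference_name,
                shared_fraction(p, ref),
            )
    return panels


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sample_random_panel(
    universe: GeneUniverse,
    size: int,
    shared_frac: float,
    reference: PanelDefinition,
    rng: np.random.Generator,
    pipeline: PipelineFilter | None = None,
    name: str = "random",
) -> PanelDefinition:
    """Draw a random panel with a prescribed overlap with the reference.

    Exactly ``k = round(size * shared_frac)`` genes (half away from zero)
    are drawn uniformly without replacement from the reference panel and
    ``size - k`` from the rest of the universe.  The panel's territory is
    the summed callable length of its members.
    """
    k = _round_half_away(size * shared_frac)
    ref_genes = sorted(reference.genes & set(universe.genes))
    outside = sorted(set(universe.genes) - reference.genes)
    if k > len(ref_genes):
        raise ValueError(
            f"infeasible panel: need {k} shared genes but the reference "
            f"has only {len(ref_genes)} in the universe"
        )
    if size - k > len(outside):
        raise ValueError(
            f"infeasible panel: need {size - k} non-reference genes but "
            f"only {len(outside)} are available outside the reference"
        )
    chosen = list(rng.choice(ref_genes, size=k, replace=False)) + list(
        rng.choice(outside, size=size - k, replace=False)
    )
    return PanelDefinition(
        name=name,
        genes=frozenset(chosen),
        territory_mb=universe.territory(chosen),
        pipeline=pipeline if pipeline is not None else reference.pipeline,
    )


def kappa(labels_a: Sequence[bool], labels_b: Sequence[bool]) -> float:
    """Cohen's Kappa for two binary labelings.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the chance agreement from the 2x2 table margins.  When p_e = 1
    (all four margins degenerate the same way) the statistic is undefined;
    by convention this returns 1 for identical vectors and 0 otherwise.
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("label vectors must be non-empty")
    n = a.size
    p_o = float(np.mean(a == b))
    pa1, pb1 = float(a.mean()), float(b.mean())
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _cell_rng(seed: int, size: int, shared_frac: float, rep: int) -> np.random.Generator:
    """Deterministic per-replicate generator, so any cell can be recomputed
    in isolation regardless of grid order."""
    key = (size, int(round(shared_frac * 1000)), rep)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def concordance_grid(
    counts: pd.DataFrame,
    universe: GeneUniverse,
    reference: PanelDefinition,
    sizes: Sequence[int] = DEFAULT_SIZES,
    shared_fracs: Sequence[float] = DEFAULT_SHARED_FRACS,
    n_rep: int = 1000,
    pipeline: PipelineFilter | None = None,
    cutoff: float = 10.0,
    seed: int = 0,
) -> list[ConcordanceCell]:
    """Kappa between reference and random panels over a (size x sharing) grid.

    ``counts`` is the samples x genes matrix of qualifying mutation counts
    under the chosen pipeline's class filter (built once per pipeline by
    :func:`tmbcut.tmb_core.mutation_count_matrix` — the same code path as
    panel TMB everywhere else).  Per cell, ``n_rep`` random panels are
    drawn; each panel's TMB is computed with its own summed-gene-length
    territory, TMB-high is called at ``cutoff``, and Cohen's Kappa against
    the reference panel's labels is recorded.  Replicate seeds derive
    deterministically from (seed, size, shared fraction, replicate index).
    Infeasible cells are skipped with a warning.
    """
    pipeline = pipeline if pipeline is not None else reference.pipeline
    ref_labels = (tmb_from_counts(counts, reference) >= cutoff).to_numpy()
    cells: list[ConcordanceCell] = []
    for size in sizes:
        for sf in shared_fracs:
            try:
                kappas = np.empty(n_rep)
                for rep in range(n_rep):
                    rng = _cell_rng(seed, size, sf, rep)
                    panel = sample_random_panel(
                        universe, size, sf, reference, rng, pipeline=pipeline
                    )
                    labels = (tmb_from_counts(counts, panel) >= cutoff).to_numpy()
                    kappas[rep] = kappa(ref_labels, labels)
            except ValueError as err:
                logger.warning(
                    "grid cell (size=%d, shared=%.2f) skipped: %s", size, sf, err
                )
                continue
            cells.append(
                ConcordanceCell(
                    panel_size=size,
                    shared_frac=sf,
                    kappas=kappas,
                    frac_above_080=float(np.mean(kappas > 0.80)),
                )
            )
    return cells


def grid_summary(cells: Sequence[ConcordanceCell]) -> pd.DataFrame:
    """Tabulate a resampling grid: mean/median Kappa and the fraction > 0.80."""
    return pd.DataFrame(
        {
            "size": [c.panel_size for c in cells],
            "shared_frac": [c.shared_frac for c in cells],
            "mean_kappa": [float(np.mean(c.kappas)) for c in cells],
            "median_kappa": [float(np.median(c.kappas)) for c in cells],
            "frac_kappa_above_080": [c.frac_above_080 for c in cells],
        }
    )


def paired_diff(tmb_a: Sequence[float], tmb_b: Sequence[float]) -> PairedDiff:
    """Paired t-test of per-sample TMB differences (a - b), mut/Mb."""
    a = np.asarray(tmb_a, dtype=float)
    b = np.asarray(tmb_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must align and have n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError(
            "all paired differences are identical; the paired t statistic "
            "is undefined (zero variance)"
        )
    n = d.size
    mean = float(d.mean())
    se = float(d.std(ddof=1) / math.sqrt(n))
    t_res = stats.ttest_rel(a, b)
    half = stats.t.ppf(0.975, n - 1) * se
    return PairedDiff(
        mean_diff=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        t_stat=float(t_res.statistic),
        p=float(t_res.pvalue),
        n=n,
    )


def wes_adjusted_cutoff_check(
    wes_tmb: Sequence[float],
    panel_tmb: Sequence[float],
    wes_cutoff: float = 8.0,
    panel_cutoff: float = 10.0,
) -> float:
    """Kappa between WES TMB-high at its own cutoff and panel TMB-high.

    Panels enrich for frequently mutated genes, so WES TMB runs lower than
    panel TMB for the same tumor; lowering the WES cutoff (default 8 vs 10
    mut/Mb) compensates.
    """
    wes = np.asarray(wes_tmb, dtype=float)
    pan = np.asarray(panel_tmb, dtype=float)
    if wes.shape != pan.shape:
        raise ValueError("WES and panel TMB vectors must align")
    return kappa(wes >= wes_cutoff, pan >= panel_cutoff)
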