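"""Per-sample tumor mutational burden (TMB) from gene-panel mutation calls.

TMB is the number of qualifying somatic mutations divided by the panel's
callable territory in megabases.  What "qualifying" means depends on the
panel's bioinformatics pipeline: which variant classes are counted and
which genes (e.g. hotspot lists) are excluded.  This module reads
MAF-dialect mutation tables and clinical tables, selects one sample per
patient, computes TMB under a named panel + pipeline, and classifies
TMB-high status against a cutoff in mut/Mb.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "SampleType",
    "MutationRecord",
    "ClinicalRecord",
    "PipelineFilter",
    "PanelDefinition",
    "SampleTMB",
    "MAF_CLASS_MAP",
    "NONSYNONYMOUS",
    "MSK_STYLE_FILTER",
    "F1CDX_STYLE_FILTER",
    "PGDX_STYLE_FILTER",
    "read_maf",
    "read_clinical",
    "select_samples",
    "mutation_count_matrix",
    "tmb_from_counts",
    "compute_tmb",
    "classify_high",
    "write_tmb_table",
]


class VariantClass(str, enum.Enum):
    """Closed set of somatic variant classes recognised by TMB pipelines."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SILENT = "silent"
    OTHER = "other"


class SampleType(str, enum.Enum):
    PRIMARY = "primary"
    METASTATIC = "metastatic"
    ADDITIONAL_METASTATIC = "additional_metastatic"


#: Fixed mapping from standard MAF ``Variant_Classification`` strings to the
#: internal enum.  Strings absent from this table map to ``OTHER`` and are
#: reported through the mapping audit log.
MAF_CLASS_MAP: dict[str, VariantClass] = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Splice_Site": VariantClass.SPLICE_SITE,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_INDEL,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INDEL,
    "In_Frame_Del": VariantClass.INFRAME_INDEL,
    "In_Frame_Ins": VariantClass.INFRAME_INDEL,
    "Silent": VariantClass.SILENT,
}

#: Variant classes conventionally counted as nonsynonymous.
NONSYNONYMOUS = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.SPLICE_SITE,
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call — the atom of TMB computation."""

    sample_id: str
    gene: str
    variant_class: VariantClass

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")


@dataclass
class ClinicalRecord:
    sample_id: str
    patient_id: str
    cancer_type: str
    sample_type: SampleType = SampleType.PRIMARY
    age: float | None = None
    sex: str | None = None
    panel_version: str | None = None
    msi_status: str = "unknown"
    os_months: float | None = None
    os_event: bool | None = None

    def __post_init__(self) -> None:
        if (self.os_months is None) != (self.os_event is None):
            raise ValueError(
                f"sample {self.sample_id}: os_months and os_event must be "
                "present or absent together"
            )
        if self.os_months is not None and self.os_months < 0:
            raise ValueError(f"sample {self.sample_id}: negative os_months")


@dataclass(frozen=True)
class PipelineFilter:
    """Counting rule of a panel's bioinformatics pipeline.

    ``counted_classes`` is the subset of variant classes that contribute to
    the mutation count; ``excluded_genes`` are removed from any panel before
    counting (hotspot exclusion lists, for example).
    """

    counted_classes: frozenset[VariantClass]
    excluded_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.counted_classes:
            raise ValueError("counted_classes must be non-empty")


# Default pipeline approximations; the vendors' exact rules are proprietary,
# so these are config-overridable and documented as approximations.
MSK_STYLE_FILTER = PipelineFilter(counted_classes=NONSYNONYMOUS)
F1CDX_STYLE_FILTER = PipelineFilter(
    counted_classes=frozenset(NONSYNONYMOUS | {VariantClass.SILENT})
)
PGDX_STYLE_FILTER = PipelineFilter(
    counted_classes=frozenset(
        {
            VariantClass.MISSENSE,
            VariantClass.NONSENSE,
            VariantClass.FRAMESHIFT_INDEL,
            VariantClass.INFRAME_INDEL,
        }
    )
)


@dataclass(frozen=True)
class PanelDefinition:
    """A gene set with callable territory (Mb) and its counting pipeline."""

    name: str
    genes: frozenset[str]
    territory_mb: float
    pipeline: PipelineFilter = MSK_STYLE_FILTER

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r}: gene set must be non-empty")
        if self.territory_mb <= 0:
            raise ValueError(
                f"panel {self.name!r}: territory_mb must be positive, "
                f"got {self.territory_mb}"
            )

    @property
    def effective_genes(self) -> frozenset[str]:
        """Genes counted after applying the pipeline's exclusion list."""
        return self.genes - self.pipeline.excluded_genes


@dataclass(frozen=True)
class SampleTMB:
    sample_id: str
    tmb: float
    panel_name: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.tmb) or self.tmb < 0:
            raise ValueError(f"sample {self.sample_id}: invalid TMB {self.tmb}")


_MAF_REQUIRED = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


def read_maf(path) -> list[MutationRecord]:
    """Read a MAF-dialect TSV into mutation records.

    Requires columns ``Tumor_Sample_Barcode``, ``Hugo_Symbol`` and
    ``Variant_Classification``; extra columns are ignored.  Unknown
    variant-classification strings map to :attr:`VariantClass.OTHER`, with an
    audit warning listing every unmapped string encountered.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file {path} is missing required column(s): {missing}")
    if df.empty:
        logger.warning("MAF file %s contains a header but no data rows", path)
        return []
    unmapped = sorted(set(df["Variant_Classification"]) - set(MAF_CLASS_MAP))
    if unmapped:
        logger.warning(
            "MAF file %s: %d variant-classification string(s) not in the "
            "mapping table, counted as 'other': %s",
            path,
            len(unmapped),
            unmapped,
        )
    classes = df["Variant_Classification"].map(
        lambda s: MAF_CLASS_MAP.get(s, VariantClass.OTHER)
    )
    return [
        MutationRecord(sample_id=s, gene=g.strip(), variant_class=c)
        for s, g, c in zip(df["Tumor_Sample_Barcode"], df["Hugo_Symbol"], classes)
    ]


_SAMPLE_TYPE_ALIASES = {
    "primary": SampleType.PRIMARY,
    "metastasis": SampleType.METASTATIC,
    "metastatic": SampleType.METASTATIC,
    "additional metastatic": SampleType.ADDITIONAL_METASTATIC,
    "additional_metastatic": SampleType.ADDITIONAL_METASTATIC,
}


def read_clinical(path) -> list[ClinicalRecord]:
    """Read a clinical TSV (one row per sample) into records.

    ``sample_id`` must be unique; ``os_months`` and ``os_event`` must be
    jointly present or jointly missing on each row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    for col in ("sample_id", "patient_id", "cancer_type"):
        if col not in df.columns:
            raise ValueError(f"clinical file {path} is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"clinical file {path}: duplicate sample_id {dup!r}")

    def _get(row, col, default=None):
        if col not in df.columns or pd.isna(row[col]):
            return default
        return row[col]

    records = []
    for _, row in df.iterrows():
        st_raw = str(_get(row, "sample_type", "primary")).strip().lower()
        if st_raw not in _SAMPLE_TYPE_ALIASES:
            raise ValueError(f"unrecognised sample_type {st_raw!r}")
        ev = _get(row, "os_event")
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                cancer_type=str(row["cancer_type"]),
                sample_type=_SAMPLE_TYPE_ALIASES[st_raw],
                age=_get(row, "age"),
                sex=_get(row, "sex"),
                panel_version=_get(row, "panel_version"),
                msi_status=_get(row, "msi_status", "unknown"),
                os_months=_get(row, "os_months"),
                os_event=None if ev is None else bool(int(ev)),
            )
        )
    return records


_SAMPLE_TYPE_PRIORITY = {
    SampleType.PRIMARY: 0,
    SampleType.METASTATIC: 1,
    SampleType.ADDITIONAL_METASTATIC: 2,
}


def select_samples(clinical: Sequence[ClinicalRecord]) -> list[ClinicalRecord]:
    """Keep exactly one sample per patient.

    Priority: primary > metastatic > additional metastatic; ties within a
    priority class are broken by lexicographically smallest ``sample_id`` so
    the selection is deterministic.  Idempotent by construction.
    """
    best: dict[str, ClinicalRecord] = {}
    for rec in clinical:
        key = (_SAMPLE_TYPE_PRIORITY[rec.sample_type], rec.sample_id)
        cur = best.get(rec.patient_id)
        if cur is None or key < (_SAMPLE_TYPE_PRIORITY[cur.sample_type], cur.sample_id):
            best[rec.patient_id] = rec
    # stable output order: by patient then sample id
    return sorted(best.values(), key=lambda r: (r.patient_id, r.sample_id))


def mutation_count_matrix(
    mutations: Iterable[MutationRecord],
    pipeline: PipelineFilter,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Samples x genes matrix of qualifying mutation counts under a pipeline.

    Only mutations whose variant class is in ``pipeline.counted_classes``
    contribute.  Gene-level exclusions are applied at panel level (a panel's
    effective gene set), not here, so one matrix serves every panel sharing
    the pipeline's class filter.  Rows cover ``sample_ids`` if given (samples
    with no qualifying mutations get all-zero rows); otherwise the samples
    observed in the mutation list.
    """
    rows = [
        (m.sample_id, m.gene)
        for m in mutations
        if m.variant_class in pipeline.counted_classes
    ]
    if rows:
        df = pd.DataFrame(rows, columns=["sample_id", "gene"])
        mat = pd.crosstab(df["sample_id"], df["gene"])
    else:
        mat = pd.DataFrame(dtype=int)
    if sample_ids is not None:
        mat = mat.reindex(index=list(sample_ids), fill_value=0)
    mat = mat.fillna(0).astype(int)
    mat.index.name = "sample_id"
    mat.columns.name = "gene"
    return mat


def tmb_from_counts(counts: pd.DataFrame, panel: PanelDefinition) -> pd.Series:
    """TMB per sample from a qualifying-count matrix; mut/Mb.

    This is the single code path for panel TMB: :func:`compute_tmb` and the
    panel-concordance resampling both route through it.
    """
    if panel.territory_mb <= 0:  # defensive; PanelDefinition already enforces
        raise ValueError("territory_mb must be positive")
    cols = [g for g in counts.columns if g in panel.effective_genes]
    total = counts[cols].sum(axis=1) if cols else pd.Series(0.0, index=counts.index)
    tmb = total / panel.territory_mb
    tmb.name = "tmb"
    return tmb.astype(float)


def compute_tmb(
    mutations: Iterable[MutationRecord],
    panel: PanelDefinition,
    sample_ids: Sequence[str] | None = None,
) -> list[SampleTMB]:
    """Per-sample TMB under a panel: qualifying count / territory (mut/Mb).

    A mutation qualifies when its gene is in the panel's effective gene set
    (panel genes minus pipeline exclusions) and its variant class is counted
    by the pipeline.  Samples in the roster with no mutation rows get TMB 0.
    """
    counts = mutation_count_matrix(mutations, panel.pipeline, sample_ids)
    tmb = tmb_from_counts(counts, panel)
    return [
        SampleTMB(sample_id=str(s), tmb=float(v), panel_name=panel.name)
        for s, v in tmb.items()
    ]


def classify_high(tmb: float, cutoff: float) -> bool:
    """TMB-high status: boundary inclusive, ``tmb >= cutoff``."""
    if cutoff < 0:
        raise ValueError(f"cutoff must be nonnegative, got {cutoff}")
    return tmb >= cutoff


def write_tmb_table(tmbs: Sequence[SampleTMB], path) -> None:
    """Write per-sample TMB as TSV (sample_id, panel, tmb)."""
    pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in tmbs],
            "panel": [t.panel_name for t in tmbs],
            "tmb": [t.tmb for t in tmbs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_panel_genes(path) -> frozenset[str]:
    """Read a plain-text gene list (one symbol per line); whitespace stripped.

    Duplicate symbols are deduplicated with a warning; an empty list is fatal.
    """
    with open(path) as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    unique = frozenset(symbols)
    if not unique:
        raise ValueError(f"panel gene list {path} is empty")
    if len(unique) < len(symbols):
        logger.warning(
            "panel gene list %s: %d duplicate symbol(s) removed",
            path,
            len(symbols) - len(unique),
        )
    return unique
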