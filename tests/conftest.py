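import numpy as np
import pandas as pd
import pytest

from tmbcut.tmb_core import (
    MutationRecord,
    PanelDefinition,
    PipelineFilter,
    VariantClass,
)


@pytest.fixture
def toy_maf_file(tmp_path):
    """Write a small MAF-dialect TSV and return its path."""

    def _write(rows, name="toy.maf", extra_cols=True):
        cols = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
        df = pd.DataFrame(rows, columns=cols)
        if extra_cols:
            df["Center"] = "synthetic"
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write


@pytest.fixture
def simple_panel():
    return PanelDefinition(
        name="toy",
        genes=frozenset({"TP53", "KRAS", "EGFR"}),
        territory_mb=1.0,
        pipeline=PipelineFilter(
            counted_classes=frozenset(
                {
                    VariantClass.MISSENSE,
                    VariantClass.NONSENSE,
                    VariantClass.SPLICE_SITE,
                    VariantClass.FRAMESHIFT_INDEL,
                    VariantClass.INFRAME_INDEL,
                }
            )
        ),
    )


def make_mutation(sample="S1", gene="TP53", vc=VariantClass.MISSENSE):
    return MutationRecord(sample_id=sample, gene=gene, variant_class=vc)


@pytest.fixture
def survival_frame():
    """Small survival table with a strong planted TMB-high benefit."""
    rng = np.random.default_rng(7)
    n = 600
    tmb = rng.lognormal(np.log(6), 0.8, n)
    high = tmb >= 10
    lam = 0.06 * np.where(high, 0.4, 1.0)
    t = rng.exponential(1 / lam)
    censored = rng.random(n) < 0.2
    obs = np.where(censored, rng.uniform(0, t), t)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "os_months": obs,
            "os_event": (~censored).astype(int),
            "tmb": tmb,
            "cancer_type": rng.choice(["lung", "melanoma", "bladder"], n),
            "age": rng.normal(62, 10, n),
            "sex": rng.choice(["M", "F"], n),
            "panel_version": rng.choice(["v1", "v2"], n),
            "msi_status": rng.choice(["MSS", "MSI-H"], n, p=[0.9, 0.1]),
        }
    )
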