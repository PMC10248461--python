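"""TMB computation, MAF parsing and sample selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmbcut.tmb_core import (
    ClinicalRecord,
    MutationRecord,
    PanelDefinition,
    PipelineFilter,
    SampleType,
    VariantClass,
    classify_high,
    compute_tmb,
    read_maf,
    read_panel_genes,
    select_samples,
)

NONSYN = PipelineFilter(
    counted_classes=frozenset(
        {
            VariantClass.MISSENSE,
            VariantClass.NONSENSE,
            VariantClass.SPLICE_SITE,
            VariantClass.FRAMESHIFT_INDEL,
            VariantClass.INFRAME_INDEL,
        }
    )
)


class TestReadMaf:
    def test_standard_class_mapping(self, toy_maf_file):
        path = toy_maf_file(
            [
                ("S1", "TP53", "Missense_Mutation"),
                ("S1", "KRAS", "Silent"),
                ("S2", "EGFR", "Nonsense_Mutation"),
            ]
        )
        recs = read_maf(path)
        assert [r.variant_class for r in recs] == [
            VariantClass.MISSENSE,
            VariantClass.SILENT,
            VariantClass.NONSENSE,
        ]
        assert recs[0].sample_id == "S1" and recs[0].gene == "TP53"

    def test_unknown_class_maps_to_other(self, toy_maf_file, caplog):
        path = toy_maf_file([("S1", "TP53", "Weird_Call")])
        with caplog.at_level("WARNING"):
            recs = read_maf(path)
        assert recs[0].variant_class is VariantClass.OTHER
        assert "Weird_Call" in caplog.text

    def test_empty_file_returns_empty_list(self, toy_maf_file, caplog):
        path = toy_maf_file([])
        with caplog.at_level("WARNING"):
            assert read_maf(path) == []
        assert "no data rows" in caplog.text

    def test_missing_column_is_fatal_and_named(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("Tumor_Sample_Barcode\tHugo_Symbol\nS1\tTP53\n")
        with pytest.raises(ValueError, match="Variant_Classification"):
            read_maf(path)


class TestSelectSamples:
    @staticmethod
    def _rec(sid, pid, st_):
        return ClinicalRecord(
            sample_id=sid, patient_id=pid, cancer_type="lung", sample_type=st_
        )

    def test_primary_favored_over_metastatic(self):
        recs = [
            self._rec("S-met", "P1", SampleType.METASTATIC),
            self._rec("S-pri", "P1", SampleType.PRIMARY),
        ]
        kept = select_samples(recs)
        assert [r.sample_id for r in kept] == ["S-pri"]

    def test_metastatic_over_additional_metastatic(self):
        recs = [
            self._rec("S-add", "P1", SampleType.ADDITIONAL_METASTATIC),
            self._rec("S-met", "P1", SampleType.METASTATIC),
        ]
        assert select_samples(recs)[0].sample_id == "S-met"

    def test_single_sample_passthrough_and_tiebreak(self):
        recs = [
            self._rec("S2", "P1", SampleType.PRIMARY),
            self._rec("S1", "P1", SampleType.PRIMARY),
            self._rec("S9", "P2", SampleType.METASTATIC),
        ]
        kept = select_samples(recs)
        assert {r.sample_id for r in kept} == {"S1", "S9"}

    def test_idempotent_one_per_patient(self):
        rng = np.random.default_rng(0)
        types = list(SampleType)
        recs = [
            self._rec(f"S{i}", f"P{rng.integers(0, 20)}", types[rng.integers(0, 3)])
            for i in range(100)
        ]
        once = select_samples(recs)
        assert len(once) == len({r.patient_id for r in recs})
        assert select_samples(once) == once


class TestComputeTmb:
    def test_no_qualifying_mutations_gives_zero(self, simple_panel):
        out = compute_tmb([], simple_panel, sample_ids=["S1"])
        assert out[0].tmb == 0.0

    def test_hand_arithmetic_twelve_over_1p2(self):
        panel = PanelDefinition(
            name="p", genes=frozenset({"G"}), territory_mb=1.2, pipeline=NONSYN
        )
        muts = [
            MutationRecord("S1", "G", VariantClass.MISSENSE) for _ in range(12)
        ]
        out = compute_tmb(muts, panel)
        assert out[0].tmb == pytest.approx(10.0)

    def test_class_filter_counts_only_nonsynonymous(self, simple_panel):
        muts = [MutationRecord("S1", "TP53", VariantClass.MISSENSE)] * 5 + [
            MutationRecord("S1", "TP53", VariantClass.SILENT)
        ] * 3
        out = compute_tmb(muts, simple_panel)
        assert out[0].tmb == pytest.approx(5.0)

    def test_territory_scaling_is_exact_inverse(self, simple_panel):
        muts = [
            MutationRecord("S1", "TP53", VariantClass.MISSENSE),
            MutationRecord("S1", "KRAS", VariantClass.NONSENSE),
            MutationRecord("S2", "EGFR", VariantClass.MISSENSE),
        ]
        doubled = PanelDefinition(
            name="p2",
            genes=simple_panel.genes,
            territory_mb=2 * simple_panel.territory_mb,
            pipeline=simple_panel.pipeline,
        )
        a = {t.sample_id: t.tmb for t in compute_tmb(muts, simple_panel)}
        b = {t.sample_id: t.tmb for t in compute_tmb(muts, doubled)}
        for sid in a:
            assert b[sid] == pytest.approx(a[sid] / 2)

    def test_removing_gene_never_increases_tmb(self, simple_panel):
        rng = np.random.default_rng(1)
        genes = sorted(simple_panel.genes)
        muts = [
            MutationRecord(
                f"S{rng.integers(0, 5)}",
                genes[rng.integers(0, 3)],
                VariantClass.MISSENSE,
            )
            for _ in range(60)
        ]
        smaller = PanelDefinition(
            name="small",
            genes=simple_panel.genes - {"TP53"},
            territory_mb=simple_panel.territory_mb,
            pipeline=simple_panel.pipeline,
        )
        full = {t.sample_id: t.tmb for t in compute_tmb(muts, simple_panel)}
        part = {t.sample_id: t.tmb for t in compute_tmb(muts, smaller)}
        for sid, v in part.items():
            assert v <= full[sid]

    def test_panel_equal_to_universe_matches_wes(self):
        """A panel spanning the whole gene universe reproduces whole-exome
        TMB under the same filter — the equivalence the panel-concordance
        module relies on."""
        rng = np.random.default_rng(2)
        universe = [f"G{i}" for i in range(30)]
        muts = [
            MutationRecord(
                f"S{rng.integers(0, 8)}",
                universe[rng.integers(0, 30)],
                VariantClass.MISSENSE,
            )
            for _ in range(200)
        ]
        wes = PanelDefinition(
            name="wes", genes=frozenset(universe), territory_mb=3.0, pipeline=NONSYN
        )
        # brute-force per-sample count
        expected = {}
        for m in muts:
            expected[m.sample_id] = expected.get(m.sample_id, 0) + 1
        for t in compute_tmb(muts, wes):
            assert t.tmb == pytest.approx(expected[t.sample_id] / 3.0)

    def test_excluded_genes_are_not_counted(self):
        panel = PanelDefinition(
            name="p",
            genes=frozenset({"A", "B"}),
            territory_mb=1.0,
            pipeline=PipelineFilter(
                counted_classes=frozenset({VariantClass.MISSENSE}),
                excluded_genes=frozenset({"B"}),
            ),
        )
        muts = [
            MutationRecord("S1", "A", VariantClass.MISSENSE),
            MutationRecord("S1", "B", VariantClass.MISSENSE),
        ]
        assert compute_tmb(muts, panel)[0].tmb == pytest.approx(1.0)

    def test_nonpositive_territory_rejected(self):
        with pytest.raises(ValueError, match="territory"):
            PanelDefinition(name="bad", genes=frozenset({"A"}), territory_mb=0.0)


class TestClassifyHigh:
    @pytest.mark.parametrize(
        "tmb,cutoff,expected",
        [(10.0, 10.0, True), (9.999, 10.0, False), (0.0, 0.0, True), (5.0, 0.0, True)],
    )
    def test_boundary_inclusive(self, tmb, cutoff, expected):
        assert classify_high(tmb, cutoff) is expected

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify_high(1.0, -1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=8),
    territory=st.floats(min_value=0.1, max_value=50.0),
)
def test_tmb_nonnegative_and_scales_with_territory(counts, territory):
    """TMB is nonnegative and exactly inversely proportional to territory."""
    muts = [
        MutationRecord(f"S{i}", "G1", VariantClass.MISSENSE)
        for i, c in enumerate(counts)
        for _ in range(c)
    ]
    sample_ids = [f"S{i}" for i in range(len(counts))]
    p1 = PanelDefinition(
        name="a", genes=frozenset({"G1"}), territory_mb=territory, pipeline=NONSYN
    )
    p2 = PanelDefinition(
        name="b", genes=frozenset({"G1"}), territory_mb=2 * territory, pipeline=NONSYN
    )
    t1 = compute_tmb(muts, p1, sample_ids)
    t2 = compute_tmb(muts, p2, sample_ids)
    for a, b in zip(t1, t2):
        assert a.tmb >= 0
        assert a.tmb == pytest.approx(2 * b.tmb)


def test_read_panel_genes_dedupes_and_rejects_empty(tmp_path, caplog):
    p = tmp_path / "genes.txt"
    p.write_text("TP53\nKRAS\nTP53\n")
    with caplog.at_level("WARNING"):
        genes = read_panel_genes(p)
    assert genes == frozenset({"TP53", "KRAS"})
    assert "duplicate" in caplog.text
    empty = tmp_path / "empty.txt"
    empty.write_text("\n")
    with pytest.raises(ValueError):
        read_panel_genes(empty)
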