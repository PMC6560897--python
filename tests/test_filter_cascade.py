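"""Symbol normalization and the three-stage candidate filter cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lbd_bridge.concept_graph import IntermediateRecord
from lbd_bridge.deg_stage import union_deg_sets
from lbd_bridge.filter_cascade import (
    AmbiguityLexicon,
    TissueAtlas,
    ambiguity_filter,
    normalize_symbol,
    overlap_cims_degs,
    run_cascade,
    stage_survivor_counts,
    tissue_filter,
    tissue_pass,
)

FINAL_FOUR = {"GNB3", "CNR1", "MTHFR", "NCAM1"}
HEART_FAILERS = {"LCAT", "CD4", "SERPINA1", "IL6", "PPBP"}


def record(gene, fxy=1, fyz=1):
    return IntermediateRecord(gene, f"G:{gene}", fxy, {"Z": fyz}, fyz, fxy * fyz)


class TestNormalizeSymbol:
    @pytest.mark.parametrize(
        "raw,expected",
        [("IL-6", "IL6"), ("ncam1", "NCAM1"), ("HLA-B", "HLAB"), (" Gnb 3. ", "GNB3")],
    )
    def test_examples(self, raw, expected):
        assert normalize_symbol(raw) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.text(min_size=1).filter(lambda s: s.strip() and s.strip(" -.")))
    def test_idempotent(self, raw):
        once = normalize_symbol(raw)
        assert normalize_symbol(once) == once

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_symbol("  ")


class TestOverlap:
    def test_disjoint_and_identity(self):
        assert overlap_cims_degs({"A"}, {"B"}) == set()
        assert overlap_cims_degs({"A", "B"}, {"A", "B"}) == {"A", "B"}

    def test_reference_cims_cross_degs_is_23(self, ref):
        deg_union = union_deg_sets(ref.deg_map.values())
        assert len(overlap_cims_degs(set(ref.cim_list), deg_union)) == 23


class TestAmbiguityFilter:
    def test_empty_lexicon_keeps_all(self):
        kept, removed = ambiguity_filter({"A", "B"}, AmbiguityLexicon({}))
        assert kept == {"A", "B"} and removed == []

    def test_reference_drop_list_leaves_nine(self, ref):
        candidates = {r.gene_symbol for r in ref.table2_records}
        kept, removed = ambiguity_filter(candidates, ref.drop_lexicon)
        assert len(kept) == 9
        assert len(removed) == 14
        assert kept == FINAL_FOUR | HEART_FAILERS

    def test_keep_override_beats_lexicon(self):
        lexicon = AmbiguityLexicon({"STAR": "common word"})
        kept, removed = ambiguity_filter({"STAR", "CNR1"}, lexicon, {"STAR": "keep"})
        assert kept == {"STAR", "CNR1"} and removed == []

    def test_drop_override_and_partition(self):
        kept, removed = ambiguity_filter({"A", "B"}, AmbiguityLexicon({}), {"B": "drop"})
        assert kept == {"A"}
        assert [g for g, _ in removed] == ["B"]

    def test_unknown_override_warns_not_fatal(self, caplog):
        with caplog.at_level("WARNING"):
            kept, _ = ambiguity_filter({"A"}, AmbiguityLexicon({}), {"GHOST": "drop"})
        assert kept == {"A"} and "GHOST" in caplog.text


def toy_atlas():
    values = pd.DataFrame(
        {
            "heart_a": [0.1, 5.0, 3.0],
            "brain_a": [8.0, 5.0, 3.0],
            "other_a": [2.0, 5.0, 3.0],
        },
        index=["BRAINONLY", "UNIFORM", "FLAT"],
    )
    groups = {"heart_a": "heart", "brain_a": "brain", "other_a": "other"}
    return TissueAtlas(values=values, tissue_groups=groups)


class TestTissuePass:
    def test_brain_only_gene_fails_heart(self):
        ok, value = tissue_pass("BRAINONLY", toy_atlas(), "heart", relative_floor=0.5)
        assert not ok and value == pytest.approx(0.1)

    def test_uniform_gene_passes_everywhere(self):
        atlas = toy_atlas()
        for group in ("heart", "brain", "other"):
            ok, _ = tissue_pass("UNIFORM", atlas, group, relative_floor=1.0)
            assert ok

    def test_absolute_floor(self):
        ok, _ = tissue_pass("FLAT", toy_atlas(), "heart", relative_floor=0.0,
                            absolute_floor=4.0)
        assert not ok

    def test_missing_gene_fails_closed(self, caplog):
        with caplog.at_level("WARNING"):
            ok, value = tissue_pass("GHOST", toy_atlas(), "heart")
        assert not ok and np.isnan(value)
        with pytest.raises(KeyError):
            tissue_pass("GHOST", toy_atlas(), "heart", missing_fails=False)

    def test_reference_atlas_reproduces_published_verdicts(self, ref):
        for gene in FINAL_FOUR:
            for group in ("heart", "brain"):
                ok, _ = tissue_pass(gene, ref.atlas, group)
                assert ok, (gene, group)
        for gene in HEART_FAILERS:
            ok, _ = tissue_pass(gene, ref.atlas, "heart")
            assert not ok, gene


class TestTissueFilter:
    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            tissue_filter({"UNIFORM"}, toy_atlas(), [])

    def test_reference_nine_to_four(self, ref):
        kept, removed = tissue_filter(FINAL_FOUR | HEART_FAILERS, ref.atlas,
                                      ["heart", "brain"])
        assert kept == FINAL_FOUR
        assert {g for g, _ in removed} == HEART_FAILERS
        assert all(group == "heart" for _, group in removed)

    def test_adding_required_groups_shrinks(self, ref):
        genes = FINAL_FOUR | HEART_FAILERS
        heart_only, _ = tissue_filter(genes, ref.atlas, ["heart"])
        both, _ = tissue_filter(genes, ref.atlas, ["heart", "brain"])
        assert both <= heart_only


class TestRunCascade:
    def test_empty_input(self, ref):
        assert run_cascade([], set(), ref.drop_lexicon, None, ref.atlas,
                           ["heart", "brain"]) == []

    def test_reference_cascade_counts(self, ref):
        deg_union = union_deg_sets(ref.deg_map.values())
        reports = run_cascade(ref.table2_records, deg_union, ref.drop_lexicon, None,
                              ref.atlas, ["heart", "brain"],
                              deg_sets_by_dataset=ref.deg_map)
        counts = stage_survivor_counts(reports)
        assert counts == {"discovery": 23, "deg_overlap": 23, "ambiguity": 9, "tissue": 4}
        assert {r.gene for r in reports if r.final_status == "pass"} == FINAL_FOUR
        # stages after a failure are not evaluated
        for r in reports:
            if r.ambiguity.status == "fail":
                assert r.tissue.status == "not-evaluated"
        # DEG passes name contributing series
        il6 = next(r for r in reports if r.gene == "IL6")
        assert "GSE83500" in il6.deg_overlap.detail

    def test_monotonicity_and_partition(self, ref):
        deg_union = union_deg_sets(ref.deg_map.values())
        reports = run_cascade(ref.table2_records, deg_union, ref.drop_lexicon, None,
                              ref.atlas, ["heart", "brain"])
        counts = stage_survivor_counts(reports)
        assert counts["discovery"] >= counts["deg_overlap"] >= counts["ambiguity"] >= counts["tissue"]
        for r in reports:
            assert (r.final_status == "pass") == (r.failing_stage is None)

    def test_order_invariance(self, ref):
        deg_union = union_deg_sets(ref.deg_map.values())
        fwd = run_cascade(ref.table2_records, deg_union, ref.drop_lexicon, None,
                          ref.atlas, ["heart", "brain"])
        rev = run_cascade(list(reversed(ref.table2_records)), deg_union,
                          ref.drop_lexicon, None, ref.atlas, ["heart", "brain"])
        assert [(r.gene, r.final_status, r.failing_stage) for r in fwd] == [
            (r.gene, r.final_status, r.failing_stage) for r in rev
        ]

    def test_filters_only_remove(self, ref):
        genes = {r.gene_symbol for r in ref.table2_records}
        reports = run_cascade(ref.table2_records, union_deg_sets(ref.deg_map.values()),
                              ref.drop_lexicon, None, ref.atlas, ["heart", "brain"])
        assert {r.gene for r in reports} == genes
        assert {r.gene for r in reports if r.final_status == "pass"} <= genes
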