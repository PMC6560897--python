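"""Differential-expression calling: t-tests, BH, ranking, top-N, mapping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lbd_bridge.deg_stage import (
    ExpressionDataset,
    bh_adjust,
    call_degs,
    map_probes_to_genes,
    rank_probes,
    select_top,
    split_aliases,
    two_sample_t,
    union_deg_sets,
)
from lbd_bridge.synthetic_data import ExpressionSpec, generate_expression

from conftest import bh_step_up_oracle


class TestTwoSampleT:
    def test_identical_vectors(self):
        t, _, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_equal_means_equal_variance(self):
        t, _, _ = two_sample_t([1.0, 2.0, 3.0], [3.0, 1.0, 2.0], variant="pooled")
        assert t == pytest.approx(0.0)

    def test_pooled_matches_hand_formula(self):
        # mean diff 4, per-group variance 1 -> pooled sd 1,
        # se = sqrt(1/3 + 1/3), t = 4 / 0.81650 = 4.8990, df = 4
        t, df, p = two_sample_t([5.0, 6.0, 7.0], [1.0, 2.0, 3.0], variant="pooled")
        assert t == pytest.approx(4 / math.sqrt(2 / 3), rel=1e-12)
        assert t == pytest.approx(4.899, abs=5e-4)
        assert df == 4
        assert 0 < p < 0.01

    def test_welch_satterthwaite_df(self):
        # hand Satterthwaite: s1^2=1 (n=3), s2^2=16 (n=4)
        case, control = [5.0, 6.0, 7.0], [0.0, 4.0, 8.0, 4.0]
        s1, n1 = 1.0, 3
        s2, n2 = np.var(control, ddof=1), 4
        expect_df = (s1 / n1 + s2 / n2) ** 2 / (
            (s1 / n1) ** 2 / (n1 - 1) + (s2 / n2) ** 2 / (n2 - 1)
        )
        _, df, _ = two_sample_t(case, control, variant="welch")
        assert df == pytest.approx(expect_df, rel=1e-12)

    def test_zero_variance_equal_means_defined(self):
        t, _, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_step_up_example(self):
        # step-up: min over j>=i of p_(j) * n / j = (0.03, 0.03, 0.03)
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 21))
        adjusted = bh_adjust(p)
        assert adjusted == pytest.approx(bh_step_up_oracle(p))
        assert (adjusted >= p - 1e-12).all() and (adjusted <= 1.0 + 1e-12).all()

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12), st.randoms())
    def test_permutation_equivariance(self, p, rand):
        order = list(range(len(p)))
        rand.shuffle(order)
        base = bh_adjust(p)
        shuffled = bh_adjust([p[i] for i in order])
        assert shuffled == pytest.approx([base[i] for i in order])


def _dataset_from_values(values, n_case, n_control, platform=None):
    probes = [f"P{i:03d}" for i in range(values.shape[0])]
    samples = [f"C{i}" for i in range(n_case)] + [f"N{i}" for i in range(n_control)]
    groups = {s: ("case" if s.startswith("C") else "control") for s in samples}
    return ExpressionDataset(
        dataset_id="T",
        matrix=pd.DataFrame(values, index=probes, columns=samples),
        sample_groups=groups,
        platform=platform or {p: f"GENE{i}" for i, p in enumerate(probes)},
    )


class TestRankProbes:
    def test_strongest_shift_ranks_first(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(30, 12))
        values[7, :6] += 8.0  # one strongly shifted probe
        table = rank_probes(_dataset_from_values(values, 6, 6))
        assert table.iloc[0]["probe_id"] == "P007"
        assert table.iloc[0]["rank"] == 1
        assert table["p_value"].is_monotonic_increasing
        assert (table["adjusted_p"] >= table["p_value"] - 1e-12).all()

    def test_null_type_one_error_rate(self):
        dataset = generate_expression(ExpressionSpec(n_probes=1000, seed=11))
        table = rank_probes(dataset)
        frac = (table["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_nonfinite_probe_excluded_not_fatal(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 8))
        values[2, 0] = np.inf
        table = rank_probes(_dataset_from_values(values, 4, 4))
        assert len(table) == 4 and "P002" not in set(table["probe_id"])

    def test_planted_probes_recovered_in_top_ranks(self):
        genes = [(f"DEGENE{i:02d}", 2.0) for i in range(20)]
        dataset = generate_expression(
            ExpressionSpec(n_probes=1000, planted_de_genes=genes, seed=7)
        )
        table = rank_probes(dataset)
        top50 = set(table.head(50)["probe_id"])
        assert {f"DEGENE{i:02d}_p1" for i in range(20)} <= top50


class TestSelectTop:
    def test_whole_table(self):
        table = pd.DataFrame({"probe_id": ["a", "b"], "p_value": [0.1, 0.2]})
        assert select_top(table, 2) == {"a", "b"}

    def test_boundary_tie_kept(self):
        table = pd.DataFrame(
            {"probe_id": list("abcd"), "p_value": [0.01, 0.02, 0.02, 0.5]}
        )
        assert select_top(table, 2) == {"a", "b", "c"}

    def test_exact_count_without_ties(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(1000)], "p_value": np.sort(rng.random(1000))}
        )
        assert len(select_top(table, 250)) == 250

    def test_monotone_in_n(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(40)], "p_value": np.sort(rng.random(40))}
        )
        for n1, n2 in [(5, 10), (10, 30), (1, 40)]:
            assert select_top(table, n1) <= select_top(table, n2)

    def test_oversized_n_returns_all(self):
        table = pd.DataFrame({"probe_id": list("abcde"), "p_value": [0.1] * 5})
        assert select_top(table, 250) == set("abcde")


class TestGeneMapping:
    def test_unannotated_probes_contribute_nothing(self):
        assert map_probes_to_genes({"p1", "p2"}, {"p1": "", "p2": "---"}) == set()

    def test_symbol_normalization(self):
        assert map_probes_to_genes({"p1"}, {"p1": "IL-6"}) == {"IL6"}

    def test_aliases_and_deduplication(self):
        platform = {"p1": "GNB3 /// GNB3v2", "p2": "GNB3", "p3": "A;B, C"}
        assert map_probes_to_genes({"p1", "p2", "p3"}, platform) == {
            "GNB3", "GNB3V2", "A", "B", "C",
        }

    def test_missing_probe_skipped(self):
        assert map_probes_to_genes({"ghost", "p1"}, {"p1": "CNR1"}) == {"CNR1"}

    def test_split_aliases(self):
        assert split_aliases("A /// B;C, D") == ["A", "B", "C", "D"]


class TestCallDegs:
    def test_planted_genes_all_recovered(self):
        genes = [(f"DEGENE{i:02d}", 2.0) for i in range(20)]
        dataset = generate_expression(
            ExpressionSpec(n_probes=1000, planted_de_genes=genes, seed=7)
        )
        _, called = call_degs(dataset, n_top=5 * 20)
        assert {g for g, _ in genes} <= called

    def test_small_table_clamped(self):
        rng = np.random.default_rng(2)
        dataset = _dataset_from_values(rng.normal(size=(5, 8)), 4, 4)
        table, genes = call_degs(dataset, n_top=250)
        assert len(table) == 5 and len(genes) == 5


class TestUnionDegSets:
    def test_single_set_identity(self):
        assert union_deg_sets([{"GNB3"}]) == {"GNB3"}

    def test_disjoint_sizes_add(self):
        assert len(union_deg_sets([{"A", "B", "C"}, {"D", "E", "F", "G"}])) == 7

    def test_normalizes_before_union(self):
        assert union_deg_sets([{"IL-6"}, {"il6"}]) == {"IL6"}

    def test_reference_mi_union_is_seven(self, ref):
        mi_sets = [ref.deg_map[s] for s in ref.mi_series]
        assert len(union_deg_sets(mi_sets)) == 7
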