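"""Switch-gene calling, weighted 3'UTR lengths, shift tests, overlaps."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from apakit.apa_analysis import (
    ShiftCall,
    _exact_kx2_pvalue,
    detect_switch_genes,
    length_expression_correlation,
    overlap_summary,
    shift_summary,
    utr_shift_test,
    weighted_utr_length,
)
from apakit.quant import PAUMatrix


def _pau_matrix(genes):
    """Build a PAUMatrix from {gene: (pau_a, pau_b, total_a, total_b)}.

    pau_a / pau_b are per-PAC usage lists; PAC ids are g:p0, g:p1, ...
    """
    idx, pa, pb = [], [], []
    tot_a, tot_b = {}, {}
    for g, (pau_a, pau_b, ta, tb) in genes.items():
        for i, (x, y) in enumerate(zip(pau_a, pau_b)):
            idx.append((g, f"{g}:p{i}"))
            pa.append(x)
            pb.append(y)
        tot_a[g], tot_b[g] = ta, tb
    index = pd.MultiIndex.from_tuples(idx, names=["gene_id", "pac_id"])
    cond = pd.DataFrame({"A": pa, "B": pb}, index=index)
    totals = pd.DataFrame({"A": tot_a, "B": tot_b}).rename_axis("gene_id")
    return PAUMatrix(
        pau_replicate=cond.copy(),
        pau_condition=cond,
        gene_totals_replicate=totals.copy(),
        gene_totals_condition=totals,
        replicate_map={"A": ["a1"], "B": ["b1"]},
    )


class TestSwitchCaller:
    def test_gene_passing_all_three_criteria_is_reported(self):
        pau = _pau_matrix({"g1": ([0.8, 0.2], [0.6, 0.4], 50, 60)})
        [ev] = detect_switch_genes(pau, "A", "B", {"g1:p1"})
        assert ev.is_switch
        assert abs(ev.delta_pau) == pytest.approx(0.2)

    def test_small_shift_fails_delta_criterion(self):
        pau = _pau_matrix({"g1": ([0.55, 0.45], [0.5, 0.5], 50, 60)})
        assert detect_switch_genes(pau, "A", "B", {"g1:p0"}) == []

    def test_no_de_pac_fails_third_criterion(self):
        pau = _pau_matrix({"g1": ([0.8, 0.2], [0.5, 0.5], 50, 60)})
        assert detect_switch_genes(pau, "A", "B", set()) == []

    def test_low_reads_fail_first_criterion_in_either_condition(self):
        pau = _pau_matrix({"g1": ([0.8, 0.2], [0.5, 0.5], 50, 10)})
        assert detect_switch_genes(pau, "A", "B", {"g1:p0"}) == []
        pau = _pau_matrix({"g1": ([0.8, 0.2], [0.5, 0.5], 11, 11)})
        assert len(detect_switch_genes(pau, "A", "B", {"g1:p0"})) == 1

    def test_swapping_conditions_negates_delta(self):
        pau = _pau_matrix({"g1": ([0.8, 0.2], [0.5, 0.5], 50, 60)})
        [fwd] = detect_switch_genes(pau, "A", "B", {"g1:p0"})
        [rev] = detect_switch_genes(pau, "B", "A", {"g1:p0"})
        assert fwd.delta_pau == pytest.approx(-rev.delta_pau)

    def test_missing_de_set_is_error(self):
        pau = _pau_matrix({"g1": ([1.0], [1.0], 50, 60)})
        with pytest.raises(ValueError):
            detect_switch_genes(pau, "A", "B", None)

    def test_matches_brute_force_recheck_of_the_three_criteria(self):
        rng = np.random.default_rng(17)
        genes = {}
        for i in range(150):
            k = int(rng.integers(1, 4))
            a = rng.dirichlet([2.0] * k)
            b = rng.dirichlet([2.0] * k)
            genes[f"g{i}"] = (
                a.tolist(), b.tolist(),
                int(rng.integers(0, 40)), int(rng.integers(0, 40)),
            )
        pau = _pau_matrix(genes)
        all_pacs = [pid for _, pid in pau.pau_condition.index]
        de_set = set(rng.choice(all_pacs, size=60, replace=False).tolist())

        called = {e.gene_id for e in detect_switch_genes(pau, "A", "B", de_set)}

        expected = set()
        for g, (pa, pb, ta, tb) in genes.items():
            crit1 = ta > 10 and tb > 10
            crit2 = max(abs(x - y) for x, y in zip(pa, pb)) >= 0.1
            crit3 = any(f"{g}:p{i}" in de_set for i in range(len(pa)))
            if crit1 and crit2 and crit3:
                expected.add(g)
        assert called == expected


class TestWeightedLength:
    def test_printed_two_site_formula(self):
        assert weighted_utr_length([100, 200], [3, 1]) == pytest.approx(125.0)

    def test_equal_weights_give_midpoint(self):
        assert weighted_utr_length([100, 200], [1, 1]) == pytest.approx(150.0)

    def test_three_site_generalization(self):
        assert weighted_utr_length([50, 100, 200], [1, 1, 2]) == pytest.approx(137.5)

    def test_zero_total_count_is_undefined(self):
        assert weighted_utr_length([100, 200], [0, 0]) is None

    @given(
        lengths=st.lists(st.integers(1, 1000), min_size=1, max_size=6),
        shift=st.integers(-100, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_translation_equivariant_and_bounded(self, lengths, shift):
        counts = [(i % 3) + 1 for i in range(len(lengths))]
        w = weighted_utr_length(lengths, counts)
        assert min(lengths) <= w <= max(lengths)
        w2 = weighted_utr_length([x + shift for x in lengths], counts)
        assert w2 == pytest.approx(w + shift)


class TestCompositionTest:
    def test_strong_proximal_to_distal_shift_is_lengthened(self):
        res = utr_shift_test("g", [100, 300], [90, 10], [50, 50])
        assert res.p_value < 0.01
        assert res.call is ShiftCall.LENGTHENED
        assert res.weighted_len_b > res.weighted_len_a

    def test_identical_compositions_are_ns(self):
        res = utr_shift_test("g", [100, 300], [40, 60], [40, 60])
        assert res.p_value == pytest.approx(1.0)
        assert res.call is ShiftCall.NS

    def test_tiny_counts_are_ns(self):
        res = utr_shift_test("g", [100, 300], [3, 2], [2, 3])
        assert res.p_value > 0.01
        assert res.call is ShiftCall.NS

    def test_single_pac_gene_flagged_ns(self):
        res = utr_shift_test("g", [100], [50], [60])
        assert res.call is ShiftCall.NS
        assert "fewer than 2" in res.reason

    def test_zero_counts_in_one_condition_flagged(self):
        res = utr_shift_test("g", [100, 300], [0, 0], [50, 50])
        assert res.call is ShiftCall.NS
        assert res.weighted_len_a is None

    def test_swapping_conditions_swaps_the_call(self):
        fwd = utr_shift_test("g", [100, 300], [90, 10], [50, 50])
        rev = utr_shift_test("g", [100, 300], [50, 50], [90, 10])
        assert fwd.call is ShiftCall.LENGTHENED
        assert rev.call is ShiftCall.SHORTENED
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_fisher_pvalues_match_hypergeometric_enumeration(self):
        for a in range(0, 9):
            for b in range(0, 9):
                for c in range(0, 9):
                    for d in range(0, 9):
                        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                            continue
                        _, p = stats.fisher_exact([[a, b], [c, d]])
                        assert p == pytest.approx(
                            _fisher_oracle(a, b, c, d), abs=1e-9
                        ), (a, b, c, d)

    def test_exact_kx2_fallback_agrees_with_fisher_at_k2(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            _, p_fisher = stats.fisher_exact(t)
            assert _exact_kx2_pvalue(t) == pytest.approx(p_fisher, abs=1e-9)

    def test_three_site_shift_detected(self):
        res = utr_shift_test(
            "g", [50, 150, 300], [200, 30, 10], [60, 40, 140]
        )
        assert res.p_value < 0.01
        assert res.call is ShiftCall.LENGTHENED


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestSummaries:
    def _res(self, gene, la, lb, p, call):
        from apakit.apa_analysis import UTRShiftResult

        return UTRShiftResult(gene, la, lb, p, call)

    def test_ratio_five_lengthened_to_one_shortened(self):
        rs = [self._res(f"g{i}", 100, 150, 0.001, ShiftCall.LENGTHENED) for i in range(1)]
        rs += [self._res(f"s{i}", 150, 100, 0.001, ShiftCall.SHORTENED) for i in range(5)]
        out = shift_summary(rs)
        assert out["proximal_to_distal_ratio"] == pytest.approx(5.0)

    def test_no_significant_genes_flagged_empty(self):
        out = shift_summary([self._res("g", 100, 110, 0.5, ShiftCall.NS)])
        assert out["median_delta_lengthened_nt"] is None
        assert out["median_delta_shortened_nt"] is None

    def test_median_deltas_are_hand_medians(self):
        deltas = [10, 30, 50]
        rs = [
            self._res(f"g{i}", 100, 100 + d, 0.001, ShiftCall.LENGTHENED)
            for i, d in enumerate(deltas)
        ]
        assert shift_summary(rs)["median_delta_lengthened_nt"] == pytest.approx(30)

    def test_overlap_identical_sets(self):
        out = overlap_summary({"a", "b"}, {"a", "b"})
        assert out["pct_a_in_b"] == out["pct_b_in_a"] == 100

    def test_overlap_disjoint_sets(self):
        out = overlap_summary({"a"}, {"b"})
        assert out["pct_a_in_b"] == 0 and out["intersection"] == 0

    def test_overlap_partial(self):
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(4, 20)}
        out = overlap_summary(a, b)
        assert out["intersection"] == 6
        assert out["pct_a_in_b"] == 60


class TestLengthExpressionCorrelation:
    def test_constant_lfc_gives_zero_slope(self):
        dl = {f"g{i}": float(i) for i in range(10)}
        lfc = {f"g{i}": 1.5 for i in range(10)}
        out = length_expression_correlation(dl, lfc)
        assert out["degenerate"]
        assert out["slope"] == 0.0

    def test_perfect_linear_relation(self):
        dl = {f"g{i}": float(i) for i in range(10)}
        lfc = {f"g{i}": 2.0 * i - 3 for i in range(10)}
        out = length_expression_correlation(dl, lfc)
        assert abs(out["pearson_r"]) == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_independent_draws_show_no_correlation(self):
        rng = np.random.default_rng(2024)
        dl = {f"g{i}": float(x) for i, x in enumerate(rng.normal(0, 50, 500))}
        lfc = {f"g{i}": float(x) for i, x in enumerate(rng.normal(0, 1, 500))}
        out = length_expression_correlation(dl, lfc)
        assert abs(out["spearman_rho"]) < 0.1
        assert abs(out["slope"]) < 0.01

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValueError):
            length_expression_correlation({"g1": 1.0}, {"g1": 0.5})
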