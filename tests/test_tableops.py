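"""The interaction algebra: nested sorting, smart sort, selection, filters, coverage."""

import numpy as np
import pytest

from paramlens import context_selection, domain_coverage, filter_interval, multi_sort, smart_sort
from paramlens.tableops import aggregate_correlations

from conftest import make_table, random_table


def lexicographic_oracle(table, keys):
    """Brute-force nested sort: full key tuple plus record_id tiebreak."""
    return tuple(
        sorted(
            range(len(table.records)),
            key=lambda i: tuple(table.records[i].value(k) for k in keys)
            + (table.records[i].record_id,),
        )
    )


class TestMultiSort:
    def test_single_key_with_record_id_ties(self):
        t = make_table({"p": [3.0, 1.0, 2.0, 1.0]}, {"m": [0.0] * 4})
        assert multi_sort(t, "p").ordering == (1, 3, 2, 0)

    def test_sorting_on_constant_column_is_stable(self):
        t = make_table({"p": [1.0, 1.0, 1.0]}, {"m": [5.0, 4.0, 3.0]})
        assert multi_sort(t, "p").ordering == t.ordering

    def test_nested_sort_reorders_only_within_bins(self):
        # sort on p2 then p1 yields the nested step pattern
        t = make_table({"p1": [2.0, 2.0, 1.0, 1.0], "p2": [2.0, 1.0, 2.0, 1.0]}, {"m": [0.0] * 4})
        t = multi_sort(multi_sort(t, "p2"), "p1")
        values = [(t.records[i].value("p2"), t.records[i].value("p1")) for i in t.ordering]
        assert values == [(1.0, 1.0), (1.0, 2.0), (2.0, 1.0), (2.0, 2.0)]

    def test_unknown_column_and_duplicate_key_rejected(self):
        t = make_table({"p": [1.0, 2.0]}, {"m": [0.0, 0.0]})
        with pytest.raises(KeyError):
            multi_sort(t, "nope")
        with pytest.raises(ValueError):
            multi_sort(multi_sort(t, "p"), "p")

    def test_matches_lexicographic_oracle_on_random_tables(self):
        rng = np.random.default_rng(101)
        for _ in range(60):
            t = random_table(rng)
            keys = list(rng.permutation(t.columns))[: int(rng.integers(1, 3))]
            sorted_t = t
            for k in keys:
                sorted_t = multi_sort(sorted_t, k)
            assert sorted_t.ordering == lexicographic_oracle(t, keys)

    def test_later_key_orders_within_contiguous_bins_of_earlier_key(self):
        rng = np.random.default_rng(55)
        for _ in range(20):
            t = random_table(rng, max_rows=60)
            a, b = t.columns[0], t.columns[-1]
            if a == b:
                continue
            sorted_t = multi_sort(multi_sort(t, a), b)
            ordered_a = [t.records[i].value(a) for i in sorted_t.ordering]
            assert ordered_a == sorted(ordered_a)  # bins of a contiguous
            # within each bin of a, values of b ascend
            start = 0
            for end in range(1, len(ordered_a) + 1):
                if end == len(ordered_a) or ordered_a[end] != ordered_a[start]:
                    bin_b = [t.records[i].value(b) for i in sorted_t.ordering[start:end]]
                    assert bin_b == sorted(bin_b)
                    start = end


class TestSmartSort:
    def test_exact_linear_measure_selects_that_parameter(self):
        # m = 2*p2 exactly; p1 is noise -> smart sort must identify p2
        rng = np.random.default_rng(1)
        p1 = list(rng.normal(size=30))
        p2 = list(rng.normal(size=30))
        t = make_table({"p1": p1, "p2": p2}, {"m": [2 * v for v in p2]})
        chosen, sorted_t = smart_sort(t)
        assert chosen == "p2"
        assert sorted_t.sort_keys == ("p2",)
        assert sorted_t.ordering == lexicographic_oracle(t, ["p2"])

    def test_single_parameter_chosen_regardless_of_measures(self):
        t = make_table({"p": [1.0, 2.0, 3.0]}, {"m": [0.0, 0.0, 0.0]})
        assert smart_sort(t)[0] == "p"

    def test_all_constant_measures_tie_break_to_leftmost_parameter(self):
        t = make_table({"pa": [1.0, 2.0], "pb": [3.0, 4.0]}, {"m": [5.0, 5.0]})
        scores = aggregate_correlations(t)
        assert scores == {"pa": 0.0, "pb": 0.0}
        assert smart_sort(t)[0] == "pa"

    def test_chosen_matches_brute_force_mean_abs_pearson(self):
        rng = np.random.default_rng(202)
        for _ in range(40):
            t = random_table(rng, max_rows=80)
            scores = {}
            vis = sorted(t.visible)
            for p in t.param_columns:
                rs = []
                pv = t.column_values(p)[vis]
                for m in t.measure_columns:
                    mv = t.column_values(m)[vis]
                    if np.ptp(pv) == 0 or np.ptp(mv) == 0:
                        rs.append(0.0)
                    else:
                        rs.append(abs(np.corrcoef(pv, mv)[0, 1]))
                scores[p] = float(np.mean(rs))
            expected = max(t.param_columns, key=lambda p: (scores[p], -t.param_columns.index(p)))
            chosen, _ = smart_sort(t)
            assert chosen == expected
            assert aggregate_correlations(t)[chosen] == pytest.approx(scores[chosen])

    def test_too_few_visible_records_rejected(self):
        t = make_table({"p": [1.0, 2.0]}, {"m": [1.0, 2.0]})
        t = filter_interval(t, "p", 0.0, 1.5)
        with pytest.raises(ValueError):
            smart_sort(t)

    def test_variance_weighted_variant_prefers_high_variance_measures(self):
        # m_big tracks p1 and has large variance; m_small tracks p2 weakly scaled
        p1 = [float(i) for i in range(10)]
        p2 = [float((i * 7) % 10) for i in range(10)]
        t = make_table(
            {"p1": p1, "p2": p2},
            {"m_big": [100.0 * v for v in p1], "m_small": [0.001 * v for v in p2]},
        )
        chosen, _ = smart_sort(t, method="variance_weighted")
        assert chosen == "p1"


class TestContextSelection:
    def test_distinct_neighbours_give_singleton_run(self):
        t = make_table({"p": [1.0, 2.0, 3.0]}, {"m": [0.0] * 3})
        assert context_selection(t, 1, "p") == (1,)

    def test_maximal_run_of_equal_values(self):
        t = make_table({"p": [1.0, 1.0, 2.0, 2.0, 2.0, 3.0]}, {"m": [0.0] * 6})
        assert context_selection(t, 3, "p") == (2, 3, 4)

    def test_run_at_top_of_table_starts_at_first_row(self):
        t = make_table({"p": [5.0, 5.0, 1.0]}, {"m": [0.0] * 3})
        assert context_selection(t, 0, "p") == (0, 1)

    def test_hidden_row_rejected(self):
        t = make_table({"p": [1.0, 2.0]}, {"m": [0.0, 0.0]})
        t = filter_interval(t, "p", 1.5, 3.0)
        with pytest.raises(ValueError):
            context_selection(t, 0, "p")

    def test_matches_maximal_run_oracle_on_random_tables(self):
        rng = np.random.default_rng(303)
        for _ in range(40):
            t = random_table(rng, max_rows=60)
            t = multi_sort(t, t.columns[int(rng.integers(len(t.columns)))])
            col = t.columns[int(rng.integers(len(t.columns)))]
            order = t.visible_ordering()
            pos = int(rng.integers(len(order)))
            row = order[pos]
            run = context_selection(t, row, col)
            # oracle: scan outwards from pos over equal values
            target = t.records[row].value(col)
            lo = pos
            while lo > 0 and t.records[order[lo - 1]].value(col) == target:
                lo -= 1
            hi = pos
            while hi + 1 < len(order) and t.records[order[hi + 1]].value(col) == target:
                hi += 1
            assert run == order[lo : hi + 1]
            # endpoints' neighbours (if any) differ in the cursor column
            if lo > 0:
                assert t.records[order[lo - 1]].value(col) != target
            if hi + 1 < len(order):
                assert t.records[order[hi + 1]].value(col) != target


class TestFilterInterval:
    def test_full_domain_interval_is_noop(self):
        t = make_table({"p": [0.0, 0.5, 1.0]}, {"m": [0.0] * 3})
        assert filter_interval(t, "p", 0.0, 1.0).visible == t.visible

    def test_inclusive_bounds(self):
        t = make_table({"p": [0.0, 0.25, 0.5, 0.75, 1.0]}, {"m": [0.0] * 5})
        assert filter_interval(t, "p", 0.25, 0.75).visible == {1, 2, 3}

    def test_successive_filters_intersect(self):
        t = make_table({"p": [0.0, 1.0, 2.0, 3.0]}, {"m": [3.0, 2.0, 1.0, 0.0]})
        t2 = filter_interval(filter_interval(t, "p", 1.0, 3.0), "m", 1.0, 3.0)
        assert t2.visible == {1, 2}

    def test_filter_prunes_selection_and_keeps_ordering(self):
        t = make_table({"p": [3.0, 1.0, 2.0]}, {"m": [0.0] * 3})
        t = multi_sort(t, "p")
        from paramlens.tableops import select

        t = select(t, (1, 2, 0))
        t2 = filter_interval(t, "p", 1.5, 3.5)
        assert t2.ordering == t.ordering
        assert t2.selection == (2, 0)

    def test_invalid_interval_rejected(self):
        t = make_table({"p": [0.0]}, {"m": [0.0]})
        with pytest.raises(ValueError):
            filter_interval(t, "p", 1.0, 0.0)

    def test_filter_and_sort_commute(self):
        rng = np.random.default_rng(404)
        for _ in range(20):
            t = random_table(rng, max_rows=50)
            col = t.columns[0]
            key = t.columns[-1]
            lo, hi = 1.0, 3.0
            a = filter_interval(multi_sort(t, key), col, lo, hi)
            b = multi_sort(filter_interval(t, col, lo, hi), key)
            assert a.visible == b.visible
            assert a.visible_ordering() == b.visible_ordering()


class TestDomainCoverage:
    def test_all_rows_cover_full_domain(self):
        t = make_table({"p": [float(i) for i in range(101)]}, {"m": [0.0] * 101})
        strips = domain_coverage(t, tuple(range(101)))
        p_strip = strips[0]
        assert p_strip.covered == ((0.0, 100.0),)
        # constant measure column: degenerate domain fully covered
        assert strips[1].covered == ((0.0, 0.0),)

    def test_single_value_widens_to_one_bin(self):
        t = make_table({"p": [0.0, 5.0, 10.0]}, {"m": [0.0] * 3})
        (p_strip, _) = domain_coverage(t, (1,), n_bins=10)
        assert len(p_strip.covered) == 1
        lo, hi = p_strip.covered[0]
        assert hi - lo == pytest.approx(1.0)  # one bin of [0, 10] at 10 bins
        assert lo <= 5.0 <= hi

    def test_empty_selection_covers_nothing(self):
        t = make_table({"p": [0.0, 1.0]}, {"m": [0.0, 1.0]})
        for strip in domain_coverage(t, ()):
            assert strip.covered == ()

    def test_empty_table_rejected(self):
        t = make_table({"p": []}, {"m": []})
        with pytest.raises(ValueError):
            domain_coverage(t, ())
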