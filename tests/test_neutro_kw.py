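"""The interval Kruskal-Wallis statistics against hand and library oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kruskal, rankdata

from neutrokw.interval_data import ComponentPair, GroupedNeutrosophicData
from neutrokw.neutro_kw import (
    DegenerateSampleError,
    chi_square_p,
    correction_term,
    decide,
    h_statistic,
    h_statistic_no_ties,
    indeterminacy_measure,
    neutrosophic_form,
    neutrosophic_kruskal_wallis,
    permutation_p,
    s_k_squared,
    s_r_squared,
    s_r_squared_no_ties,
)
from neutrokw.ranking import component_ranks


class TestBuildingBlocks:
    def test_s_k_squared_reference_values(self):
        assert s_k_squared([757.5, 775.5, 297], [20, 20, 20]) == pytest.approx(
            63170.775
        )
        assert s_k_squared([766.5, 767, 296.5], [20, 20, 20]) == pytest.approx(
            63186.175
        )

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_single_group_s_k_equals_correction(self, n):
        # With one group holding all ranks, S_k^2 = (n(n+1)/2)^2 / n = C.
        assert s_k_squared([n * (n + 1) / 2], [n]) == correction_term(n)

    def test_s_k_squared_input_validation(self):
        with pytest.raises(ValueError, match="group sizes"):
            s_k_squared([10.0, 20.0], [3, 2, 1])
        with pytest.raises(ValueError, match="positive"):
            s_k_squared([10.0], [0])

    def test_s_r_squared_reference_values(self, table1):
        pair = s_r_squared(component_ranks(table1))
        assert pair.as_tuple() == (73803.5, 73802.0)

    @pytest.mark.parametrize(
        "n, expected", [(60, 73810), (1, 1), (4, 30)]
    )
    def test_s_r_squared_no_ties_closed_form(self, n, expected):
        assert s_r_squared_no_ties(n) == expected

    @pytest.mark.parametrize("n, expected", [(60, 55815), (1, 1), (4, 25)])
    def test_correction_term(self, n, expected):
        assert correction_term(n) == expected

    @pytest.mark.parametrize("fn", [s_r_squared_no_ties, correction_term])
    def test_closed_forms_reject_n_below_one(self, fn):
        with pytest.raises(ValueError):
            fn(0)


class TestHStatistic:
    def test_reference_values(self):
        h_l = h_statistic(60, 63170.775, 73803.5, 55815)
        h_u = h_statistic(60, 63186.175, 73802, 55815)
        assert h_l == pytest.approx(24.126, abs=5e-4)
        assert h_u == pytest.approx(24.1785, abs=5e-4)

    def test_zero_when_rank_sums_balanced(self):
        n = 12
        c = correction_term(n)
        assert h_statistic(n, c, s_r_squared_no_ties(n), c) == 0.0

    def test_fully_degenerate_sample_is_an_error(self):
        with pytest.raises(DegenerateSampleError):
            h_statistic(4, 25.0, 25.0, 25.0)

    @given(st.data())
    def test_tie_free_identity_with_simple_form(self, data):
        """With no ties the corrected and uncorrected H agree exactly."""
        k = data.draw(st.integers(2, 4))
        sizes = [data.draw(st.integers(1, 6)) for _ in range(k)]
        n = sum(sizes)
        ranks = list(range(1, n + 1))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        rng.shuffle(ranks)
        sums, start = [], 0
        for s in sizes:
            sums.append(sum(ranks[start : start + s]))
            start += s
        s_k2 = s_k_squared(sums, sizes)
        if n < 2:
            return
        h_tie = h_statistic(n, s_k2, s_r_squared_no_ties(n), correction_term(n))
        h_simple = h_statistic_no_ties(n, s_k2)
        assert h_tie == pytest.approx(h_simple, rel=1e-10, abs=1e-10)
        assert -1e-10 <= h_tie <= n - 1 + 1e-10

    def test_three_singletons_are_permutation_invariant(self):
        # k = 3 singleton groups: S_k^2 = 1 + 4 + 9 = 14 for every rank
        # assignment (singletons make S_k^2 a symmetric function), so all 6
        # assignments give H = n - 1 = 2.
        values = []
        for perm in itertools.permutations([1, 2, 3]):
            s_k2 = s_k_squared(list(perm), [1, 1, 1])
            values.append(h_statistic_no_ties(3, s_k2))
        assert values == pytest.approx([2.0] * 6)


class TestPValues:
    def test_chi_square_edge_and_reference(self):
        assert chi_square_p(0.0, 2) == 1.0
        # df = 2 has the closed form exp(-h/2).
        assert chi_square_p(9.21, 2) == pytest.approx(math.exp(-9.21 / 2))
        assert chi_square_p(9.21, 2) == pytest.approx(0.01, abs=5e-5)
        assert chi_square_p(24.126, 2) == pytest.approx(5.77e-6, rel=1e-2)

    def test_chi_square_rejects_bad_input(self):
        with pytest.raises(ValueError):
            chi_square_p(-1.0, 2)
        with pytest.raises(ValueError):
            chi_square_p(1.0, 0)

    def test_exhaustive_three_assignments(self):
        # Groups {1,2} and {3}: 3 distinct assignments with H values
        # {0, 1.5, 1.5} — the two-sided statistic cannot tell the singleton
        # holding the max from the one holding the min — so p = 2/3.
        data = GroupedNeutrosophicData.from_items(
            [("a", [(1, 1), (2, 2)]), ("b", [(3, 3)])]
        )
        assert permutation_p(data, "lower", "exhaustive") == pytest.approx(2 / 3)

    def test_exhaustive_matches_independent_enumeration(self):
        """Exhaustive permutation p equals a from-scratch enumeration oracle."""
        data = GroupedNeutrosophicData.from_items(
            [("a", [(1, 2), (4, 5), (4, 6)]), ("b", [(2, 3), (7, 8)]), ("c", [(0, 9)])]
        )
        for component in ("lower", "upper"):
            values = np.array(data.component_values(component))
            sizes = data.group_sizes
            ranks = rankdata(values)
            n = len(values)
            c = n * (n + 1) ** 2 / 4
            s_r2 = float(np.sum(ranks**2))

            def h_of(assignment):
                s_k2 = sum(
                    ranks[list(g)].sum() ** 2 / len(g) for g in assignment
                )
                return (n - 1) * (s_k2 - c) / (s_r2 - c)

            # Enumerate ordered set partitions with the given block sizes.
            hits = total = 0
            observed = h_of(
                [
                    list(range(sum(sizes[:i]), sum(sizes[: i + 1])))
                    for i in range(len(sizes))
                ]
            )
            for perm in set(
                itertools.permutations(
                    [g for g, s in enumerate(sizes) for _ in range(s)]
                )
            ):
                assignment = [
                    [i for i, lab in enumerate(perm) if lab == g]
                    for g in range(len(sizes))
                ]
                total += 1
                if h_of(assignment) >= observed - 1e-12:
                    hits += 1
            expected = hits / total
            assert permutation_p(data, component, "exhaustive") == pytest.approx(
                expected
            )

    def test_all_identical_values_give_p_one(self):
        data = GroupedNeutrosophicData.from_items(
            [("a", [(5, 5), (5, 5)]), ("b", [(5, 5)])]
        )
        assert permutation_p(data, "lower", "exhaustive") == 1.0
        assert permutation_p(data, "lower", 50, seed=1) == 1.0

    def test_monte_carlo_deterministic_under_seed(self, small_dataset):
        p1 = permutation_p(small_dataset, "upper", 500, seed=42)
        p2 = permutation_p(small_dataset, "upper", 500, seed=42)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_exhaustive_cap_enforced(self, table1):
        with pytest.raises(ValueError, match="cap"):
            permutation_p(table1, "lower", "exhaustive")


class TestIndeterminacyAndForm:
    def test_reference_measure(self):
        h = ComponentPair(24.12600967, 24.17853589)
        assert indeterminacy_measure(h) == pytest.approx(0.00217, abs=5e-5)
        assert round(indeterminacy_measure(h), 3) == 0.002

    @pytest.mark.parametrize("h", [0.0, 3.7, 24.1])
    def test_equal_components_have_zero_indeterminacy(self, h):
        assert indeterminacy_measure(ComponentPair(h, h)) == 0.0

    def test_zero_upper_with_nonzero_lower_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            indeterminacy_measure(ComponentPair(1.0, 0.0))

    def test_form_self_consistency(self):
        form = neutrosophic_form(ComponentPair(10.0, 12.0))
        assert form.determinate_term == 10.0
        assert form.indeterminate_coefficient == 12.0
        assert form.indeterminacy_interval == (0.0, pytest.approx(1 / 6))
        i_u = form.indeterminacy_interval[1]
        assert form.determinate_term + form.indeterminate_coefficient * i_u == (
            pytest.approx(12.0)
        )

    def test_zero_width_form_collapses(self):
        form = neutrosophic_form(ComponentPair(7.5, 7.5))
        assert form.indeterminacy_interval == (0.0, 0.0)


class TestDecide:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            ((24.126, 24.178), "reject"),
            ((1.0, 2.0), "fail_to_reject"),
            ((8.0, 10.0), "indeterminate"),
            ((9.21, 9.21), "fail_to_reject"),  # boundary: not strictly above
        ],
    )
    def test_rule(self, pair, expected):
        assert decide(ComponentPair(*pair), 9.21) == expected

    def test_positive_critical_value_required(self):
        with pytest.raises(ValueError):
            decide(ComponentPair(1.0, 2.0), 0.0)


class TestFullTest:
    def test_reference_dataset_end_to_end(self, table1):
        result = neutrosophic_kruskal_wallis(table1, alpha=0.01)
        assert result.df == 2
        assert result.H.lower_component == pytest.approx(24.126, abs=5e-4)
        assert result.H.upper_component == pytest.approx(24.179, abs=5e-4)
        assert result.critical_value == pytest.approx(9.2103, abs=5e-4)
        assert result.decision == "reject"
        assert result.p.lower_component < 1e-5
        assert result.indeterminacy == pytest.approx(0.00217, abs=5e-5)

    def test_classical_reduction_matches_scipy(self):
        """Zero-width data reproduces the classical tie-corrected test."""
        rng = np.random.default_rng(7)
        samples = [rng.integers(0, 12, size=m).astype(float) for m in (8, 11, 9, 6)]
        data = GroupedNeutrosophicData.from_items(
            [(f"g{i}", [(v, v) for v in s]) for i, s in enumerate(samples)]
        )
        result = neutrosophic_kruskal_wallis(data, alpha=0.05)
        h_ref, p_ref = kruskal(*samples)
        assert result.H.lower_component == pytest.approx(h_ref, rel=1e-12)
        assert result.H.upper_component == pytest.approx(h_ref, rel=1e-12)
        assert result.p.lower_component == pytest.approx(p_ref, rel=1e-12)
        assert result.indeterminacy == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_h_from_first_principles_on_random_instances(self, seed):
        """Both H components match a from-scratch evaluation of the formula."""
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 5, size=3)
        groups = []
        for i, m in enumerate(sizes):
            lo = rng.integers(0, 6, size=m).astype(float)
            up = lo + rng.integers(0, 3, size=m)
            groups.append((f"g{i}", list(zip(lo, up))))
        data = GroupedNeutrosophicData.from_items(groups)
        try:
            result = neutrosophic_kruskal_wallis(data)
        except DegenerateSampleError:
            return  # all pooled values identical; H undefined by design
        n = data.n
        for component, h_impl in (
            ("lower", result.H.lower_component),
            ("upper", result.H.upper_component),
        ):
            values = np.array(data.component_values(component))
            ranks = rankdata(values)
            sums, start = [], 0
            for m in data.group_sizes:
                sums.append(ranks[start : start + m].sum())
                start += m
            s_k2 = sum(r**2 / m for r, m in zip(sums, data.group_sizes))
            s_r2 = float(np.sum(ranks**2))
            c = n * (n + 1) ** 2 / 4
            assert h_impl == pytest.approx((n - 1) * (s_k2 - c) / (s_r2 - c))
            assert -1e-10 <= h_impl <= n - 1 + 1e-10

    def test_invalid_alpha_rejected(self, table1):
        with pytest.raises(ValueError, match="alpha"):
            neutrosophic_kruskal_wallis(table1, alpha=1.5)

    def test_degenerate_component_reported(self):
        data = GroupedNeutrosophicData.from_items(
            [("a", [(1, 1), (1, 2)]), ("b", [(1, 1)])]
        )
        with pytest.raises(DegenerateSampleError):
            neutrosophic_kruskal_wallis(data)

    def test_result_serializes_to_json(self, table1):
        import json

        payload = json.dumps(neutrosophic_kruskal_wallis(table1).to_dict())
        parsed = json.loads(payload)
        assert parsed["decision"] == "reject"
        assert parsed["H_lower"] == pytest.approx(24.126, abs=5e-4)
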