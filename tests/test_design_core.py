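"""Allocation-table combinatorics against brute-force enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from distrand import (
    DesignSpec,
    InterestingSet,
    build_allocation_table,
    completion_prob,
    marginal_allocation_prob,
    partial_draw_prob,
    separate_trials_tables,
    uninteresting_count_distribution,
)
from distrand.errors import DistrandError

from conftest import brute_force_interesting_probs, brute_force_marginal


class TestPartialDrawProb:
    @pytest.mark.parametrize(
        "x, p, expected",
        [
            ((1, 1), (0.5, 0.5), 0.25),
            ((), (), 1.0),
            ((1, 0), (0.3, 0.6), 0.3 * 0.4),
            ((0, 0, 1), (0.2, 0.3, 0.9), 0.8 * 0.7 * 0.9),
        ],
    )
    def test_product(self, x, p, expected):
        assert partial_draw_prob(x, p) == pytest.approx(expected, abs=1e-15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            partial_draw_prob((1, 0), (0.5,))


class TestCompletionProb:
    def test_exact_k_binomial(self):
        spec = DesignSpec("distributive", K=4, k=2)
        iset = InterestingSet((1,))
        # one interesting allocated: need 1 of 3 balanced -> C(3,1) 0.5^3
        assert completion_prob(1, spec, iset) == pytest.approx(0.375)

    def test_too_many_allocations_zero(self):
        spec = DesignSpec("distributive", K=4, k=2)
        iset = InterestingSet((1, 2, 3))
        assert completion_prob(3, spec, iset) == 0.0

    def test_full_factorial_always_one(self):
        spec = DesignSpec("full_factorial", K=6)
        assert completion_prob(2, spec, InterestingSet((1, 2, 3))) == 1.0

    def test_capped_sums_lower_tail(self):
        spec = DesignSpec("capped_factorial", K=5, k=2)
        iset = InterestingSet((1,))
        # l=1: at most 1 of 4 uninteresting -> (C(4,0)+C(4,1)) 0.5^4
        assert completion_prob(1, spec, iset) == pytest.approx(5 / 16)


class TestCountDistribution:
    def test_balanced_is_binomial(self):
        spec = DesignSpec("distributive", K=4, k=2)
        dist = uninteresting_count_distribution(spec, InterestingSet((1,)))
        assert dist == pytest.approx([1 / 8, 3 / 8, 3 / 8, 1 / 8])

    def test_empty_convolution(self):
        spec = DesignSpec("distributive", K=2, k=1)
        dist = uninteresting_count_distribution(spec, InterestingSet((1, 2)))
        assert dist == pytest.approx([1.0])

    def test_unbalanced_convolution(self):
        spec = DesignSpec("distributive", K=3, k=1, alloc_probs=(0.5, 0.3, 0.6))
        dist = uninteresting_count_distribution(spec, InterestingSet((1,)))
        assert dist == pytest.approx([0.28, 0.54, 0.18])


class TestBuildTable:
    def test_one_interesting_balanced(self):
        # K=4, k=2: 3 of the 6 equiprobable pairs contain intervention 1
        table = build_allocation_table(
            DesignSpec("distributive", K=4, k=2), InterestingSet((1,))
        )
        assert table.p_final == pytest.approx([0.5, 0.5])

    def test_two_interesting_balanced(self):
        table = build_allocation_table(
            DesignSpec("distributive", K=5, k=2), InterestingSet((1, 2))
        )
        # rows ordered 00, 10, 01, 11 (intervention 1 fastest-varying)
        assert table.p_final == pytest.approx([0.3, 0.3, 0.3, 0.1])

    def test_cap_not_binding_equals_full_factorial(self):
        iset = InterestingSet((1, 3))
        capped = build_allocation_table(
            DesignSpec("capped_factorial", K=4, k=4), iset
        )
        full = build_allocation_table(DesignSpec("full_factorial", K=4), iset)
        assert capped.p_final == pytest.approx(full.p_final)

    def test_distributive_all_allocated(self):
        table = build_allocation_table(
            DesignSpec("distributive", K=3, k=3), InterestingSet((1, 2))
        )
        # only the all-ones interesting row is feasible
        assert table.p_final == pytest.approx([0, 0, 0, 1])

    def test_controlled_zero_fraction_matches_distributive(self):
        iset = InterestingSet((1, 2))
        plain = build_allocation_table(DesignSpec("distributive", K=6, k=3), iset)
        ctrl = build_allocation_table(
            DesignSpec("controlled_distributive", K=6, k=3, control_fraction=0.0),
            iset,
        )
        assert ctrl.p_final == pytest.approx(plain.p_final)
        assert not ctrl.is_control.any()

    def test_controlled_scaling_and_control_row(self):
        iset = InterestingSet((1,))
        ctrl = build_allocation_table(
            DesignSpec("controlled_distributive", K=10, k=4, control_fraction=0.2),
            iset,
        )
        assert ctrl.is_control[-1]
        assert ctrl.p_final[-1] == pytest.approx(0.2)
        assert ctrl.p_final.sum() == pytest.approx(1.0, abs=1e-12)

    def test_parallel_arms(self):
        table = build_allocation_table(DesignSpec("parallel", K=4))
        assert table.n_rows == 5
        assert table.p_final == pytest.approx(np.full(5, 0.2))
        assert table.is_control.sum() == 1

    def test_separate_requires_helper(self):
        with pytest.raises(ValueError, match="separate"):
            build_allocation_table(DesignSpec("separate", K=4))
        tables = separate_trials_tables(DesignSpec("separate", K=4))
        assert len(tables) == 4 and all(t.n_rows == 3 for t in tables)

    def test_csv_round_trip(self, tmp_path):
        table = build_allocation_table(
            DesignSpec("distributive", K=5, k=2), InterestingSet((1, 2))
        )
        path = tmp_path / "table.csv"
        table.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df["p_final"]) == pytest.approx(list(table.p_final))


class TestOracleEquivalence:
    """The reduced p'/p'' factorization must match full enumeration."""

    @pytest.mark.parametrize(
        "kind, K, k, interesting",
        [
            ("distributive", 6, 2, (1, 3)),
            ("distributive", 8, 4, (2, 5, 7)),
            ("capped_factorial", 6, 3, (1, 2)),
            ("full_factorial", 7, None, (1, 4, 6)),
            ("controlled_distributive", 6, 2, (1, 3)),
        ],
    )
    def test_fixed_cases(self, kind, K, k, interesting):
        c = 0.3 if kind == "controlled_distributive" else 0.0
        spec = DesignSpec(kind, K=K, k=k, control_fraction=c)
        iset = InterestingSet(interesting)
        table = build_allocation_table(spec, iset)
        oracle = brute_force_interesting_probs(spec, iset)
        assert table.p_final == pytest.approx(oracle, abs=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_arbitrary_allocation_ratios(self, data):
        K = data.draw(st.integers(3, 8), label="K")
        k = data.draw(st.integers(1, K), label="k")
        L = data.draw(st.integers(0, min(4, K)), label="L")
        idx = tuple(
            sorted(
                data.draw(
                    st.sets(st.integers(1, K), min_size=L, max_size=L), label="idx"
                )
            )
        )
        probs = tuple(
            data.draw(
                st.lists(
                    st.floats(0.05, 0.95, allow_nan=False),
                    min_size=K,
                    max_size=K,
                ),
                label="probs",
            )
        )
        kind = data.draw(
            st.sampled_from(["distributive", "capped_factorial"]), label="kind"
        )
        spec = DesignSpec(kind, K=K, k=k, alloc_probs=probs)
        iset = InterestingSet(idx)
        try:
            table = build_allocation_table(spec, iset)
        except DistrandError:
            return
        oracle = brute_force_interesting_probs(spec, iset)
        np.testing.assert_allclose(table.p_final, oracle, atol=1e-10)
        assert table.p_final.sum() == pytest.approx(1.0, abs=1e-12)


class TestMarginals:
    def test_balanced_distributive_is_k_over_K(self):
        table = build_allocation_table(
            DesignSpec("distributive", K=10, k=4), InterestingSet((1, 2))
        )
        for i in (1, 2, 5, 10):  # interesting and uninteresting alike
            assert marginal_allocation_prob(table, i) == pytest.approx(0.4, abs=1e-12)

    def test_full_factorial_balanced(self):
        table = build_allocation_table(
            DesignSpec("full_factorial", K=6), InterestingSet((1,))
        )
        assert marginal_allocation_prob(table, 1) == pytest.approx(0.5)
        assert marginal_allocation_prob(table, 4) == pytest.approx(0.5)

    def test_controlled_scaling(self):
        table = build_allocation_table(
            DesignSpec("controlled_distributive", K=10, k=4, control_fraction=0.2),
            InterestingSet((1,)),
        )
        assert marginal_allocation_prob(table, 1) == pytest.approx(0.32, abs=1e-12)

    def test_unbalanced_against_enumeration(self):
        probs = (0.3, 0.7, 0.5, 0.5, 0.5, 0.5)
        spec = DesignSpec("distributive", K=6, k=2, alloc_probs=probs)
        table = build_allocation_table(spec, InterestingSet((1, 2)))
        for i in (1, 2):
            assert marginal_allocation_prob(table, i) == pytest.approx(
                brute_force_marginal(spec, i), abs=1e-10
            )

    def test_capped_uninteresting_marginal(self):
        spec = DesignSpec("capped_factorial", K=5, k=2)
        table = build_allocation_table(spec, InterestingSet((1,)))
        assert marginal_allocation_prob(table, 3) == pytest.approx(
            brute_force_marginal(spec, 3), abs=1e-10
        )


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="distributive", K=1, k=1),
            dict(kind="distributive", K=4, k=0),
            dict(kind="distributive", K=4, k=5),
            dict(kind="distributive", K=4),                       # missing k
            dict(kind="distributive", K=4, k=2, alloc_probs=(0.5,) * 3),
            dict(kind="distributive", K=4, k=2, alloc_probs=(0.0, 0.5, 0.5, 0.5)),
            dict(kind="distributive", K=4, k=2, control_fraction=0.3),
            dict(kind="controlled_distributive", K=4, k=2, control_fraction=1.0),
            dict(kind="nonsense", K=4, k=2),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DesignSpec(**kwargs)

    def test_roundtrip_dict(self):
        spec = DesignSpec("controlled_distributive", K=8, k=3, control_fraction=0.1)
        assert DesignSpec.from_dict(spec.to_dict()) == spec
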