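"""Hypergeometric upper tail, Bonferroni adjustment and the per-plant
enrichment scan."""

import itertools
import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phytoscreen import bonferroni_adjust, hypergeom_upper_tail, run_acea
from phytoscreen.activity import ActivityCall
from phytoscreen.errors import ContractViolation
from phytoscreen.io_chem import PlantRecord


def exact_upper_tail(N, n, m, k):
    """Oracle: exact tail by summing combinatorial counts as rationals."""
    total = sum(
        math.comb(n, j) * math.comb(N - n, m - j)
        for j in range(k, min(n, m) + 1)
        if m - j <= N - n
    )
    return Fraction(total, math.comb(N, m))


def test_oracle_agrees_with_literal_subset_enumeration():
    """The combinatorial oracle itself is validated against brute-force
    enumeration of every m-subset of a small population."""
    N, n, m, k = 9, 4, 5, 2
    population = [1] * n + [0] * (N - n)
    hits = sum(
        1 for sub in itertools.combinations(population, m) if sum(sub) >= k
    )
    assert exact_upper_tail(N, n, m, k) == Fraction(hits, math.comb(N, m))


class TestHypergeomUpperTail:
    def test_k_zero_is_exactly_one(self):
        assert hypergeom_upper_tail(100, 30, 10, 0) == 1.0

    def test_hand_enumerated_case(self):
        # N=10, n=4, m=5: of the 252 possible draws, 66 contain >= 3 actives
        assert exact_upper_tail(10, 4, 5, 3) == Fraction(66, 252)
        assert hypergeom_upper_tail(10, 4, 5, 3) == pytest.approx(66 / 252, rel=1e-12)

    def test_degenerate_all_active(self):
        assert hypergeom_upper_tail(7, 7, 7, 7) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "N, n, m, k, match",
        [
            (10, 11, 5, 2, "n <= N"),
            (10, 4, 11, 2, "m <= N"),
            (10, 4, 5, 5, "min"),
            (10, 4, 5, -1, "min"),
        ],
    )
    def test_contract_violations_named(self, N, n, m, k, match):
        with pytest.raises(ContractViolation, match=match):
            hypergeom_upper_tail(N, n, m, k)

    @given(
        st.integers(1, 40).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(0, N),
                st.integers(0, N),
            )
        )
    )
    def test_monotone_nonincreasing_in_k(self, Nnm):
        N, n, m = Nnm
        tail = [hypergeom_upper_tail(N, n, m, k) for k in range(min(n, m) + 1)]
        assert all(b <= a + 1e-15 for a, b in zip(tail, tail[1:]))


class TestBonferroni:
    def test_scaling(self):
        assert bonferroni_adjust(1e-5, 2402) == pytest.approx(0.02402)

    def test_cap_at_one(self):
        assert bonferroni_adjust(0.001, 2402) == 1.0

    def test_single_test_identity(self):
        assert bonferroni_adjust(0.37, 1) == 0.37

    def test_domain_checks(self):
        with pytest.raises(ContractViolation):
            bonferroni_adjust(1.5, 10)
        with pytest.raises(ContractViolation):
            bonferroni_adjust(0.5, 0)


def _call(cid, active):
    return ActivityCall(cid, 1.0 if active else 0.0, 0.01 if active else 0.9, active)


def _plant(pid, name, cids):
    return PlantRecord(plant_id=pid, plant_name=name, family="F", compound_ids=set(cids))


class TestRunAcea:
    def test_maximal_enrichment_is_significant(self):
        # one plant holds all 10 actives among a 500-compound library
        calls = [_call(f"c{i}", i < 10) for i in range(500)]
        plants = [
            _plant("p1", "hot", [f"c{i}" for i in range(10)]),
            _plant("p2", "cold", [f"c{i}" for i in range(100, 130)]),
        ]
        res = run_acea(plants, calls)
        assert res[0].plant_id == "p1"
        assert res[0].significant
        assert res[0].p_adj < 1e-10
        assert not res[1].significant

    def test_identical_counts_tie_broken_by_name(self):
        calls = [_call(f"c{i}", i < 40) for i in range(200)]
        shared_active = [f"c{i}" for i in range(5)]
        shared_inactive = [f"c{i}" for i in range(50, 55)]
        plants = [
            _plant("p2", "zeta", shared_active + shared_inactive),
            _plant("p1", "alpha", [f"c{i}" for i in range(5, 10)] + [f"c{i}" for i in range(60, 65)]),
        ]
        res = run_acea(plants, calls)
        assert (res[0].m, res[0].k) == (res[1].m, res[1].k)
        assert res[0].p == res[1].p and res[0].p_adj == res[1].p_adj
        assert [r.plant_name for r in res] == ["alpha", "zeta"]

    def test_empty_plant_untestable(self, caplog):
        calls = [_call("c1", True), _call("c2", False)]
        plants = [_plant("p1", "void", [])]
        with caplog.at_level("WARNING"):
            res = run_acea(plants, calls)
        assert res[0].p == 1.0 and not res[0].significant
        assert "untestable" in caplog.text

    def test_shared_compound_counts_once_in_library(self):
        calls = [_call(f"c{i}", i == 0) for i in range(10)]
        plants = [
            _plant("p1", "a", ["c0", "c1"]),
            _plant("p2", "b", ["c0", "c2"]),
        ]
        res = run_acea(plants, calls)
        assert all(r.N == 10 and r.n == 1 for r in res)
        assert all(r.k == 1 for r in res)  # the shared active counts in both

    def test_min_m_filter_reduces_ng(self):
        calls = [_call(f"c{i}", i < 5) for i in range(50)]
        plants = [
            _plant("p1", "big", [f"c{i}" for i in range(10)]),
            _plant("p2", "tiny", ["c40"]),
        ]
        full = run_acea(plants, calls)
        filtered = run_acea(plants, calls, min_m=5)
        assert len(full) == 2 and len(filtered) == 1
        # the surviving test is adjusted by a smaller family
        assert filtered[0].p_adj <= full[0].p_adj if full[0].plant_id == "p1" else True
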