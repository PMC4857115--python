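"""Activity model: bit weighting, hybrid score, empirical P, library calls."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phytoscreen import (
    ConfigurationError,
    empirical_pvalue,
    fit_activity_model,
    predict_library,
    score_compound,
)
from phytoscreen.activity import ActivityModel, score_batch
from phytoscreen.chem_core import N_MACCS_BITS


def _pad(bits_on, n=N_MACCS_BITS):
    v = np.zeros(n, dtype=bool)
    v[list(bits_on)] = True
    return v


def _random_fps(rng, n, density=0.2):
    return rng.random((n, N_MACCS_BITS)) < density


class TestFit:
    def test_floor_enforced(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError, match="10"):
            fit_activity_model(_random_fps(rng, 3), _random_fps(rng, 300))
        with pytest.raises(ConfigurationError, match="200"):
            fit_activity_model(_random_fps(rng, 20), _random_fps(rng, 50))

    def test_weight_endpoints(self):
        rng = np.random.default_rng(1)
        A = _random_fps(rng, 20)
        D = _random_fps(rng, 300)
        A[:, 0] = True  # bit present in every active
        D[:, 0] = False  # and in no decoy
        A[:, 1] = True
        D[:, 1] = True  # identical frequency 1.0 in both sets
        model = fit_activity_model(A, D)
        # ln((1+eps)/eps) = ln(101) ~ 4.62, inside the [-5, 5] clip
        assert model.bit_weights[0] == pytest.approx(
            min(5.0, math.log(1.01 / 0.01)), abs=1e-12
        )
        assert model.bit_weights[1] == pytest.approx(0.0, abs=1e-12)

    def test_null_scores_sorted(self):
        rng = np.random.default_rng(2)
        model = fit_activity_model(_random_fps(rng, 15), _random_fps(rng, 250))
        assert np.all(np.diff(model.null_scores) >= 0)
        assert len(model.null_scores) == 250


class TestScore:
    def test_identical_query_scores_at_least_half(self):
        rng = np.random.default_rng(3)
        A = _random_fps(rng, 12)
        model = fit_activity_model(A, _random_fps(rng, 220))
        assert score_compound(model, A[0]) >= 0.5

    def test_disjoint_query_scores_zero(self):
        rng = np.random.default_rng(4)
        A = np.zeros((12, N_MACCS_BITS), bool)
        A[:, :20] = rng.random((12, 20)) < 0.6
        A[:, 0] = True  # keep every active non-empty
        D = np.zeros((250, N_MACCS_BITS), bool)
        D[:, 150:] = rng.random((250, 16)) < 0.5
        model = fit_activity_model(A, D)
        q = _pad(range(100, 140))
        assert score_compound(model, q) == 0.0

    def test_matches_brute_force_on_toy_model(self):
        # independent re-implementation: explicit loops over bits and actives
        rng = np.random.default_rng(5)
        A = _random_fps(rng, 3, density=0.3)
        weights = rng.normal(0, 1.5, N_MACCS_BITS).clip(-5, 5)
        model = ActivityModel(
            active_fps=A, bit_weights=weights, null_scores=np.array([0.0])
        )
        q = _random_fps(rng, 1, density=0.3)[0]
        w_pos = np.exp(weights)
        wtcs = []
        for a in A:
            num = sum(w_pos[b] for b in range(N_MACCS_BITS) if q[b] and a[b])
            den = sum(w_pos[b] for b in range(N_MACCS_BITS) if q[b] or a[b])
            wtcs.append(num / den if den else 0.0)
        top = sorted(wtcs, reverse=True)[:5]
        expected = 0.5 * max(wtcs) + 0.5 * (sum(top) / len(top))
        assert score_compound(model, q) == pytest.approx(expected, rel=1e-12)


class TestEmpiricalP:
    def _model_with_nulls(self, nulls):
        return ActivityModel(
            active_fps=np.ones((1, N_MACCS_BITS), bool),
            bit_weights=np.zeros(N_MACCS_BITS),
            null_scores=np.sort(np.asarray(nulls, dtype=float)),
        )

    def test_score_above_all_nulls(self):
        model = self._model_with_nulls(np.linspace(0, 0.9, 999))
        assert empirical_pvalue(model, 0.95) == pytest.approx(1 / 1000)

    def test_score_below_all_nulls(self):
        model = self._model_with_nulls(np.linspace(0.1, 0.9, 999))
        assert empirical_pvalue(model, 0.05) == 1.0

    def test_median_with_tie_counting(self):
        nulls = np.linspace(0, 1, 999)
        model = self._model_with_nulls(nulls)
        med = float(np.median(nulls))
        n_ge = int(np.sum(nulls >= med))  # ties count toward the tail
        assert empirical_pvalue(model, med) == pytest.approx((1 + n_ge) / 1000)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_score(self, s1, s2):
        model = self._model_with_nulls(np.linspace(0, 1, 499))
        lo, hi = min(s1, s2), max(s1, s2)
        assert empirical_pvalue(model, hi) <= empirical_pvalue(model, lo)

    def test_never_zero(self):
        model = self._model_with_nulls([0.1] * 500)
        assert empirical_pvalue(model, 2.0) > 0.0


class TestPredictLibrary:
    def test_reference_actives_recovered(self, model, dataset):
        calls = predict_library(model, dataset.reference_actives)
        frac = np.mean([c.is_active for c in calls])
        assert frac > 0.05  # far above the decoy-expected rate

    def test_alpha_zero_calls_nothing(self, model, dataset):
        calls = predict_library(model, dataset.compounds[:50], alpha=0.0)
        assert not any(c.is_active for c in calls)

    def test_score_p_consistency(self, calls, model):
        for c in calls[:500]:
            assert 0.0 < c.p_value <= 1.0
            assert c.is_active == (c.p_value < 0.05)
            assert c.p_value == pytest.approx(empirical_pvalue(model, c.score))

    def test_scores_monotone_with_p(self, calls):
        arr = sorted(calls, key=lambda c: c.score)
        pvals = [c.p_value for c in arr]
        assert all(p2 <= p1 for p1, p2 in zip(pvals, pvals[1:]))
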