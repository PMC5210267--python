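"""Unit and property tests for the four procedures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from bonev import (
    PValueVector,
    bh_adjust,
    bh_reject,
    bonev_adjust,
    bonferroni_ev_reject,
    estimate_rejection_fraction,
    pi0_fixed_lambda,
    storey_qvalues,
    storey_reject,
)
from bonev.types import Pi0Estimate, Pi0Method

from conftest import make_pvector


def tail_min_oracle(p: np.ndarray, scale: float) -> np.ndarray:
    """O(m^2) reference for step-up adjustment: for each sorted index i,
    min over j >= i of p_(j) * scale / j, capped at 1, in input order."""
    m = p.size
    order = np.argsort(p, kind="stable")
    sp = p[order]
    adj_sorted = np.array(
        [min(1.0, min(sp[j] * scale / (j + 1) for j in range(i, m))) for i in range(m)]
    )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pvec(p):
    return PValueVector([f"x{i}" for i in range(len(p))], p)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.04, 0.5], [0.04, 0.04, 0.04 / 0.75, 0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(pvec(p)), expected, rtol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pv = make_pvector(rng, int(rng.integers(1, 200)))
            _, sm_adj, _, _ = multipletests(pv.p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(pv), sm_adj, rtol=1e-10, atol=1e-15)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_tail_min_oracle(self, p):
        pv = pvec(p)
        np.testing.assert_array_equal(bh_adjust(pv), tail_min_oracle(pv.p, pv.m))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            pv = make_pvector(rng, 100)
            adj = bh_adjust(pv)
            assert (adj >= 0).all() and (adj <= 1).all()
            order = np.argsort(pv.p, kind="stable")
            assert (np.diff(adj[order]) >= -1e-15).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        pv = make_pvector(rng, 60)
        perm = rng.permutation(60)
        permuted = PValueVector([pv.ids[i] for i in perm], pv.p[perm])
        np.testing.assert_array_equal(bh_adjust(permuted), bh_adjust(pv)[perm])


class TestBHReject:
    def test_rejects_two_smallest(self):
        res = bh_reject(pvec([0.01, 0.02, 0.04, 0.5]), alpha=0.05)
        assert res.n_rejected == 2
        np.testing.assert_array_equal(res.rejected, [True, True, False, False])

    def test_no_rejections(self):
        assert bh_reject(pvec([0.9, 0.8]), alpha=0.05).n_rejected == 0

    def test_zero_pvalue_always_rejected(self):
        for alpha in (0.001, 0.05, 0.5):
            res = bh_reject(pvec([0.0, 0.6, 0.7]), alpha=alpha)
            assert res.rejected[0]

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            bh_reject(pvec([0.1]), alpha)

    def test_consistent_with_adjust(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pv = make_pvector(rng, 80)
            res = bh_reject(pv, 0.05)
            np.testing.assert_array_equal(res.rejected, bh_adjust(pv) <= 0.05)


class TestStoreyQvalues:
    def test_scaling_example(self):
        q = storey_qvalues(pvec([0.01, 0.02, 0.04, 0.5]), pi0=0.5)
        np.testing.assert_allclose(q, [0.02, 0.02, 0.02 / 0.75, 0.25], rtol=1e-12)

    def test_pi0_one_equals_bh(self):
        rng = np.random.default_rng(13)
        pv = make_pvector(rng, 120)
        np.testing.assert_array_equal(storey_qvalues(pv, pi0=1.0), bh_adjust(pv))

    def test_single_value(self):
        np.testing.assert_allclose(storey_qvalues(pvec([0.2]), pi0=1.0), [0.2])

    def test_scaling_identity(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            pv = make_pvector(rng, int(rng.integers(1, 150)))
            pi0 = float(rng.uniform(0.05, 1.0))
            expected = np.minimum(1.0, pi0 * bh_adjust(pv))
            np.testing.assert_allclose(storey_qvalues(pv, pi0), expected, rtol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50),
        st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_tail_min_oracle(self, p, pi0):
        pv = pvec(p)
        np.testing.assert_array_equal(
            storey_qvalues(pv, pi0), tail_min_oracle(pv.p, pi0 * pv.m)
        )

    def test_invalid_pi0(self):
        with pytest.raises(ValueError):
            storey_qvalues(pvec([0.1]), pi0=0.0)


class TestBonferroniEV:
    def test_threshold_example(self):
        res = bonferroni_ev_reject(pvec([0.005, 0.02, 0.3]), gamma=0.03)
        np.testing.assert_array_equal(res.rejected, [True, False, False])

    def test_gamma_zero_rejects_only_exact_zeros(self):
        res = bonferroni_ev_reject(pvec([0.0, 1e-300, 0.5]), gamma=0.0)
        np.testing.assert_array_equal(res.rejected, [True, False, False])

    def test_gamma_m_rejects_all(self):
        res = bonferroni_ev_reject(pvec([0.1, 0.99, 1.0]), gamma=3.0)
        assert res.rejected.all()

    def test_negative_gamma(self):
        with pytest.raises(ValueError):
            bonferroni_ev_reject(pvec([0.1]), gamma=-1.0)

    def test_expected_false_discoveries_matches_budget(self):
        """Under m independent uniform nulls, E(# rejections) = gamma."""
        rng = np.random.default_rng(29)
        m, gamma, reps = 2000, 5.0, 400
        counts = []
        for _ in range(reps):
            pv = PValueVector([f"n{i}" for i in range(m)], rng.uniform(0, 1, m))
            counts.append(bonferroni_ev_reject(pv, gamma).n_rejected)
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - gamma) <= 3 * se


class TestRejectionFraction:
    def test_hand_example(self):
        assert estimate_rejection_fraction(pvec([0.01, 0.02, 0.04, 0.5]), 0.05) == 0.5

    def test_all_large(self):
        assert estimate_rejection_fraction(pvec([0.97, 0.98, 0.99]), 0.05) == 0.0

    def test_all_zero(self):
        assert estimate_rejection_fraction(pvec([0.0, 0.0]), 0.05) == 1.0


class TestBonEV:
    def test_worked_example(self, worked_example):
        res = bonev_adjust(worked_example, alpha=0.05, lam=0.5)
        assert res.pi0_hat == 1.0
        assert res.rejection_fraction_hat == 0.3
        assert res.cutoff == 0.015
        assert res.n_rejected == 3
        np.testing.assert_array_equal(res.rejected[:3], [True, True, True])
        assert not res.rejected[3:].any()

    def test_no_bh_rejections_gives_none(self):
        res = bonev_adjust(pvec([0.4, 0.6, 0.9]), alpha=0.05)
        assert res.rejection_fraction_hat == 0.0
        assert res.n_rejected == 0
        np.testing.assert_array_equal(res.adjusted, np.ones(3))

    def test_smaller_pi0_grows_rejections(self, worked_example):
        """Halving pi0 doubles the cutoff; the rejection set weakly grows."""
        full = bonev_adjust(worked_example, alpha=0.05, pi0=Pi0Estimate(1.0, 1.0, 0.5, Pi0Method.FIXED_LAMBDA))
        half = bonev_adjust(worked_example, alpha=0.05, pi0=Pi0Estimate(0.5, 0.5, 0.5, Pi0Method.FIXED_LAMBDA))
        assert half.cutoff == 2 * full.cutoff
        assert (full.rejected <= half.rejected).all()

    def test_rejected_iff_adjusted_below_alpha(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            pv = make_pvector(rng, 150)
            res = bonev_adjust(pv, 0.05)
            np.testing.assert_array_equal(res.rejected, res.adjusted <= 0.05)
            assert (res.adjusted >= 0).all() and (res.adjusted <= 1).all()


class TestNesting:
    def test_bh_within_bonev_within_storey(self):
        """Rejection sets nest: BH ⊆ Bon-EV ⊆ Storey, with shared capped pi0."""
        rng = np.random.default_rng(101)
        for _ in range(1000):
            m = int(rng.integers(5, 120))
            pv = make_pvector(rng, m)
            alpha = float(rng.uniform(0.01, 0.2))
            pi0 = pi0_fixed_lambda(pv, 0.5)
            bh = bh_reject(pv, alpha).rejected
            bonev = bonev_adjust(pv, alpha, pi0=pi0).rejected
            storey = storey_reject(pv, alpha, pi0=pi0).rejected
            assert (bh <= bonev).all()
            assert (bonev <= storey).all()
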