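"""Support extraction, nullity test, Gramian positive-definite test, and the
kernel-structured reduced test, including the equivalence property that makes
the positive-definite test a drop-in replacement for the nullity test."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eprays import (
    augment,
    build_gramian,
    nsa_reduced_test,
    nullity,
    nullity_test,
    pd_test,
    support,
)
from eprays.elementarity import KernelStructureError
from eprays.nsa import init_kernel_tableau
from eprays.synth import generate_random_network

CHAIN = np.array([[1, -1, 0], [0, 1, -1]], dtype=object)
BRANCHED = np.array([[1, -1, 0, -1], [0, 1, -1, 0]], dtype=object)


class TestSupport:
    def test_exact_zero_set(self):
        s = support(np.array([0, 2, 0, 3], dtype=object))
        assert s.Z == (0, 2) and s.Z_bar == (1, 3)

    def test_relative_threshold(self):
        s = support(np.array([0.0, 2.0, 1e-12, 3.0]), zero_tol=1e-9)
        assert s.Z_bar == (1, 3)

    def test_all_zero_vector_has_empty_support(self):
        assert support(np.zeros(3, dtype=object)).Z_bar == ()

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            support(np.array([], dtype=object))


class TestNullity:
    @pytest.mark.parametrize("M,expected", [
        (np.eye(3, dtype=int).astype(object), 0),
        (CHAIN, 1),
        (np.zeros((0, 4), dtype=object).reshape(0, 4), 4),
    ])
    def test_examples(self, M, expected):
        assert nullity(M) == expected

    def test_float_matches_exact_on_random_integers(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            A = rng.integers(-3, 4, size=(rng.integers(1, 6), rng.integers(1, 6)))
            assert nullity(A.astype(object)) == nullity(A.astype(float))


class TestNullityTest:
    def test_chain_full_support_is_elementary(self):
        assert nullity_test(CHAIN, (0, 1, 2), 2)

    def test_branched_full_support_is_not(self):
        assert not nullity_test(BRANCHED, (0, 1, 2, 3), 2)

    def test_zero_column_singleton(self):
        S = np.array([[0, 1], [0, -1]], dtype=object)
        assert nullity_test(S, (0,), 2)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="empty support"):
            nullity_test(CHAIN, (), 2)


class TestGramian:
    def test_chain_k2_by_outer_products(self):
        G = build_gramian(CHAIN, 2).G
        assert np.array_equal(G.astype(int), np.array([[2, 0, 1], [0, 3, 0], [1, 0, 2]]))

    def test_k0_is_all_ones(self):
        assert np.array_equal(build_gramian(CHAIN, 0).G.astype(int), np.ones((3, 3), dtype=int))

    def test_rank1_update_telescopes(self):
        ctx1 = build_gramian(CHAIN, 1)
        assert np.array_equal(ctx1.updated(CHAIN[1, :]).G, build_gramian(CHAIN, 2).G)

    def test_slicing_matches_direct_gramian(self):
        ctx = build_gramian(BRANCHED, 2)
        cols = [0, 1, 3]
        star = np.vstack([BRANCHED[:2, cols], np.ones((1, 3), dtype=object)])
        assert np.array_equal(ctx.G[np.ix_(cols, cols)], star.T @ star)

    def test_nonpositive_row_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_gramian(CHAIN, 1, a=[1, 0, 1])


class TestPdTest:
    def test_chain_elementary(self):
        assert pd_test(build_gramian(CHAIN, 2), (0, 1, 2))

    def test_branched_full_support_singular(self):
        # the 3x4 extended matrix has rank <= 3, so its 4x4 Gramian is singular
        assert not pd_test(build_gramian(BRANCHED, 2), (0, 1, 2, 3))

    def test_singleton_support_always_passes(self):
        assert pd_test(build_gramian(BRANCHED, 2), (2,))

    def test_float_mode_matches_exact(self):
        ctx_e = build_gramian(BRANCHED, 2)
        ctx_f = build_gramian(BRANCHED.astype(float), 2)
        for cols in [(0, 1, 2, 3), (0, 1, 2), (0, 3), (1,)]:
            assert pd_test(ctx_e, cols) == pd_test(ctx_f, cols)


class TestPdNullityEquivalence:
    """The Gramian test must agree with the nullity test for every valid
    candidate — nonnegative and at steady state over the processed rows — and
    its verdict must be independent of the choice of positive row."""

    @staticmethod
    def _candidates(S, k):
        from eprays.oracle import brute_force_rays
        from eprays.network import AugmentedNetwork, MetabolicNetwork

        base = MetabolicNetwork(
            [f"m{i}" for i in range(max(k, 1))],
            [f"r{j}" for j in range(S.shape[1])],
            np.asarray(S[: max(k, 1), :], dtype=object),
            [False] * S.shape[1],
            [True] * S.shape[1],
            allow_empty_exchange=True,
        )
        aug = AugmentedNetwork(base, np.asarray(S[:k, :], dtype=object).reshape(k, S.shape[1]), [])
        rays = brute_force_rays(aug).rays_aug
        sums = [
            np.array([a + b for a, b in zip(u.tolist(), v.tolist())], dtype=object)
            for i, u in enumerate(rays)
            for v in rays[i + 1 :][:3]
        ]
        return rays, sums

    def test_rays_and_ray_sums(self):
        for seed in range(8):
            net = generate_random_network(4, 7, rev_frac=0.3, seed=seed + 500)
            S = augment(net).S_aug
            for k in range(net.m + 1):
                ctx = build_gramian(S, k)
                rays, sums = self._candidates(S, k)
                for v in rays:
                    supp = support(v)
                    assert pd_test(ctx, supp) is True
                    assert nullity_test(S, supp, k) is True
                for v in sums:
                    supp = support(v)
                    assert pd_test(ctx, supp) == nullity_test(S, supp, k) == False  # noqa: E712

    def test_invariant_to_positive_row(self):
        rng = np.random.default_rng(11)
        net = generate_random_network(4, 7, rev_frac=0.3, seed=501)
        S = augment(net).S_aug
        a = np.array([Fraction(int(x), 7) for x in rng.integers(1, 20, size=S.shape[1])], dtype=object)
        for k in (0, 2, 4):
            ctx1 = build_gramian(S, k)
            ctx2 = build_gramian(S, k, a=a)
            rays, sums = self._candidates(S, k)
            for v in rays + sums:
                supp = support(v)
                assert pd_test(ctx1, supp) == pd_test(ctx2, supp)


class TestNsaReducedTest:
    def test_single_kernel_row_always_elementary(self):
        kernel = np.array([[1, 1, 1]], dtype=object)
        assert nsa_reduced_test(kernel, [2], {0, 1, 2}, set())

    def test_branched_examples(self):
        kernel = np.array([[1, 1, 1, 0], [1, 0, 0, 1]], dtype=object)
        idc = [2, 3]
        assert nsa_reduced_test(kernel, idc, {0, 1, 2, 3}, {3})
        assert not nsa_reduced_test(kernel, idc, {0, 1, 2, 3}, set())

    def test_structure_violation_raises(self):
        kernel = np.array([[1, 1, 1, 0], [1, 0, 1, 1]], dtype=object)
        with pytest.raises(KernelStructureError):
            nsa_reduced_test(kernel, [2, 3], {0, 1, 2, 3}, {3})

    def test_reduced_equals_direct_rank_on_random_kernels(self):
        from eprays._linalg import rank_exact

        for seed in range(20):
            net = generate_random_network(4, 8, rev_frac=0.4, seed=seed + 300)
            aug = augment(net)
            t, idc = init_kernel_tableau(aug)
            q = len(t.rows)
            if q < 2:
                continue
            kernel = np.array([r.flux_dense() for r in t.rows], dtype=object)
            rng = np.random.default_rng(seed)
            processed = set(range(aug.r_prime))
            for _ in range(10):
                Z = set(int(j) for j in rng.choice(aug.r_prime, size=rng.integers(0, aug.r_prime), replace=False))
                Zk = sorted(Z)
                direct = (rank_exact(kernel[:, Zk]) if Zk else 0) == q - 1
                assert nsa_reduced_test(kernel, idc, processed, Z) == direct


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(-5, 5), min_size=1, max_size=12))
def test_support_partitions_all_indices(vals):
    s = support(np.array(vals, dtype=object))
    assert sorted(s.Z + s.Z_bar) == list(range(len(vals)))
    assert all(vals[i] == 0 for i in s.Z)
    assert all(vals[i] != 0 for i in s.Z_bar)
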