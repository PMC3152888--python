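import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from debi import (
    compute_cutoffs,
    extend_bicluster,
    filter_overlap,
    fisher_association,
    overlap_area,
)
from debi.biclusters import Bicluster
from debi.extend import _tail_p

from conftest import binary, hypergeom_tail_oracle


def make_C(m, on):
    C = np.zeros(m, bool)
    C[list(on)] = True
    return C


class TestFisherAssociation:
    def test_perfect_match_is_inverse_binomial(self):
        v = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        # all four gene 1s inside the 4 phenotype samples: p = 1/C(8,4)
        assert fisher_association(v, v) == pytest.approx(1 / 70, abs=1e-15)

    def test_uninformative_gene_scores_one(self):
        C = make_C(8, range(4))
        assert fisher_association(np.ones(8, bool), C) == 1.0

    def test_depletion_direction_scores_one(self):
        C = make_C(8, range(4))
        assert fisher_association(~C, C) == 1.0

    def test_degenerate_phenotype_scores_one(self, rng):
        g = rng.random(8) < 0.5
        assert fisher_association(g, np.ones(8, bool)) == 1.0
        assert fisher_association(g, np.zeros(8, bool)) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(4, 30))
            g = rng.random(m) < rng.uniform(0.1, 0.9)
            C = make_C(m, rng.choice(m, size=int(rng.integers(1, m)), replace=False))
            p = fisher_association(g, C)
            expected = hypergeom_tail_oracle(
                int((g & C).sum()), int(g.sum()), int(C.sum()), m
            )
            assert p == pytest.approx(expected, abs=1e-12)


class TestCutoffs:
    def test_alpha_one_tests_everything(self):
        cut = compute_cutoffs(1.0, 4, 4)
        assert cut.min_sigma_in == -1
        assert cut.max_sigma_out == 5
        assert cut.tested(0, 4)

    def test_small_table_boundary(self):
        # with 4 samples in and 4 out at alpha=0.05, a gene with <= 3 ones
        # inside can never reach significance
        cut = compute_cutoffs(0.05, 4, 4)
        assert cut.min_sigma_in == 3

    def test_skipped_genes_are_never_significant(self, rng):
        """Cut-off soundness on random genes and phenotypes."""
        for _ in range(200):
            m = int(rng.integers(6, 25))
            n_in = int(rng.integers(1, m))
            alpha = float(rng.choice([0.05, 1e-3, 1e-6]))
            cut = compute_cutoffs(alpha, n_in, m - n_in)
            C = make_C(m, rng.choice(m, size=n_in, replace=False))
            g = rng.random(m) < rng.uniform(0.1, 0.9)
            s_in = int((g & C).sum())
            s_out = int(g.sum()) - s_in
            if not cut.tested(s_in, s_out):
                assert fisher_association(g, C) > alpha

    def test_tail_monotonicities(self):
        """The pre-screen relies on tail monotonicity in both margins."""
        n_in, n_out = 6, 9
        M = n_in + n_out
        for t in range(n_out + 1):
            ps = [_tail_p(s, s + t, n_in, M) for s in range(n_in + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        for s in range(n_in + 1):
            pt = [_tail_p(s, s + t, n_in, M) for t in range(n_out + 1)]
            assert all(a <= b + 1e-15 for a, b in zip(pt, pt[1:]))


class TestExtension:
    def test_exact_block_returns_exactly_block_genes(self):
        bits = np.zeros((12, 10), bool)
        bits[2:6, 3:8] = True
        B = binary(bits)
        C = make_C(10, range(3, 8))
        b = extend_bicluster(range(2, 6), C, B, alpha=0.01)
        assert b.gene_indices == (2, 3, 4, 5)
        assert b.sample_indices == (3, 4, 5, 6, 7)
        assert np.all(b.pvalues < 0.01)

    def test_gene_with_extra_sample_is_added_weak_seed_gene_deleted(self):
        bits = np.zeros((8, 20), bool)
        bits[0:4, 0:10] = True      # clean block
        bits[4, 0:11] = True        # covers the block plus one extra sample
        bits[5, 0:3] = True         # weak partial overlap
        bits[5, 12:19] = True
        B = binary(bits)
        C = make_C(20, range(10))
        b = extend_bicluster((0, 1, 2, 3, 5), C, B, alpha=0.001)
        assert 4 in b.gene_indices
        assert 5 not in b.gene_indices

    def test_vanishing_alpha_drops_bicluster(self):
        bits = np.zeros((4, 6), bool)
        bits[:2, :3] = True
        B = binary(bits)
        assert extend_bicluster((0, 1), make_C(6, range(3)), B, alpha=1e-300) is None

    def test_extension_idempotent(self, rng):
        bits = rng.random((15, 12)) < 0.35
        B = binary(bits)
        C = make_C(12, rng.choice(12, size=5, replace=False))
        first = extend_bicluster(range(3), C, B, alpha=0.2)
        if first is not None:
            second = extend_bicluster(first.gene_indices, C, B, alpha=0.2)
            assert second.gene_indices == first.gene_indices
            np.testing.assert_array_equal(second.pvalues, first.pvalues)


def bic(genes, samples, m=12):
    C = np.zeros(m, bool)
    C[list(samples)] = True
    return Bicluster(tuple(genes), C, "up", np.ones(len(list(genes))))


class TestFilterOverlap:
    def test_duplicate_biclusters_collapse(self):
        a = bic(range(4), range(4))
        b = bic(range(4), range(4))
        assert filter_overlap([a, b], 0.5) == [a]

    def test_disjoint_biclusters_all_survive(self):
        a = bic(range(4), range(4))
        b = bic(range(5, 9), range(5, 9))
        assert len(filter_overlap([a, b], 0.25)) == 2

    def test_nested_deleted_at_half_but_kept_at_one(self):
        big = bic(range(10), range(10), m=12)
        small = bic(range(4), range(4), m=12)  # fully inside: overlap 16
        assert filter_overlap([big, small], 0.5) == [big]
        # "exceeds" is strict: at L = 1.0 overlap equals the smaller size
        assert filter_overlap([big, small], 1.0) == [big, small]

    @given(data=st.data())
    @settings(max_examples=40)
    def test_survivors_pairwise_within_limit(self, data):
        """Post-condition for randomized collections with forced nesting."""
        k = data.draw(st.integers(2, 6))
        bics = []
        for _ in range(k):
            genes = data.draw(st.sets(st.integers(0, 9), min_size=1))
            samples = data.draw(st.sets(st.integers(0, 9), min_size=1))
            bics.append(bic(genes, samples, m=10))
        # force a nested duplicate of the first bicluster
        g0 = sorted(bics[0].gene_indices)
        s0 = sorted(bics[0].sample_indices)
        bics.append(bic(g0[: max(1, len(g0) // 2)], s0[: max(1, len(s0) // 2)], m=10))
        for L in (0.25, 0.5):
            kept = filter_overlap(bics, L)
            for i, u in enumerate(kept):
                for v in kept[i + 1 :]:
                    assert overlap_area(u, v) <= L * min(u.size, v.size) + 1e-9
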