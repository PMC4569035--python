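"""EM haplotype frequencies and the multi-allelic LD statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import msatld as m
from msatld.ld import HaplotypeTable, _collapse_pair, chi2prime, dprime
from msatld.panel import MISSING, Locus


def make_table(x):
    """HaplotypeTable wrapper around an explicit frequency matrix."""
    x = np.asarray(x, dtype=float)
    return HaplotypeTable(
        x=x, alleles_a=np.arange(x.shape[0]) + 1, alleles_b=np.arange(x.shape[1]) + 1,
        p=x.sum(axis=1), q=x.sum(axis=0), n=100, loglik=0.0, iterations=1, converged=True,
    )


def simplex_search_mle(ga, gb, n_starts=6, seed=0):
    """Direct likelihood maximization over the haplotype simplex.

    Independent of the EM path: SLSQP on the flattened table with an
    analytic gradient, equality constraint sum(x) = 1 and box bounds,
    best of several random Dirichlet starts.
    """
    k, mm, _, _, _, _, _, classes = _collapse_pair(ga, gb)
    dim = k * mm
    rng = np.random.default_rng(seed)

    def nll_grad(xf):
        x = xf.reshape(k, mm)
        ll = 0.0
        g = np.zeros((k, mm))
        for is_dh, (a1, b1, a2, b2), c in classes:
            if is_dh:
                P = 2.0 * (x[a1, b1] * x[a2, b2] + x[a1, b2] * x[a2, b1])
                P = max(P, 1e-300)
                ll += c * np.log(P)
                g[a1, b1] += c * 2.0 * x[a2, b2] / P
                g[a2, b2] += c * 2.0 * x[a1, b1] / P
                g[a1, b2] += c * 2.0 * x[a2, b1] / P
                g[a2, b1] += c * 2.0 * x[a1, b2] / P
            else:
                same = (a1, b1) == (a2, b2)
                P = max((1.0 if same else 2.0) * x[a1, b1] * x[a2, b2], 1e-300)
                ll += c * np.log(P)
                if same:
                    g[a1, b1] += c * 2.0 / max(x[a1, b1], 1e-300)
                else:
                    g[a1, b1] += c / max(x[a1, b1], 1e-300)
                    g[a2, b2] += c / max(x[a2, b2], 1e-300)
        return -ll, -g.ravel()

    cons = {"type": "eq", "fun": lambda xf: xf.sum() - 1, "jac": lambda xf: np.ones_like(xf)}
    best = None
    for s in range(n_starts):
        x0 = np.full(dim, 1.0 / dim) if s == 0 else rng.dirichlet(np.ones(dim))
        r = minimize(nll_grad, x0, jac=True, method="SLSQP",
                     bounds=[(0.0, 1.0)] * dim, constraints=[cons],
                     options={"maxiter": 2000, "ftol": 1e-16})
        if best is None or r.fun < best.fun:
            best = r
    x = np.clip(best.x, 0.0, None)
    return (x / x.sum()).reshape(k, mm), -best.fun


class TestEM:
    def test_phase_determined_sample_counts_directly(self):
        # genotypes {(1,1;1,1) x2, (1,2;1,1), (1,1;1,2)}: no double hets
        genos = np.array(
            [
                [[1, 1], [1, 1]],
                [[1, 1], [1, 1]],
                [[1, 2], [1, 1]],
                [[1, 1], [1, 2]],
            ],
            dtype=np.int32,
        )
        gm = m.GenotypeMatrix(list("abcd"), ["A", "B"], genos)
        h = m.em_haplotype_frequencies(gm, "A", "B")
        expected = np.array([[0.75, 0.125], [0.125, 0.0]])
        assert np.allclose(h.x, expected, atol=1e-12)
        assert h.converged and not h.ambiguous

    @pytest.mark.parametrize("trial", range(5))
    def test_em_matches_simplex_search_mle(self, trial):
        rng = np.random.default_rng(100 + trial)
        k, mm = int(rng.integers(2, 4)), int(rng.integers(2, 4))
        x_true = rng.dirichlet(np.ones(k * mm)).reshape(k, mm)
        gm = m.make_genotype_fixture(x_true, 50, seed=int(rng.integers(10**6)))
        h = m.em_haplotype_frequencies(gm, "L1", "L2", tol=1e-13, max_iter=100000)
        xo, llo = simplex_search_mle(gm.genotypes[:, 0, :], gm.genotypes[:, 1, :], seed=trial)
        assert h.x.shape == xo.shape
        assert np.abs(h.x - xo).max() < 1e-6
        assert h.loglik >= llo - 1e-6

    def test_all_double_heterozygote_sample_is_flagged_ambiguous(self):
        genos = np.array([[[1, 2], [1, 2]]] * 6, dtype=np.int32)
        gm = m.GenotypeMatrix([f"i{i}" for i in range(6)], ["A", "B"], genos)
        h = m.em_haplotype_frequencies(gm, "A", "B")
        assert h.ambiguous
        assert np.allclose(h.p, [0.5, 0.5]) and np.allclose(h.q, [0.5, 0.5])
        assert np.isclose(h.x.sum(), 1.0)

    def test_loglik_trace_is_monotone_nondecreasing(self):
        gm = m.make_genotype_fixture(
            np.array([[0.3, 0.1], [0.1, 0.2], [0.1, 0.2]]), 80, seed=4
        )
        h = m.em_haplotype_frequencies(gm, "L1", "L2", track_loglik=True)
        trace = np.array(h.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_marginals_match_gene_counts_exactly(self):
        gm = m.make_genotype_fixture(
            np.array([[0.25, 0.25], [0.3, 0.2]]), 60, seed=9
        )
        h = m.em_haplotype_frequencies(gm, "L1", "L2")
        ga = gm.genotypes[:, 0, :].ravel()
        counts = np.bincount(ga)[1:]
        assert np.allclose(h.p, counts / counts.sum(), atol=1e-9)
        assert np.isclose(h.x.sum(), 1.0, atol=1e-9)

    def test_no_shared_individuals_raises(self):
        genos = np.array(
            [[[1, 1], [MISSING, MISSING]], [[MISSING, MISSING], [1, 2]]], dtype=np.int32
        )
        gm = m.GenotypeMatrix(["a", "b"], ["A", "B"], genos)
        with pytest.raises(ValueError, match="typed at both"):
            m.em_haplotype_frequencies(gm, "A", "B")


class TestDprime:
    def test_linkage_equilibrium_gives_zero(self):
        p, q = np.array([0.5, 0.3, 0.2]), np.array([0.6, 0.4])
        assert dprime(make_table(np.outer(p, q))) == pytest.approx(0.0, abs=1e-12)

    def test_complete_association_gives_one(self):
        assert dprime(make_table([[0.5, 0.0], [0.0, 0.5]])) == pytest.approx(1.0)

    def test_hand_evaluated_3x2_table(self):
        x = [[0.3, 0.1], [0.1, 0.2], [0.1, 0.2]]
        assert dprime(make_table(x)) == pytest.approx(0.4, abs=1e-12)

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            dprime(make_table([[0.6, 0.4]]))


class TestChi2prime:
    def test_linkage_equilibrium_gives_zero(self):
        p, q = np.array([0.4, 0.3, 0.3]), np.array([0.5, 0.5])
        assert chi2prime(make_table(np.outer(p, q))) == pytest.approx(0.0, abs=1e-12)

    def test_complete_ld_biallelic_gives_one(self):
        assert chi2prime(make_table([[0.5, 0.0], [0.0, 0.5]])) == pytest.approx(1.0)

    def test_hand_evaluated_3x2_table(self):
        x = [[0.3, 0.1], [0.1, 0.2], [0.1, 0.2]]
        assert chi2prime(make_table(x)) == pytest.approx(1.0 / 6.0, abs=1e-7)

    @given(st.integers(0, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_biallelic_equals_r_squared(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.ones(4)).reshape(2, 2)
        h = make_table(x)
        if h.p.min() < 1e-3 or h.q.min() < 1e-3:
            return
        D = x[0, 0] - h.p[0] * h.q[0]
        r2 = D * D / (h.p[0] * h.p[1] * h.q[0] * h.q[1])
        assert chi2prime(h) == pytest.approx(min(r2, 1.0), abs=1e-10)


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_relabeling_and_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k, mm = 3, 4
        x = rng.dirichlet(np.ones(k * mm)).reshape(k, mm)
        h = make_table(x)
        perm_r, perm_c = rng.permutation(k), rng.permutation(mm)
        h_perm = make_table(x[np.ix_(perm_r, perm_c)])
        h_swap = make_table(x.T)
        for stat in (dprime, chi2prime):
            assert stat(h) == pytest.approx(stat(h_perm), abs=1e-12)
            assert stat(h) == pytest.approx(stat(h_swap), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_statistics_bounded_on_em_output(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.ones(6)).reshape(3, 2)
        gm = m.make_genotype_fixture(x, 40, seed=seed)
        h = m.em_haplotype_frequencies(gm, "L1", "L2")
        if h.k >= 2 and h.m >= 2:
            assert 0.0 <= dprime(h) <= 1.0
            assert 0.0 <= chi2prime(h) <= 1.0

    def test_convergence_to_population_values_at_large_n(self):
        x_pop = np.array([[0.3, 0.1], [0.1, 0.2], [0.1, 0.2]])
        h_pop = make_table(x_pop)
        gm = m.make_genotype_fixture(x_pop, 10_000, seed=12)
        h = m.em_haplotype_frequencies(gm, "L1", "L2")
        # sampling error of each cell ~ sqrt(x(1-x)/2N) < 0.004; 3 SE bound
        assert dprime(h) == pytest.approx(dprime(h_pop), abs=0.02)
        assert chi2prime(h) == pytest.approx(chi2prime(h_pop), abs=0.02)


class TestPairwiseLD:
    @pytest.fixture()
    def four_marker_panel(self):
        lmap = m.LinkageMap(
            [Locus("a", 1, 0), Locus("b", 1, 10), Locus("c", 1, 60), Locus("d", 2, 0)]
        )
        rng = np.random.default_rng(0)
        genos = rng.integers(1, 4, size=(30, 4, 2)).astype(np.int32)
        gm = m.GenotypeMatrix([f"i{i}" for i in range(30)], ["a", "b", "c", "d"], genos)
        return gm, lmap

    def test_synteny_classification(self, four_marker_panel):
        gm, lmap = four_marker_panel
        pairs = m.pairwise_ld(gm, lmap)
        classes = {(p.locus_a, p.locus_b): p.synteny for p in pairs}
        assert classes[("a", "b")] == "syntenic_lt50"
        assert classes[("a", "c")] == "syntenic_ge50"   # 60 cM
        assert classes[("b", "c")] == "syntenic_ge50"   # 50 cM boundary
        assert sum(1 for v in classes.values() if v == "nonsyntenic") == 3

    def test_pair_count_is_all_combinations(self, four_marker_panel):
        gm, lmap = four_marker_panel
        assert len(m.pairwise_ld(gm, lmap)) == 6

    def test_syntenic_ld_exceeds_nonsyntenic_on_simulation(self, stable_pairs):
        syn = [p.chi2prime for p in stable_pairs if p.synteny == "syntenic_lt50" and p.defined]
        non = [p.chi2prime for p in stable_pairs if p.synteny == "nonsyntenic" and p.defined]
        assert np.mean(syn) > np.mean(non)

    def test_monomorphic_pair_recorded_not_fatal(self):
        lmap = m.LinkageMap([Locus("a", 1, 0), Locus("b", 1, 5)])
        genos = np.ones((10, 2, 2), dtype=np.int32)
        genos[:, 1, :] = np.random.default_rng(0).integers(1, 3, size=(10, 2))
        gm = m.GenotypeMatrix([f"i{i}" for i in range(10)], ["a", "b"], genos)
        pairs = m.pairwise_ld(gm, lmap)
        assert len(pairs) == 1 and not pairs[0].defined
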