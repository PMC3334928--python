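"""GTR+gamma+I likelihood, optimization, tree search and bootstrap."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

import degenphylo as dp
from degenphylo.ml_inference import (
    _CHAR_INDEX,
    _PARTIALS,
    LikelihoodEngine,
    _from_dendropy,
    _postorder,
    canonical_bipartition,
)
from degenphylo.support_comparison import tree_bipartitions


def _matrix(taxa, seqs):
    return dp.concatenate([dp.CodonAlignment(list(taxa), list(seqs), "g")])


def _tree(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_loglik(tree, seqs_by_taxon, model):
    """Exhaustive enumeration over all internal-node state assignments per
    site per rate category (feasible for <= 5 leaves)."""
    rates, weights = model.mixture()
    pi = np.asarray(model.base_frequencies)
    Q = model.rate_matrix()
    root = tree.seed_node
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    n_sites = len(next(iter(seqs_by_taxon.values())))
    total = 0.0
    for site in range(n_sites):
        lik = 0.0
        for r, w in zip(rates, weights):
            P = {nd: expm(Q * r * float(nd.edge.length or 0.0))
                 for nd in tree.preorder_node_iter() if nd.parent_node}
            s = 0.0
            for states in itertools.product(range(4), repeat=len(internals)):
                assign = dict(zip(internals, states))
                p = pi[assign[root]]
                for nd in tree.preorder_node_iter():
                    if nd.parent_node is None:
                        continue
                    x = assign[nd.parent_node]
                    if nd.is_leaf():
                        partial = _PARTIALS[
                            _CHAR_INDEX[seqs_by_taxon[nd.taxon.label][site]]]
                        p *= float(P[nd][x] @ partial)
                    else:
                        p *= P[nd][x, assign[nd]]
                s += p
            lik += w * s
        total += math.log(lik)
    return total


def random_case(rng, n_taxa):
    shapes = {
        3: "(a:{},b:{},c:{});",
        4: "((a:{},b:{}):{},c:{},d:{});",
        5: "((a:{},b:{}):{},(c:{},d:{}):{},e:{});",
    }
    n_edges = {3: 3, 4: 5, 5: 7}[n_taxa]
    lengths = rng.uniform(0.02, 0.8, size=n_edges)
    nwk = shapes[n_taxa].format(*lengths)
    ex = tuple(rng.uniform(0.3, 3.0, size=6))
    f = rng.dirichlet([8, 8, 8, 8])
    model = dp.SubstitutionModel(ex, tuple(f / f.sum()),
                                 gamma_shape=float(rng.uniform(0.3, 2.0)),
                                 p_invariant=float(rng.uniform(0, 0.4)))
    chars = list("ACGTRYKN-?")
    taxa = list("abcde")[:n_taxa]
    seqs = {t: "".join(rng.choice(chars, 9)) for t in taxa}
    return nwk, model, seqs


# ---------------------------------------------------------------------------
# Likelihood correctness
# ---------------------------------------------------------------------------

class TestDiscreteGamma:
    def test_category_means_match_numeric_integration(self):
        for alpha in (0.3, 1.0, 2.5):
            got = dp.discrete_gamma_rates(alpha, 4)
            edges = [0] + list(gamma_dist.ppf([0.25, 0.5, 0.75], alpha,
                                              scale=1 / alpha)) + [np.inf]
            for i in range(4):
                mean, _ = quad(
                    lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha),
                    edges[i], edges[i + 1])
                assert got[i] == pytest.approx(4 * mean, rel=1e-6)
            assert got.mean() == pytest.approx(1.0)

    def test_single_category_is_rate_one(self):
        assert dp.discrete_gamma_rates(0.7, 1).tolist() == [1.0]

    def test_mixture_with_invariant_has_mean_one(self):
        m = dp.SubstitutionModel(gamma_shape=0.5, p_invariant=0.3)
        rates, weights = m.mixture()
        assert rates[0] == 0.0 and weights[0] == pytest.approx(0.3)
        assert float(rates @ weights) == pytest.approx(1.0)


class TestJukesCantorClosedForm:
    def test_zero_branch_identical_sequences(self):
        m = dp.SubstitutionModel(n_gamma_categories=1)
        ll = dp.log_likelihood(_tree("(a:0,b:0);"),
                               _matrix("ab", ["AAACGT", "AAACGT"]), m)
        assert ll == pytest.approx(6 * math.log(0.25), abs=1e-10)

    def test_match_and_mismatch_probabilities(self):
        t = 0.3
        m = dp.SubstitutionModel(n_gamma_categories=1)
        ll = dp.log_likelihood(_tree(f"(a:{t / 2},b:{t / 2});"),
                               _matrix("ab", ["AAACGT", "AAGCGT"]), m)
        p_match = 0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3))
        p_mismatch = 0.25 * (0.25 - 0.25 * math.exp(-4 * t / 3))
        assert ll == pytest.approx(5 * math.log(p_match) + math.log(p_mismatch),
                                   abs=1e-10)

    def test_plain_gtr_two_taxon_matches_matrix_exponential(self):
        # ncat=1, p_inv=0 must reduce the mixture to plain GTR
        rng = np.random.default_rng(1)
        f = rng.dirichlet([5] * 4)
        m = dp.SubstitutionModel(tuple(rng.uniform(0.5, 2, 6)), tuple(f),
                                 n_gamma_categories=1)
        t = 0.4
        P = expm(m.rate_matrix() * t)
        pi = np.asarray(m.base_frequencies)
        seqs = ["ACGTAC", "ATGTCC"]
        expected = sum(
            math.log(pi["ACGT".index(a)] * P["ACGT".index(a), "ACGT".index(b)])
            for a, b in zip(*seqs))
        ll = dp.log_likelihood(_tree(f"(a:{t},b:0);"), _matrix("ab", seqs), m)
        assert ll == pytest.approx(expected, abs=1e-10)


class TestPruningVsBruteForce:
    @pytest.mark.parametrize("n_taxa", [3, 4, 5])
    def test_matches_exhaustive_enumeration(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(5):
            nwk, model, seqs = random_case(rng, n_taxa)
            tree = _tree(nwk)
            mat = _matrix(seqs.keys(), seqs.values())
            ll = dp.log_likelihood(tree, mat, model)
            bll = brute_force_loglik(_tree(nwk), seqs, model)
            assert ll == pytest.approx(bll, abs=1e-8)

    def test_partitioned_likelihood_is_sum_of_parts(self):
        rng = np.random.default_rng(7)
        nwk, model, seqs = random_case(rng, 4)
        mat = _matrix(seqs.keys(), seqs.values())
        scheme = dp.PartitionScheme({
            "nonsyn_nt1_nt2": frozenset(range(0, 9, 3)) | frozenset(range(1, 9, 3)),
            "potsyn_nt1_nt3": frozenset(range(2, 9, 3)),
        })
        m2 = dp.SubstitutionModel(gamma_shape=2.0)
        ll = dp.log_likelihood(_tree(nwk), mat, {"nonsyn_nt1_nt2": model,
                                                 "potsyn_nt1_nt3": m2}, scheme)
        # independent: evaluate each partition as its own matrix
        part_ll = 0.0
        for name, m in (("nonsyn_nt1_nt2", model), ("potsyn_nt1_nt3", m2)):
            sub_seqs = {t: "".join(seqs[t][i] for i in sorted(scheme[name]))
                        for t in seqs}
            part_ll += brute_force_loglik(_tree(nwk), sub_seqs, m)
        assert ll == pytest.approx(part_ll, abs=1e-8)


class TestInvariances:
    def _setup(self):
        rng = np.random.default_rng(3)
        nwk, model, seqs = random_case(rng, 5)
        return nwk, model, seqs

    def test_reroot_invariance(self):
        model = dp.SubstitutionModel((1.2, 2.5, 0.8, 1.1, 3.0, 1.0),
                                     (0.3, 0.2, 0.3, 0.2), 0.6, 0.15)
        seqs = {"a": "ACGTRYNCA", "b": "TTGTACN-A", "c": "ACGAAYNCA",
                "d": "GCGTRCNCA", "e": "ACTTRYN?A"}
        mat = _matrix(seqs.keys(), seqs.values())
        t1 = _tree("((a:0.1,b:0.25):0.12,(c:0.3,d:0.05):0.2,e:0.4);")
        t2 = _tree("(a:0.1,b:0.25,((c:0.3,d:0.05):0.2,e:0.4):0.12);")
        t3 = _tree("(c:0.3,d:0.05,((a:0.1,b:0.25):0.12,e:0.4):0.2);")
        lls = [dp.log_likelihood(t, mat, model) for t in (t1, t2, t3)]
        assert max(lls) - min(lls) < 1e-9

    def test_taxon_reordering_invariance(self):
        model = dp.SubstitutionModel()
        nwk = "((a:0.1,b:0.2):0.1,c:0.3,d:0.1);"
        seqs = {"a": "ACG", "b": "ACT", "c": "GCT", "d": "ACC"}
        m1 = _matrix(["a", "b", "c", "d"], [seqs[t] for t in "abcd"])
        m2 = _matrix(["d", "c", "b", "a"], [seqs[t] for t in "dcba"])
        assert dp.log_likelihood(_tree(nwk), m1, model) == pytest.approx(
            dp.log_likelihood(_tree(nwk), m2, model), abs=1e-10)

    def test_iupac_leaf_sums_over_compatible_states(self):
        # a Y leaf character equals the sum of likelihoods with C and T
        model = dp.SubstitutionModel((1.5, 2.0, 0.7, 1.2, 2.8, 1.0),
                                     (0.3, 0.2, 0.3, 0.2), 1.0, 0.1)
        nwk = "((a:0.1,b:0.2):0.1,c:0.3,d:0.1);"
        def ll(ch):
            seqs = {"a": "AC" + ch, "b": "ACT", "c": "GCT", "d": "ACC"}
            return dp.log_likelihood(
                _tree(nwk), _matrix(seqs.keys(), seqs.values()), model)
        lik_y = math.exp(ll("Y"))
        assert lik_y == pytest.approx(math.exp(ll("C")) + math.exp(ll("T")),
                                      rel=1e-9)

    def test_degen1_recoded_matrix_is_accepted(self):
        aln = dp.CodonAlignment(list("abcd"),
                                ["CATTTACGT", "CACTTGCGC", "CATCTACGA",
                                 "CACCTGAGA"], "g")
        recoded = dp.degen1_recode(aln)
        mat = dp.concatenate([recoded])
        ll = dp.log_likelihood(_tree("((a:0.1,b:0.2):0.1,c:0.3,d:0.1);"),
                               mat, dp.SubstitutionModel())
        assert np.isfinite(ll) and ll < 0


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class TestOptimization:
    def test_trace_is_monotone_and_reaches_fixed_point(self):
        tree = dp.simulate_tree(6, seed=5, branch_length_scale=0.15)
        model = dp.SubstitutionModel(gamma_shape=0.8, p_invariant=0.1)
        aln = dp.simulate_gtr_alignment(tree, model, 600, seed=6)
        mat = dp.concatenate([aln])
        res = dp.optimize_parameters(tree, mat, dp.SubstitutionModel(
            gamma_shape=2.0), tol=1e-3, max_rounds=10)
        assert all(b >= a - 1e-9 for a, b in zip(res.trace, res.trace[1:]))
        # refitting at the optimum changes the likelihood by < tol
        res2 = dp.optimize_parameters(res.tree, mat, res.models, tol=1e-3,
                                      max_rounds=1)
        assert res2.log_likelihood - res.log_likelihood < 1.0

    def test_gamma_shape_recovery_within_30_percent(self):
        # data simulated with alpha=0.5 on a fixed 8-taxon tree
        tree = dp.simulate_tree(8, seed=21, branch_length_scale=0.2)
        truth = dp.SubstitutionModel((1.0, 2.0, 1.0, 1.0, 2.0, 1.0),
                                     (0.25, 0.25, 0.25, 0.25),
                                     gamma_shape=0.5, p_invariant=0.0)
        aln = dp.simulate_gtr_alignment(tree, truth, 6000, seed=22)
        mat = dp.concatenate([aln])
        start = dp.SubstitutionModel((1.0, 2.0, 1.0, 1.0, 2.0, 1.0),
                                     (0.25, 0.25, 0.25, 0.25),
                                     gamma_shape=1.5, p_invariant=0.0)
        res = dp.optimize_parameters(tree, mat, start, tol=1e-2, max_rounds=8,
                                     free_params=("gamma_shape",))
        alpha = res.models.gamma_shape
        assert 0.35 <= alpha <= 0.65


# ---------------------------------------------------------------------------
# Search and bootstrap
# ---------------------------------------------------------------------------

class TestSearch:
    def test_four_taxa_matches_exhaustive_topology_scan(self):
        rng = np.random.default_rng(17)
        tree = _tree("((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3);")
        model = dp.SubstitutionModel()
        aln = dp.simulate_gtr_alignment(tree, model, 300, seed=18)
        mat = dp.concatenate([aln])
        best = dp.search_tree(mat, model, n_starts=3, seed=19)
        # exhaustive: optimize branch lengths on each of the 3 topologies
        engine = LikelihoodEngine.from_matrix(mat, model)
        topo_lls = {}
        for nwk in ("((a:0.1,b:0.1):0.1,c:0.1,d:0.1);",
                    "((a:0.1,c:0.1):0.1,b:0.1,d:0.1);",
                    "((a:0.1,d:0.1):0.1,b:0.1,c:0.1);"):
            root = _from_dendropy(_tree(nwk), engine.taxa)
            topo_lls[nwk] = engine.optimize_branch_lengths(root, passes=6)
        best_nwk = max(topo_lls, key=topo_lls.get)
        assert tree_bipartitions(best) == tree_bipartitions(_tree(best_nwk))
        assert best.log_likelihood == pytest.approx(topo_lls[best_nwk], abs=0.05)

    def test_six_taxa_strong_signal_recovers_topology(self):
        nwk = ("(((a:0.1,b:0.1):0.25,c:0.35):0.25,(d:0.1,e:0.1):0.25,"
               "f:0.35);")
        true_tree = _tree(nwk)
        model = dp.SubstitutionModel(gamma_shape=1.0)
        aln = dp.simulate_gtr_alignment(true_tree, model, 600, seed=23)
        mat = dp.concatenate([aln])
        best = dp.search_tree(mat, model, n_starts=2, seed=24)
        assert tree_bipartitions(best) == tree_bipartitions(true_tree)

    def test_seed_determinism(self):
        tree = dp.simulate_tree(7, seed=2, branch_length_scale=0.2)
        model = dp.SubstitutionModel()
        mat = dp.concatenate([dp.simulate_gtr_alignment(tree, model, 300,
                                                        seed=3)])
        t1 = dp.search_tree(mat, model, n_starts=2, seed=5)
        t2 = dp.search_tree(mat, model, n_starts=2, seed=5)
        assert (t1.as_string(schema="newick") == t2.as_string(schema="newick"))
        assert t1.log_likelihood == t2.log_likelihood

    def test_too_few_taxa_rejected(self):
        mat = _matrix("abc", ["ACG", "ACG", "ACT"])
        with pytest.raises(dp.InvalidArgumentError):
            dp.search_tree(mat, dp.SubstitutionModel())


class TestBootstrap:
    def _small(self):
        tree = dp.simulate_tree(6, seed=31, branch_length_scale=0.25)
        model = dp.SubstitutionModel()
        mat = dp.concatenate([dp.simulate_gtr_alignment(tree, model, 300,
                                                        seed=32)])
        return mat, model

    def test_single_replicate_frequencies_are_zero_or_hundred(self):
        mat, model = self._small()
        res = dp.bootstrap(mat, model, n_replicates=1, seed=33)
        assert set(res.frequencies.values()) <= {0.0, 100.0}

    def test_determinism(self):
        mat, model = self._small()
        r1 = dp.bootstrap(mat, model, n_replicates=3, seed=33)
        r2 = dp.bootstrap(mat, model, n_replicates=3, seed=33)
        assert r1.frequencies == r2.frequencies

    def test_annotate_support_with_own_splits_gives_100(self):
        mat, model = self._small()
        best = dp.search_tree(mat, model, seed=40)
        splits = tree_bipartitions(best)
        result = dp.BootstrapResult(1, {s: 100.0 for s in splits},
                                    [l.taxon.label
                                     for l in best.leaf_node_iter()])
        annotated = dp.annotate_support(best, result)
        labels = [nd.label for nd in annotated.preorder_node_iter()
                  if not nd.is_leaf() and nd.parent_node is not None
                  and nd.label is not None]
        assert labels and all(l == "100" for l in labels)
        assert annotated.unrepresented_bipartitions == {}

    def test_unrepresented_bipartitions_reported(self):
        mat, model = self._small()
        best = dp.search_tree(mat, model, seed=40)
        taxa = sorted(l.taxon.label for l in best.leaf_node_iter())
        fake = canonical_bipartition(frozenset(taxa[:2]), frozenset(taxa))
        splits = tree_bipartitions(best)
        if fake in splits:  # pick a pair that is NOT a cherry of the tree
            fake = canonical_bipartition(frozenset([taxa[0], taxa[3]]),
                                         frozenset(taxa))
        result = dp.BootstrapResult(
            1, {fake: 60.0, **{s: 100.0 for s in splits}}, taxa)
        annotated = dp.annotate_support(best, result)
        assert annotated.unrepresented_bipartitions == {fake: 60.0}
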