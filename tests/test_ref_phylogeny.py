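import itertools
import math

import numpy as np
import pytest

from phylotu import evo_models as em
from phylotu import ref_phylogeny as rp
from phylotu.formats import Msa, SeqRecord, parse_newick
from phylotu.synthetic_data import make_toy_reference


class TestConvolute:
    def test_identity_matrix_is_noop(self):
        rng = np.random.default_rng(0)
        L = rng.normal(-5, 2, size=(4, 20))
        out = rp.convolute(L, np.eye(4))
        assert np.allclose(out, L)

    def test_one_hot_column_gives_log_p_row(self, gtr_model):
        P = em.transition_matrix(gtr_model, 0.1)
        L = np.full((4, 1), -np.inf)
        L[0, 0] = 0.0  # certain 'A'
        out = rp.convolute(L, P)
        assert np.allclose(out[:, 0], np.log(P[:, 0]))

    def test_matches_linear_space_oracle(self, gtr_model):
        rng = np.random.default_rng(1)
        P = em.transition_matrix(gtr_model, 0.3)
        L = rng.uniform(-30, 0, size=(4, 50))
        out = rp.convolute(L, P)
        naive = np.log(P @ np.exp(L))
        assert np.allclose(out, naive, atol=1e-10)

    def test_extreme_magnitudes_stay_finite(self, gtr_model):
        P = em.transition_matrix(gtr_model, 0.2)
        L = np.full((4, 3), -1e4)
        L[1] = -9990.0
        out = rp.convolute(L, P)
        assert np.all(np.isfinite(out))
        assert np.allclose(out[:, 0], -9990 + np.log(P[:, 1]), atol=1e-6)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            rp.convolute(np.zeros((4, 2)), np.ones((4, 4)))


def brute_force_loglik(tree, site):
    """Exhaustive sum over all ancestral-state assignments at one site."""
    model = tree.model
    internal = [n.id for n in tree.nodes if not n.is_leaf]
    Pm = {v: em.transition_matrix(model, tree.nodes[v].length)
          for v in tree.branches()}
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = model.pi[amap[0]]
        for v in tree.branches():
            node = tree.nodes[v]
            if node.is_leaf:
                b = tree.leaf_states[v][site]
                p *= 1.0 if b == 4 else Pm[v][amap[node.parent], b]
            else:
                p *= Pm[v][amap[node.parent], amap[v]]
        total += p
    return math.log(total)


class TestEvaluate:
    def test_two_identical_leaves_zero_branches(self, gtr_model):
        spec = parse_newick("(A:0.0,B:0.0);")
        t = rp.PhyloTree.from_treespec(spec, {"A": "A", "B": "A"},
                                       model=gtr_model)
        ll = t.evaluate()
        assert ll == pytest.approx(math.log(gtr_model.pi[0]), abs=1e-9)

    @pytest.mark.parametrize("model_name", ["GTR", "TN93", "HKY85"])
    def test_matches_exhaustive_enumeration(self, model_name):
        pkg, truth = make_toy_reference(n_leaves=5, S=50, seed=5,
                                        model_name=model_name)
        seqs = {k: v[:10] for k, v in pkg.tree.leaf_seqs.items()}
        t = rp.PhyloTree.from_treespec(truth["treespec"], seqs,
                                       model=truth["model"])
        ll = t.evaluate()
        brute = sum(brute_force_loglik(t, s) for s in range(10))
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_pulley_rerooting_invariance(self, toy_pkg):
        pkg, _ = toy_pkg
        tree = pkg.tree
        for v in tree.branches():
            assert tree.loglik_at(v) == pytest.approx(tree.loglik, abs=1e-6)

    def test_missing_model_rejected(self, gtr_model):
        spec = parse_newick("(A:0.1,B:0.1);")
        t = rp.PhyloTree.from_treespec(spec, {"A": "A", "B": "C"})
        with pytest.raises(rp.TreeError):
            t.evaluate()

    def test_dgamma_k1_equals_fixed_rate(self, tiny_pkg):
        pkg, truth = tiny_pkg
        fixed = pkg.tree.loglik
        t2 = rp.PhyloTree.from_treespec(truth["treespec"], pkg.tree.leaf_seqs,
                                        model=pkg.tree.model,
                                        dgamma=em.discretize_gamma(0.5, 1))
        assert t2.evaluate() == pytest.approx(fixed, abs=1e-12)

    def test_dgamma_changes_likelihood(self, tiny_pkg):
        pkg, truth = tiny_pkg
        t2 = rp.PhyloTree.from_treespec(truth["treespec"], pkg.tree.leaf_seqs,
                                        model=pkg.tree.model,
                                        dgamma=em.discretize_gamma(0.5, 4))
        assert t2.evaluate() != pytest.approx(pkg.tree.loglik, abs=1e-9)


class TestAncestralInference:
    def test_identical_leaves_propagate(self, gtr_model):
        spec = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        seqs = {k: "ACGT" for k in "ABCD"}
        t = rp.PhyloTree.from_treespec(spec, seqs, model=gtr_model)
        t.evaluate()
        t.infer_ancestral_sequences()
        for node in t.nodes:
            if not node.is_leaf:
                assert t.node_states[node.id] == "ACGT"

    def test_majority_pair_wins(self, gtr_model):
        spec = parse_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        t = rp.PhyloTree.from_treespec(
            spec, {"A": "A", "B": "A", "C": "C"}, model=gtr_model)
        t.evaluate()
        t.infer_ancestral_sequences()
        # the ancestor of the two 'A' leaves is 'A' under any sensible model
        anc = next(n.id for n in t.nodes
                   if not n.is_leaf and n.parent == 0)
        assert t.node_states[anc] == "A"

    def test_all_gap_sites_stay_gaps(self, gtr_model):
        spec = parse_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        t = rp.PhyloTree.from_treespec(
            spec, {"A": "A-G", "B": "A-G", "C": "A-G"}, model=gtr_model)
        t.evaluate()
        t.infer_ancestral_sequences()
        for node in t.nodes:
            if not node.is_leaf:
                assert t.node_states[node.id][1] == "-"

    def test_unevaluated_tree_rejected(self, gtr_model):
        spec = parse_newick("(A:0.1,B:0.1);")
        t = rp.PhyloTree.from_treespec(spec, {"A": "A", "B": "C"},
                                       model=gtr_model)
        with pytest.raises(rp.TreeError):
            t.infer_ancestral_sequences()


class TestTaxonomy:
    def _tree(self, gtr_model):
        spec = parse_newick("((A:0.1,B:0.1)N1:0.1,(C:0.1,D:0.1):0.1)root;")
        t = rp.PhyloTree.from_treespec(spec, {k: "ACGT" for k in "ABCD"},
                                       model=gtr_model)
        return t

    def test_unnamed_nodes_inherit(self, gtr_model):
        t = self._tree(gtr_model)
        t.propagate_taxonomy({"root": "k__K", "N1": "k__K;p__P",
                              "A": "k__K;p__P;c__C"})
        by_name = {n.name: n.taxonomy for n in t.nodes}
        assert by_name["B"] == "k__K;p__P"      # inherits from N1
        assert by_name["C"] == "k__K"           # inherits through unnamed node
        assert by_name["A"] == "k__K;p__P;c__C"  # keeps its own

    def test_chain_of_unnamed_nodes(self, gtr_model):
        spec = parse_newick("(((A:0.1,B:0.1):0.1,C:0.1):0.1,D:0.1)root;")
        t = rp.PhyloTree.from_treespec(spec, {k: "ACGT" for k in "ABCD"},
                                       model=gtr_model)
        t.propagate_taxonomy({"root": "o__Y"})
        assert all(n.taxonomy == "o__Y" for n in t.nodes)

    def test_unannotated_root_rejected(self, gtr_model):
        t = self._tree(gtr_model)
        with pytest.raises(rp.TreeError):
            t.propagate_taxonomy({"A": "k__K"})


class TestCanonicalization:
    def test_multifurcation_split(self, gtr_model):
        spec = parse_newick("(A:0.1,B:0.1,C:0.1,D:0.1);")
        t = rp.PhyloTree.from_treespec(spec, {k: "ACGT" for k in "ABCD"},
                                       model=gtr_model)
        for node in t.nodes:
            assert len(node.children) in (0, 2)
        # zero-length connectors keep total path lengths unchanged
        t.evaluate()
        d = t.path_lengths_from(
            next(n.id for n in t.nodes if n.name == "A"))
        for name in "BCD":
            leaf = next(n.id for n in t.nodes if n.name == name)
            assert d[leaf] == pytest.approx(0.2)


class TestReferencePackage:
    def test_consistency_and_metadata(self, toy_pkg):
        pkg, _ = toy_pkg
        assert pkg.profile.K == pkg.tree.S
        assert pkg.index.n == pkg.profile.K
        assert pkg.metadata["model"] == "GTR"

    def test_orphan_leaves_rejected(self, gtr_model):
        spec = parse_newick("(A:0.1,B:0.1);")
        msa = Msa(records=[SeqRecord(id="A", seq="ACGT")])
        with pytest.raises(rp.TreeError, match="B"):
            rp.build_reference_package(msa, spec, {"root": "k__K"},
                                       model=gtr_model)

    def test_save_load_round_trip(self, toy_pkg, tmp_path):
        pkg, _ = toy_pkg
        p1 = tmp_path / "pkg.json"
        p2 = tmp_path / "pkg2.json"
        rp.save_reference_package(pkg, p1)
        back = rp.load_reference_package(p1)
        assert back.tree.loglik == pytest.approx(pkg.tree.loglik, abs=1e-9)
        assert back.profile.K == pkg.profile.K
        rp.save_reference_package(back, p2)
        assert p1.read_text() == p2.read_text()

    def test_rebuild_is_deterministic(self):
        from phylotu.synthetic_data import make_toy_reference
        import json

        a, _ = make_toy_reference(n_leaves=6, S=60, seed=9)
        b, _ = make_toy_reference(n_leaves=6, S=60, seed=9)
        assert a.tree.loglik == b.tree.loglik
        assert a.msa.consensus == b.msa.consensus

    def test_dgamma_flag_effect(self):
        pkg_f, truth = make_toy_reference(n_leaves=6, S=80, seed=10)
        msa = pkg_f.msa
        pkg_g = rp.build_reference_package(
            msa, truth["treespec"], truth["taxonomy"],
            model=truth["model"], dgamma=True)
        assert [n.name for n in pkg_g.tree.nodes] == \
            [n.name for n in pkg_f.tree.nodes]
        if pkg_g.metadata.get("gamma_shape") is not None:
            assert pkg_g.tree.loglik != pytest.approx(pkg_f.tree.loglik,
                                                      abs=1e-9)
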