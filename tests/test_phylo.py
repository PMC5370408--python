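"""Alignment, trimming, distances, NJ, bootstrap, clades, congruence."""

import numpy as np
import pytest

from aarscreen import phylo as P
from aarscreen import synthetic_data as S
from aarscreen.aars import pairwise_similarity, alignment_stats
from aarscreen.tree import Tree, random_topology


def family_msa(fam):
    return P.MSA([i for i, _ in fam.records], dict(fam.records))


class TestProgressiveAlignment:
    def test_two_identical_sequences_align_gapless(self):
        msa = P.align_progressive([("a", "MKLV" * 20), ("b", "MKLV" * 20)])
        assert "-" not in msa.rows["a"] + msa.rows["b"]
        assert msa.ncol == 80

    def test_single_sequence_is_trivial_msa(self):
        msa = P.align_progressive([("only", "MKLVDE")])
        assert msa.rows == {"only": "MKLVDE"}

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            P.align_progressive([("a", "MKL"), ("a", "MKV")])

    def test_ungapping_recovers_inputs(self, rng):
        fam = S.generate_protein_family(
            S.ProteinFamilySpec("F", 6, 150, subs_per_site=0.2, seed=1))
        msa = P.align_progressive(fam.records)
        for rid, seq in fam.records:
            assert msa.ungapped(rid) == seq

    def test_input_order_invariance(self):
        fam = S.generate_protein_family(
            S.ProteinFamilySpec("F", 6, 120, subs_per_site=0.15, seed=2))
        msa1 = P.align_progressive(fam.records)
        msa2 = P.align_progressive(list(reversed(fam.records)))
        assert msa1.rows == msa2.rows

    def test_pair_identity_close_to_pairwise_dp_baseline(self):
        fam = S.generate_protein_family(
            S.ProteinFamilySpec("F", 8, 200, subs_per_site=0.05, seed=3))
        msa = P.align_progressive(fam.records)
        ids = msa.ids
        ok = total = 0
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                total += 1
                cols = [(x, y) for x, y in zip(msa.rows[a], msa.rows[b])
                        if x != "-" and y != "-"]
                msa_ident = sum(x == y for x, y in cols) / max(len(cols), 1)
                dp_ident = alignment_stats(msa.ungapped(a),
                                           msa.ungapped(b)).identity
                ok += msa_ident >= dp_ident - 0.02
        assert ok / total >= 0.95


class TestTrimToCore:
    def make_msa(self, high_col=40, ncol=320, nrow=5):
        rng = np.random.default_rng(9)
        rows = {}
        for r in range(nrow):
            row = list("".join(rng.choice(list("ACDEFGIKLMNPQRSTVY"), ncol)))
            row[high_col - 1:high_col + 3] = list("HIGH")
            rows[f"r{r}"] = "".join(row)
        return P.MSA(sorted(rows), rows)

    def test_window_starts_13_columns_upstream_of_high(self):
        msa = self.make_msa(high_col=40)
        trimmed = P.trim_to_core(msa, P.TrimConfig(upstream_residues=13,
                                                   abd_end=300))
        # original column 27 (1-based) must be the new first column
        assert trimmed.rows["r0"] == msa.rows["r0"][26:300]
        assert trimmed.high_anchor_cols[0] == 13

    def test_zero_upstream_starts_at_the_high_column(self):
        msa = self.make_msa(high_col=40)
        trimmed = P.trim_to_core(msa, P.TrimConfig(upstream_residues=0,
                                                   abd_end=300))
        assert trimmed.rows["r0"].startswith("HIGH")

    def test_clamped_at_first_column(self):
        msa = self.make_msa(high_col=5)
        trimmed = P.trim_to_core(msa, P.TrimConfig(upstream_residues=13,
                                                   abd_end=200))
        assert trimmed.rows["r0"] == msa.rows["r0"][:200]

    def test_gap_free_window_loses_no_columns(self):
        msa = self.make_msa()
        trimmed = P.trim_to_core(msa, P.TrimConfig(abd_end=300))
        assert trimmed.ncol == 300 - 27 + 1

    def test_mostly_gapped_columns_removed_but_never_anchors(self):
        msa = self.make_msa(nrow=4)
        rows = {k: v[:60] + "-" * 10 + v[70:] for k, v in msa.rows.items()}
        rows["r0"] = msa.rows["r0"]   # one row keeps residues there
        gappy = P.MSA(sorted(rows), rows)
        trimmed = P.trim_to_core(gappy, P.TrimConfig(abd_end=300))
        assert trimmed.ncol == 300 - 27 + 1 - 10
        joined = trimmed.rows["r0"]
        assert "HIGH" in joined

    def test_no_high_anchor_errors(self):
        rows = {"a": "ACDEF" * 30, "b": "ACDEF" * 30}
        with pytest.raises(ValueError, match="HIGH"):
            P.trim_to_core(P.MSA(["a", "b"], rows), P.TrimConfig(abd_end=100))

    def test_abd_end_from_reference_row(self):
        msa = self.make_msa()
        trimmed = P.trim_to_core(msa, P.TrimConfig(abd_end="infer_from_reference"),
                                 reference_row="r0", reference_abd_end=250)
        assert trimmed.ncol == 250 - 27 + 1
        with pytest.raises(ValueError, match="abd_end"):
            P.trim_to_core(msa, P.TrimConfig(abd_end="infer_from_reference"))


class TestDistances:
    def test_identical_rows_give_zero(self):
        msa = P.MSA(["a", "b", "c"], {k: "MKLV" * 30 for k in "abc"})
        D, _ = P.distance_matrix(msa)
        assert np.allclose(D, 0)

    def test_poisson_correction_closed_form(self):
        base = "A" * 100
        mutated = "C" * 10 + "A" * 90     # p = 0.10
        msa = P.MSA(["a", "b", "c"], {"a": base, "b": mutated, "c": base})
        D, ids = P.distance_matrix(msa)
        assert D[0, 1] == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_insufficient_overlap_names_the_pair(self):
        rows = {"a": "MKLVDEAGHT" + "-" * 90,
                "b": "-" * 90 + "MKLVDEAGHT",
                "c": "M" * 100}
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            P.distance_matrix(P.MSA(["a", "b", "c"], rows))

    def test_matrix_equals_naive_double_loop_oracle(self, rng):
        fam = S.generate_protein_family(
            S.ProteinFamilySpec("F", 6, 100, subs_per_site=0.2, seed=4))
        msa = family_msa(fam)
        D, ids = P.distance_matrix(msa)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                ra, rb = msa.rows[a], msa.rows[b]
                shared = [(x, y) for x, y in zip(ra, rb)
                          if x != "-" and y != "-"]
                p = sum(x != y for x, y in shared) / len(shared)
                assert D[i, j] == pytest.approx(-np.log(1 - min(p, 0.95)))

    def test_saturation_capped_with_warning(self):
        rows = {"a": "A" * 100, "b": "C" * 100, "c": "A" * 100}
        with pytest.warns(UserWarning, match="capped"):
            D, _ = P.distance_matrix(P.MSA(["a", "b", "c"], rows))
        assert D[0, 1] == pytest.approx(-np.log(0.05))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = P.nj_tree(D, ["a", "b", "c"])
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_additive_four_taxa_topology_recovered(self):
        # tree ((a,b),(c,d)) with internal branch 1.0
        D = np.array([[0, 2, 5, 6], [2, 0, 5, 6], [5, 5, 0, 3], [6, 6, 3, 0]],
                     float)
        tree = P.nj_tree(D, ["a", "b", "c", "d"])
        assert tree.bipartitions() == {frozenset({"c", "d"})}

    def test_additive_matrices_recover_random_topologies(self, rng):
        for trial in range(50):
            n = int(rng.integers(5, 13))
            true = random_topology([f"L{i:02d}" for i in range(n)], rng)
            for node in true.preorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.1, 1.0))
            labels = sorted(true.leaf_labels())
            D = np.array([[0.0 if a == b else true.path_length(a, b)
                           for b in labels] for a in labels])
            est = P.nj_tree(D, labels)
            assert est.bipartitions() == true.bipartitions()

    def test_nj_agrees_with_least_squares_on_four_taxa(self, rng):
        splits = [frozenset({"c", "d"}), frozenset({"b", "d"}),
                  frozenset({"b", "c"})]
        # design matrices: distances (ab,ac,ad,bc,bd,cd) vs 5 branches
        designs = {}
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for split in splits:
            groups = {"a": 0, "b": 1, "c": 2, "d": 3}
            sp = {groups[x] for x in split}
            rows = []
            for i, j in pairs:
                row = [0] * 5
                row[i], row[j] = 1, 1
                crosses = ((i in sp) != (j in sp))
                row[4] = 1 if crosses else 0
                rows.append(row)
            designs[split] = np.array(rows, float)
        agree = 0
        trials = 60
        for _ in range(trials):
            # noisy-additive distances: a random 4-taxon tree plus
            # perturbation smaller than the internal branch
            perm = rng.permutation(4)
            ext = rng.uniform(0.1, 1.0, 4)
            internal = rng.uniform(0.1, 0.6)
            side = {int(perm[0]), int(perm[1])}
            D = np.zeros((4, 4))
            for i, j in pairs:
                d0 = ext[i] + ext[j] + (internal if (i in side) != (j in side)
                                        else 0.0)
                D[i, j] = D[j, i] = max(d0 + rng.normal(0, 0.03), 0.01)
            d = np.array([D[i, j] for i, j in pairs])
            sses = {}
            for split, X in designs.items():
                beta, *_ = np.linalg.lstsq(X, d, rcond=None)
                sses[split] = float(((X @ beta - d) ** 2).sum())
            best = min(sses, key=lambda s: (sses[s], sorted(s)))
            nj_split = next(iter(P.nj_tree(D, ["a", "b", "c", "d"])
                                 .bipartitions()), None)
            agree += (nj_split == best)
        assert agree / trials >= 0.95


class TestBootstrap:
    def test_zero_divergence_reports_unresolved(self):
        msa = P.MSA(list("abcd"), {k: "MKLV" * 30 for k in "abcd"})
        result = P.bootstrap_support(msa, n_replicates=10, seed=1)
        assert not result.resolved
        assert result.tree.bipartitions() == set()

    def test_same_seed_reproduces_supports(self):
        fam = S.generate_protein_family(
            S.ProteinFamilySpec("F", 6, 200, subs_per_site=0.15, seed=5))
        msa = family_msa(fam)
        r1 = P.bootstrap_support(msa, 25, seed=7)
        r2 = P.bootstrap_support(msa, 25, seed=7)
        s1 = sorted(n.support for n in r1.tree.preorder() if n.support is not None)
        s2 = sorted(n.support for n in r2.tree.preorder() if n.support is not None)
        assert s1 == s2

    def test_caterpillar_bipartitions_strongly_supported(self):
        newick = ("((((((t1:0.05,t2:0.05):0.05,t3:0.05):0.05,t4:0.05):0.05,"
                  "t5:0.05):0.05,t6:0.05):0.05,t7:0.05,t8:0.05);")
        fam = S.generate_protein_family(S.ProteinFamilySpec(
            "F", 8, 300, tree_shape="fixed_newick", newick=newick, seed=6))
        msa = family_msa(fam)
        result = P.bootstrap_support(msa, 100, seed=11)
        true_bps = fam.tree.bipartitions()
        supports = {}
        below = {}
        for node in result.tree.postorder():
            if node.is_leaf:
                below[id(node)] = {node.label}
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.children))
                if node.parent is not None and node.support is not None:
                    side = below[id(node)]
                    universe = set(result.tree.leaf_labels())
                    canon = side if min(universe) not in side else universe - side
                    supports[frozenset(canon)] = node.support
        strong = sum(1 for bp in true_bps if supports.get(bp, 0) >= 70)
        assert strong / len(true_bps) >= 0.8


class TestCladeAssignment:
    def test_query_nested_in_labelled_clade(self):
        tree = Tree.from_newick(
            "(((a1:1,a2:1):1,(q:1,a3:1):1):1,(b1:1,b2:1):1);")
        labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        res = P.assign_clade(tree, labels, "q")
        assert res.label == "A" and res.rule == "monophyletic"

    def test_equidistant_query_reports_tie(self):
        tree = Tree.from_newick("(q:1,a1:1,b1:1);")
        res = P.assign_clade(tree, {"a1": "A", "b1": "B"}, "q")
        assert res.label is None and res.rule == "tie"
        assert res.tied == ["A", "B"]

    def test_missing_query_errors(self):
        tree = Tree.from_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="query"):
            P.assign_clade(tree, {"a": "A", "b": "B"}, "zzz")

    def test_truth_recovered_on_synthetic_family(self):
        fam = S.generate_protein_family(
            S.ProteinFamilySpec("F", 10, 300, subs_per_site=0.2, seed=8))
        msa = family_msa(fam)
        D, ids = P.distance_matrix(msa)
        est = P.nj_tree(D, ids)
        biparts = sorted(fam.tree.bipartitions(), key=len, reverse=True)
        side = set(biparts[0])
        labels = {leaf: ("IN" if leaf in side else "OUT")
                  for leaf in fam.tree.leaf_labels()}
        correct = 0
        for query in ids:
            res = P.assign_clade(est, {k: v for k, v in labels.items()
                                       if k != query}, query)
            correct += (res.label == labels[query])
        assert correct == len(ids)


class TestCongruence:
    def test_identical_trees_reach_minimum_p(self, rng):
        tree = random_topology([f"x{i}" for i in range(10)], rng)
        res = P.congruence_test(tree, tree, n_perm=199, seed=3)
        assert res.rf_distance == 0
        assert res.permutation_p == pytest.approx(1 / 200)

    def test_rf_matches_dendropy_oracle(self, rng):
        import dendropy
        from dendropy.calculate import treecompare
        for _ in range(10):
            ta = random_topology([f"x{i}" for i in range(9)], rng)
            tb = random_topology([f"x{i}" for i in range(9)], rng)
            res = P.congruence_test(ta, tb, n_perm=9, seed=0)
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=ta.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            db = dendropy.Tree.get(data=tb.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            expected = treecompare.symmetric_difference(da, db)
            assert res.rf_distance == expected

    def test_coevolved_families_detected(self):
        a, b = S.generate_coevolved_pair(
            S.ProteinFamilySpec("A", 12, 300, subs_per_site=0.15, seed=21),
            S.ProteinFamilySpec("B", 12, 300, subs_per_site=0.15, seed=22))
        ta = P.nj_tree(*P.distance_matrix(family_msa(a)))
        tb = P.nj_tree(*P.distance_matrix(family_msa(b)))
        res = P.congruence_test(ta, tb, n_perm=999, seed=13)
        assert res.permutation_p <= 0.01

    def test_too_few_shared_leaves_errors(self, rng):
        ta = random_topology(["a", "b", "c", "d"], rng)
        tb = random_topology(["a", "b", "x", "y"], rng)
        with pytest.raises(ValueError, match="share"):
            P.congruence_test(ta, tb)

    def test_normalized_rf_in_unit_interval(self, rng):
        for _ in range(10):
            ta = random_topology([f"x{i}" for i in range(8)], rng)
            tb = random_topology([f"x{i}" for i in range(8)], rng)
            res = P.congruence_test(ta, tb, n_perm=9, seed=1)
            assert 0 <= res.normalized_rf <= 1
            assert res.rf_distance % 2 == 0
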