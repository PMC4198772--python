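"""Distances, neighbor-joining, bootstrap and monophyly checks."""

import math

import numpy as np
import pytest

from ervkit import phylo
from ervkit._seq import mutate_protein, random_protein


def random_additive_tree(rng, n):
    """Exact path-length matrix of a random binary tree with positive
    branch lengths — an independent additivity oracle built by joining
    random subtree pairs and accumulating leaf depths."""
    d = np.zeros((n, n))
    groups = [[i] for i in range(n)]
    group_dist = [{i: 0.0} for i in range(n)]
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), 2, replace=False))
        bi = float(rng.uniform(0.5, 5.0))
        bj = float(rng.uniform(0.5, 5.0))
        gi, gj = groups[i], groups[j]
        di = {k: v + bi for k, v in group_dist[i].items()}
        dj = {k: v + bj for k, v in group_dist[j].items()}
        for a in gi:
            for b in gj:
                d[a, b] = d[b, a] = di[a] + dj[b]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [gi + gj]
        group_dist = [g for k, g in enumerate(group_dist) if k not in (i, j)] \
            + [{**di, **dj}]
    return d


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        dm = phylo.distance_matrix({"a": "MKVL", "b": "MKVL"}, "p")
        assert dm.values[0, 1] == 0.0

    def test_poisson_closed_form(self):
        aln = {"a": "A" * 90 + "C" * 10, "b": "A" * 100}
        dm = phylo.distance_matrix(aln, "poisson")
        assert dm.values[0, 1] == pytest.approx(-math.log(0.9), rel=1e-6)
        assert dm.values[0, 1] == pytest.approx(0.10536, abs=1e-5)

    def test_jc_closed_form(self):
        aln = {"a": "A" * 91 + "C" * 9, "b": "A" * 100}
        dm = phylo.distance_matrix(aln, "jc")
        expected = -0.75 * math.log(1 - 4 * 0.09 / 3)
        assert dm.values[0, 1] == pytest.approx(expected, rel=1e-6)
        assert dm.values[0, 1] == pytest.approx(0.09587, abs=1e-5)

    def test_pairwise_deletion(self):
        aln = {"a": "AAAA--CC", "b": "AAAACC--"}
        dm = phylo.distance_matrix(aln, "p")
        assert dm.values[0, 1] == 0.0  # only the 4 shared columns count

    def test_saturation_error_names_pair(self):
        aln = {"x1": "ACGT" * 5, "x2": "TGCA" * 5}
        with pytest.raises(ValueError, match="x1/x2"):
            phylo.distance_matrix(aln, "jc")


class TestNjTree:
    def test_four_taxon_worked_example(self):
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     dtype=float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(taxa=list("ABCD"), values=d))
        splits = {frozenset(s) for s in tree.bipartitions()}
        assert splits & {frozenset("AB"), frozenset("CD")}
        # internal edge of the AB|CD split has length 1
        pl = tree.path_lengths()
        assert np.allclose(
            pl.values[[pl.taxa.index(t) for t in "ABCD"]][:, [pl.taxa.index(t) for t in "ABCD"]],
            d)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(taxa=list("XYZ"), values=d))
        lens = {c.name: bl for c, bl in tree.root.children}
        assert lens == {"X": 1.0, "Y": 3.0, "Z": 5.0}

    @pytest.mark.parametrize("seed", range(20))
    def test_additive_matrices_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        d = random_additive_tree(rng, n)
        taxa = [f"t{i}" for i in range(n)]
        tree = phylo.nj_tree(phylo.DistanceMatrix(taxa=taxa, values=d))
        pl = tree.path_lengths()
        order = [pl.taxa.index(t) for t in taxa]
        assert np.allclose(pl.values[order][:, order], d, atol=1e-9)

    def test_agrees_with_reference_implementation(self):
        # independent cross-check against scikit-bio's NJ on metric matrices
        import skbio

        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.random((6, 3))
            from scipy.spatial.distance import pdist, squareform

            d = squareform(pdist(pts))
            taxa = [f"t{i}" for i in range(6)]
            ours = phylo.nj_tree(phylo.DistanceMatrix(taxa=taxa, values=d))
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
            all_t = frozenset(taxa)
            norm = lambda s: min(s, all_t - s,
                                 key=lambda x: (len(x), tuple(sorted(x))))
            ours_splits = {norm(frozenset(s)) for s in ours.bipartitions()}
            ref_splits = set()
            for node in ref.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < len(taxa) - 1:
                    ref_splits.add(norm(below))
            assert ours_splits == ref_splits

    def test_star_tree_on_zero_matrix(self):
        d = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            tree = phylo.nj_tree(phylo.DistanceMatrix(taxa=list("ABCD"),
                                                      values=d))
        assert len(tree.root.children) == 4


class TestBootstrap:
    @pytest.fixture(scope="class")
    def clade_alignment(self):
        rng = np.random.default_rng(0)
        root = random_protein(rng, 300)
        ca = mutate_protein(rng, root, 0.5)
        aln = {f"A{i}": mutate_protein(rng, ca, 0.01) for i in range(3)}
        aln.update({f"B{i}": mutate_protein(rng, root, 0.01) for i in range(3)})
        return aln

    def test_strong_clade_high_support(self, clade_alignment):
        tree = phylo.bootstrap_support(clade_alignment, "poisson",
                                       n_reps=200, seed=1)
        mono, side = phylo.check_monophyly(tree, {"A0", "A1", "A2"})
        assert mono
        node = tree.bipartitions()[side]
        assert node.support >= 99

    def test_single_replicate_support_binary(self, clade_alignment):
        tree = phylo.bootstrap_support(clade_alignment, "poisson",
                                       n_reps=1, seed=2)
        sups = [n.support for n in tree.bipartitions().values()]
        assert all(s in (0.0, 100.0) for s in sups)

    def test_seed_determinism(self, clade_alignment):
        t1 = phylo.bootstrap_support(clade_alignment, "poisson", 50, seed=3)
        t2 = phylo.bootstrap_support(clade_alignment, "poisson", 50, seed=3)
        assert t1.newick() == t2.newick()

    def test_support_grows_with_separation(self):
        rng = np.random.default_rng(9)
        root = random_protein(rng, 200)
        sups = []
        for sep in (0.05, 0.2, 0.5):
            ca = mutate_protein(rng, root, sep)
            aln = {f"A{i}": mutate_protein(rng, ca, 0.02) for i in range(3)}
            aln.update({f"B{i}": mutate_protein(rng, root, 0.02)
                        for i in range(3)})
            tree = phylo.bootstrap_support(aln, "poisson", 100, seed=4)
            ok, side = phylo.check_monophyly(tree, {"A0", "A1", "A2"})
            sups.append(tree.bipartitions()[side].support if ok else 0.0)
        assert sups[0] <= sups[-1]
        assert sups[-1] >= 99


class TestMonophylyAndPartitions:
    def test_simple_cases(self):
        d = np.array([[0, 2, 9, 9], [2, 0, 9, 9], [9, 9, 0, 2], [9, 9, 2, 0]],
                     dtype=float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(taxa=list("ABCD"), values=d))
        assert phylo.check_monophyly(tree, {"A", "B"})[0]
        assert not phylo.check_monophyly(tree, {"A", "C"})[0]
        with pytest.raises(ValueError):
            phylo.check_monophyly(tree, {"A", "Q"})

    def test_genus_structured_placement(self, genus_reps):
        # 7 genus clusters + an implant drawn near the lentiviral member:
        # the implant-inclusive cluster must be monophyletic, high support
        rng = np.random.default_rng(5)
        aln = {}
        for genus, rep in genus_reps.items():
            for i in range(2):
                aln[f"{genus}_{i}"] = mutate_protein(rng, rep, 0.08)
        aln["implant"] = mutate_protein(rng, genus_reps["lentivirus"], 0.12)
        tree = phylo.bootstrap_support(aln, "poisson", n_reps=100, seed=6)
        clade = {"lentivirus_0", "lentivirus_1", "implant"}
        ok, side = phylo.check_monophyly(tree, clade)
        assert ok
        assert tree.bipartitions()[side].support >= 95

    def test_per_gene_trees_agree(self, genus_reps):
        # gag-vs-pol partitions of one non-recombinant alignment place the
        # implant in the same clade (the recombination screen)
        rng = np.random.default_rng(6)
        aln = {}
        for genus, rep in genus_reps.items():
            aln[genus] = mutate_protein(rng, rep, 0.05)
        aln["implant"] = mutate_protein(rng, genus_reps["lentivirus"], 0.10)
        ncol = len(next(iter(aln.values())))
        half = ncol // 2
        for part in (phylo.sub_alignment(aln, 1, half),
                     phylo.sub_alignment(aln, half + 1, ncol)):
            tree = phylo.nj_tree(phylo.distance_matrix(part, "poisson"))
            ok, _ = phylo.check_monophyly(tree, {"lentivirus", "implant"})
            assert ok


def test_newick_roundtrip(tmp_path):
    d = np.array([[0, 2, 9, 9], [2, 0, 9, 9], [9, 9, 0, 2], [9, 9, 2, 0]],
                 dtype=float)
    tree = phylo.nj_tree(phylo.DistanceMatrix(taxa=list("ABCD"), values=d))
    text = tree.newick()
    assert text.endswith(";")
    back = phylo.read_newick(text)
    assert sorted(back.leaves()) == ["A", "B", "C", "D"]
    norm = lambda s, full: min(s, full - s, key=lambda x: (len(x), tuple(sorted(x))))
    full = frozenset("ABCD")
    assert ({norm(frozenset(s), full) for s in back.bipartitions()}
            == {norm(frozenset(s), full) for s in tree.bipartitions()})
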