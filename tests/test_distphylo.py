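"""Ts/Tv counting, K2P distances, neighbor-joining, bootstrap, split comparison."""

import itertools
import math
import random

import numpy as np
import pytest
import skbio
import dendropy

from msatphylo import reference_data as ref
from msatphylo.distphylo import (
    DistanceMatrix,
    DistanceUndefinedError,
    PhyloTree,
    SiteDiffSummary,
    TreeNode,
    bootstrap_support,
    build_distance_matrix,
    compare_splits,
    count_site_differences,
    k2p_distance,
    neighbor_joining,
)


class TestSiteDifferences:
    def test_identical_rows(self):
        s = count_site_differences("ACGT", "ACGT")
        assert (s.ts, s.tv, s.compared) == (0, 0, 4)

    def test_gap_and_ambiguity_excluded(self):
        s = count_site_differences("A-CT", "AGCT")
        assert (s.ts, s.tv, s.compared) == (0, 0, 3)
        s = count_site_differences("AKCT", "AGCT")
        assert (s.ts, s.tv, s.compared) == (0, 0, 3)

    def test_all_twelve_mismatch_types_classified(self):
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for x, y in itertools.permutations("ACGT", 2):
            s = count_site_differences(x, y)
            if (x, y) in transitions:
                assert (s.ts, s.tv) == (1, 0), (x, y)
            else:
                assert (s.ts, s.tv) == (0, 1), (x, y)

    def test_mixed_pair(self):
        s = count_site_differences("AG", "GC")
        assert (s.ts, s.tv) == (1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_site_differences("ACG", "AC")


class TestK2P:
    def test_zero_differences_zero_distance(self):
        assert k2p_distance(SiteDiffSummary(0, 0, 0, 100)).d == 0.0

    def test_worked_minimum_distance(self):
        """Ts=8, Tv=12 over 469 comparable sites gives the published 0.044."""
        r = k2p_distance(SiteDiffSummary(ts=8, tv=12, gap_excluded=0, compared=469))
        assert round(r.d, 3) == 0.044
        assert r.d == pytest.approx(0.043911, abs=1e-6)
        assert r.se == pytest.approx(0.010, abs=2e-3)

    def test_saturation_flagged_undefined(self):
        with pytest.raises(DistanceUndefinedError, match="undefined"):
            k2p_distance(SiteDiffSummary(ts=45, tv=15, gap_excluded=0, compared=100))
        with pytest.raises(DistanceUndefinedError):
            k2p_distance(SiteDiffSummary(ts=0, tv=0, gap_excluded=0, compared=0))

    def test_dominates_p_distance_on_grid(self):
        for ts in range(0, 30, 3):
            for tv in range(0, 20, 2):
                r = k2p_distance(SiteDiffSummary(ts, tv, 0, 200))
                p_dist = (ts + tv) / 200
                assert r.d >= p_dist - 1e-12
                assert (r.d == 0) == (ts == tv == 0)

    def test_monotone_in_ts_and_tv(self):
        base = k2p_distance(SiteDiffSummary(10, 10, 0, 500)).d
        assert k2p_distance(SiteDiffSummary(11, 10, 0, 500)).d > base
        assert k2p_distance(SiteDiffSummary(10, 11, 0, 500)).d > base

    def test_reduces_to_jukes_cantor_at_equal_rates(self):
        """With transitions 1/3 of differences (P = D/3, Q = 2D/3), K2P equals
        the Jukes-Cantor distance -3/4 ln(1 - 4D/3)."""
        for d_total in np.linspace(0.01, 0.5, 20):
            p, q = d_total / 3, 2 * d_total / 3
            k2p = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
            jc = -0.75 * math.log(1 - 4 * d_total / 3)
            assert k2p == pytest.approx(jc, rel=1e-12)


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        aligned = {t: "ACGTACGTAC" for t in "ABCD"}
        m = build_distance_matrix(aligned)
        assert np.all(m.d == 0)
        assert np.all(m.differences == 0)

    def test_symmetry_and_consistency(self, default_report):
        m = default_report.matrix
        assert np.allclose(m.d, m.d.T)
        assert np.all(np.diag(m.d) == 0)
        aligned = default_report.cross_alignment
        for a, b in itertools.combinations(m.taxa, 2):
            s = count_site_differences(aligned[a], aligned[b])
            i, j = m.taxa.index(a), m.taxa.index(b)
            assert m.differences[i, j] == s.differences

    def test_saturated_pair_named(self):
        aligned = {"A": "AAAA" * 5, "B": "CCCC" * 5, "C": "AAAA" * 5}
        with pytest.raises(DistanceUndefinedError, match=r"pair \(A, B\)"):
            build_distance_matrix(aligned)


def _random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree; returns (PhyloTree-free) distance dict."""
    names = [chr(ord("A") + i) for i in range(n_taxa)]
    # sequential taxon addition onto random edges, tracked as a dendropy tree
    newick = f"({names[0]}:{rng.uniform(0.1, 1):.4f},{names[1]}:{rng.uniform(0.1, 1):.4f},{names[2]}:{rng.uniform(0.1, 1):.4f});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for name in names[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.length is not None]
        edge = rng.choice(edges)
        old_len = edge.length
        child = edge.head_node
        parent = edge.tail_node
        split = rng.uniform(0.2, 0.8) * old_len
        mid = parent.new_child(edge_length=old_len - split)
        parent.remove_child(child)
        mid.add_child(child)
        child.edge.length = split
        leaf = mid.new_child(edge_length=rng.uniform(0.1, 1))
        leaf.taxon = tree.taxon_namespace.new_taxon(label=name)
    pdm = tree.phylogenetic_distance_matrix()
    dist = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        dist[frozenset({t1.label, t2.label})] = pdm.patristic_distance(t1, t2)
    splits = set()
    tree.encode_bipartitions()
    all_names = frozenset(names)
    for bip in tree.bipartition_encoding:
        side = frozenset(t.label for t in bip.leafset_taxa(tree.taxon_namespace))
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(side if "A" not in side else all_names - side)
    return names, dist, splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix.from_pairs(
            ["A", "B", "C"],
            {
                frozenset("AB"): 0.3,
                frozenset("AC"): 0.5,
                frozenset("BC"): 0.6,
            },
        )
        tree = neighbor_joining(D)
        lengths = dict(
            (child.name, length) for child, length in tree.root.children
        )
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_matrices(self, n_taxa):
        """On additive matrices NJ is exact: topology and path lengths."""
        rng = random.Random(100 + n_taxa)
        for _ in range(5):
            names, dist, true_splits = _random_additive_tree(n_taxa, rng)
            tree = neighbor_joining(DistanceMatrix.from_pairs(names, dist))
            assert tree.splits() == true_splits
            recovered = tree.leaf_distance_matrix()
            for pair, d in dist.items():
                a, b = sorted(pair)
                assert recovered.get(a, b) == pytest.approx(d, abs=1e-9)

    def test_published_matrix_tropical_cherry(self):
        """The printed distance matrix puts marmorata with bicolor pacifica,
        rejecting a japonica+anguilla cherry in the unrooted 4-taxon sense."""
        D = DistanceMatrix.from_pairs(ref.TAXA, ref.K2P_DISTANCES)
        tree = neighbor_joining(D)
        assert tree.splits() == {frozenset({"M", "B"})}

    def test_four_taxa_single_internal_edge(self, default_report):
        assert len(default_report.tree.splits()) == 1

    def test_matches_skbio_on_noisy_matrix(self):
        """Independent cross-check: scikit-bio's NJ finds the same topology."""
        rng = random.Random(17)
        names = list("ABCDEF")
        _, dist, _ = _random_additive_tree(6, rng)
        noisy = {k: v * (1 + rng.uniform(-0.05, 0.05)) for k, v in dist.items()}
        mine = neighbor_joining(DistanceMatrix.from_pairs(names, noisy))
        mat = np.zeros((6, 6))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    mat[i, j] = noisy[frozenset({a, b})]
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(mat, ids=names))
        sk = dendropy.Tree.get(data=str(sk_tree), schema="newick")
        sk.encode_bipartitions()
        all_names = frozenset(names)
        sk_splits = set()
        for bip in sk.bipartition_encoding:
            side = frozenset(t.label for t in bip.leafset_taxa(sk.taxon_namespace))
            if 2 <= len(side) <= 4:
                sk_splits.add(side if "A" not in side else all_names - side)
        assert mine.splits() == sk_splits

    def test_fewer_than_three_taxa_rejected(self):
        D = DistanceMatrix.from_pairs(["A", "B"], {frozenset("AB"): 0.1})
        with pytest.raises(ValueError):
            neighbor_joining(D)


class TestCompareSplits:
    def _quartet(self, cherry):
        a, b = cherry
        c, d = sorted(set("ABCD") - set(cherry))
        inner = TreeNode(children=[(TreeNode(name=c), 1.0), (TreeNode(name=d), 1.0)])
        root = TreeNode(
            children=[(TreeNode(name=a), 1.0), (TreeNode(name=b), 1.0), (inner, 1.0)]
        )
        return PhyloTree(root=root)

    def test_identical_trees(self):
        t = self._quartet("AB")
        cmp = compare_splits(t, self._quartet("AB"))
        assert cmp.symmetric_difference == 0

    def test_distinct_quartets_differ_by_two(self):
        cmp = compare_splits(self._quartet("AB"), self._quartet("AC"))
        assert cmp.symmetric_difference == 2

    def test_leaf_mismatch_rejected(self):
        t1 = self._quartet("AB")
        t2 = self._quartet("AB")
        for child, _ in t2.root.children:
            if child.name == "A":
                child.name = "X"
        with pytest.raises(ValueError):
            compare_splits(t1, t2)

    def test_random_six_taxon_pairs_match_bruteforce(self):
        rng = random.Random(23)
        for _ in range(5):
            _, d1, s1 = _random_additive_tree(6, rng)
            _, d2, s2 = _random_additive_tree(6, rng)
            t1 = neighbor_joining(DistanceMatrix.from_pairs(list("ABCDEF"), d1))
            t2 = neighbor_joining(DistanceMatrix.from_pairs(list("ABCDEF"), d2))
            cmp = compare_splits(t1, t2)
            assert cmp.symmetric_difference == len(s1 ^ s2)
            assert cmp.shared == len(s1 & s2)


class TestBootstrap:
    def _unanimous_alignment(self):
        # every variable column supports {A,B} | {C,D}
        base = "ACGTACGTACGTACGTACGT"
        rows = {t: base for t in "ABCD"}
        for col in (2, 7, 11, 15, 19):
            for t in "CD":
                s = list(rows[t])
                s[col] = "T" if base[col] != "T" else "A"
                rows[t] = "".join(s)
        return rows

    def test_unanimous_signal_full_support(self):
        tree = bootstrap_support(self._unanimous_alignment(), n_reps=100, seed=0)
        (node,) = tree.internal_nodes()
        assert node.support == 100.0

    def test_same_seed_reproducible(self, default_report):
        aligned = default_report.cross_alignment
        t1 = bootstrap_support(aligned, n_reps=200, seed=5)
        t2 = bootstrap_support(aligned, n_reps=200, seed=5)
        s1 = [n.support for n in t1.internal_nodes()]
        s2 = [n.support for n in t2.internal_nodes()]
        assert s1 == s2
        t3 = bootstrap_support(aligned, n_reps=200, seed=6)
        s3 = [n.support for n in t3.internal_nodes()]
        assert all(abs(a - b) < 15 for a, b in zip(s1, s3))

    def test_supports_invariant_to_taxon_order(self, default_report):
        aligned = default_report.cross_alignment
        reordered = dict(sorted(aligned.items(), reverse=True))
        t1 = bootstrap_support(aligned, n_reps=100, seed=9)
        t2 = bootstrap_support(reordered, n_reps=100, seed=9)
        by_split_1 = {t1.splits().pop(): t1.internal_nodes()[0].support}
        by_split_2 = {t2.splits().pop(): t2.internal_nodes()[0].support}
        assert by_split_1 == by_split_2

    def test_against_independent_resampling_oracle(self, default_report):
        """Mixed-signal alignment: supports within 3 points of a second,
        independently coded column-resampling implementation (four-point
        pairing instead of NJ, plain string counting instead of code arrays).
        """
        aligned = default_report.cross_alignment
        tree = bootstrap_support(aligned, n_reps=2000, seed=101)
        (node,) = tree.internal_nodes()
        target_split = tree.splits().pop()

        taxa = sorted(aligned)
        ncol = len(aligned[taxa[0]])
        rng = random.Random(555)
        hits = valid = 0
        ts_pairs = {frozenset("AG"), frozenset("CT")}
        for _ in range(2000):
            cols = [rng.randrange(ncol) for _ in range(ncol)]
            d = {}
            ok = True
            for a, b in itertools.combinations(taxa, 2):
                ts = tv = compared = 0
                for c in cols:
                    x, y = aligned[a][c], aligned[b][c]
                    if x not in "ACGT" or y not in "ACGT":
                        continue
                    compared += 1
                    if x != y:
                        if frozenset((x, y)) in ts_pairs:
                            ts += 1
                        else:
                            tv += 1
                p, q = ts / compared, tv / compared
                if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
                    ok = False
                    break
                d[frozenset((a, b))] = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(
                    1 - 2 * q
                )
            if not ok:
                continue
            valid += 1
            # four-point pairing: the NJ quartet split is the minimal pair-sum
            sums = {}
            for pair in itertools.combinations(taxa, 2):
                rest = tuple(sorted(set(taxa) - set(pair)))
                key = frozenset(pair) if taxa[0] not in pair else frozenset(rest)
                sums[key] = d[frozenset(pair)] + d[frozenset(rest)]
            best = min(sums, key=lambda k: sums[k])
            if best == target_split:
                hits += 1
        oracle = 100.0 * hits / valid
        assert node.support == pytest.approx(oracle, abs=3.0)
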