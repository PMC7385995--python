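"""K2P distances vs brute-force counting, NJ vs least-squares topology
search, consensus sampling, insertion-age arithmetic and bootstrap."""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitescout.align import MultipleAlignment, progressive_msa
from mitescout.config import PipelineConfig
from mitescout.phylo import (
    AgeEstimate,
    SaturationError,
    age_histogram,
    balanced_consensus,
    bootstrap_support,
    element_ages,
    k2p_distance,
    k2p_matrix,
    majority_consensus_row,
    neighbor_joining,
)
from mitescout.simulate import evolve_k2p

PURINES = {"A", "G"}


def brute_force_k2p(a: str, b: str):
    """Per-site counting oracle, written independently of the implementation."""
    ti = tv = n = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ti += 1
        else:
            tv += 1
    if n == 0:
        return None
    P, Q = ti / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return ("saturated", P, Q)
    return (-0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q), P, Q)


class TestK2P:
    def test_identical_rows_zero(self):
        res = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (res.P, res.Q, res.k) == (0.0, 0.0, 0.0)

    def test_closed_form_value(self):
        # 100 sites, 10 transitions, 5 transversions: P=0.1, Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        res = k2p_distance(a, b)
        assert res.P == pytest.approx(0.10)
        assert res.Q == pytest.approx(0.05)
        assert res.k == pytest.approx(0.17018, abs=5e-6)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            k2p_distance("AG", "GG")  # P=0.5, Q=0 -> 1-2P-Q = 0

    def test_gaps_and_ambiguity_pairwise_deleted(self):
        res = k2p_distance("AC-GN", "ACCGT")
        assert res.compared_sites == 3

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError):
            k2p_distance("--", "AC")

    def test_exhaustive_small_equivalence(self):
        """All pairs of length-3 sequences against the counting oracle."""
        seqs = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
        for a in seqs:
            for b in seqs:
                expect = brute_force_k2p(a, b)
                assert expect is not None
                if expect[0] == "saturated":
                    with pytest.raises(SaturationError):
                        k2p_distance(a, b)
                else:
                    res = k2p_distance(a, b)
                    assert res.k == pytest.approx(expect[0], abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=40), st.integers(0, 2**31 - 1))
    def test_symmetry_and_jensen_bound(self, a, seed):
        rng = np.random.default_rng(seed)
        b = "".join(rng.choice(list("ACGT"), size=len(a)))
        try:
            r1 = k2p_distance(a, b)
        except SaturationError:
            return
        r2 = k2p_distance(b, a)
        assert r1.k == pytest.approx(r2.k)
        assert r1.k >= r1.P + r1.Q - 1e-12  # multiple-hit correction only adds

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        anc = "".join(rng.choice(list("ACGT"), size=200))
        rows = [evolve_k2p(anc, 0.05, rng) for _ in range(6)]
        msa = MultipleAlignment(taxa=[f"t{i}" for i in range(6)], rows=rows)
        dm = k2p_matrix(msa)
        for i in range(6):
            for j in range(i + 1, 6):
                assert dm[i, j] == pytest.approx(k2p_distance(rows[i], rows[j]).k)


def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies by leaf insertion on every edge."""
    if len(taxa) == 3:
        return [tuple(taxa)]

    def insert(tree, leaf):
        """Nested-tuple tree -> all trees with leaf added on some edge."""
        out = []
        for i, child in enumerate(tree):
            if isinstance(child, tuple):
                for sub in insert(child, leaf):
                    out.append(tuple(sub if k == i else c for k, c in enumerate(tree)))
            out.append(tuple((child, leaf) if k == i else c for k, c in enumerate(tree)))
        return out

    trees = [tuple(taxa[:3])]
    for leaf in taxa[3:]:
        trees = [t2 for t in trees for t2 in insert(t, leaf)]
    return trees


def tree_splits(tree):
    """Non-trivial splits of a nested-tuple unrooted tree, canonicalized."""
    leaves = set()

    def collect(t):
        if isinstance(t, tuple):
            out = set()
            for c in t:
                out |= collect(c)
            return out
        leaves.add(t)
        return {t}

    collect(tree)
    ref = min(leaves)
    splits = set()

    def walk(t):
        if not isinstance(t, tuple):
            return {t}
        below = set()
        for c in t:
            sub = walk(c)
            if 1 < len(sub) < len(leaves) - 1:
                side = frozenset(leaves - sub) if ref in sub else frozenset(sub)
                splits.add(side)
            below |= sub
        return below

    walk(tree)
    return splits


def least_squares_fit(tree, dm, labels):
    """Nonnegative least-squares residual of a topology against a matrix.

    Edges are the leaf pendant edges plus one internal edge per non-trivial
    split; the path between two leaves crosses an internal edge iff the split
    separates them.
    """
    import scipy.optimize

    idx = {t: i for i, t in enumerate(labels)}
    splits = sorted(tree_splits(tree), key=lambda s: sorted(s))
    n_edges = len(labels) + len(splits)
    rows, y = [], []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            row = np.zeros(n_edges)
            row[idx[a]] = 1
            row[idx[b]] = 1
            for k, side in enumerate(splits):
                if (a in side) != (b in side):
                    row[len(labels) + k] = 1
            rows.append(row)
            y.append(dm[i, j])
    A = np.array(rows)
    y = np.array(y)
    x, _ = scipy.optimize.nnls(A, y)
    return float(((A @ x - y) ** 2).sum())


class TestNeighborJoining:
    ADDITIVE_4 = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )

    def test_four_taxon_additive_recovers_tree(self):
        # generating tree: (A:1,B:2) -1- (C:3,D:4)
        tree = neighbor_joining(self.ADDITIVE_4, ["A", "B", "C", "D"])
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        d = tree.leaf_distances()
        assert d[("A", "B")] == pytest.approx(3.0, abs=1e-9)
        assert d[("A", "C")] == pytest.approx(5.0, abs=1e-9)
        assert d[("C", "D")] == pytest.approx(7.0, abs=1e-9)

    def test_least_squares_brute_force_agrees(self):
        labels = ["A", "B", "C", "D"]
        best = None
        for topo in enumerate_unrooted_topologies(labels):
            r = least_squares_fit(topo, self.ADDITIVE_4, labels)
            if best is None or r < best[0]:
                best = (r, tree_splits(topo))
        nj = neighbor_joining(self.ADDITIVE_4, labels)
        assert best[0] == pytest.approx(0.0, abs=1e-12)
        assert best[1] == nj.bipartitions()

    def test_five_taxon_additive(self):
        # tree ((A:1,B:2):1,(C:1,D:1):2,E:3); distances computed by hand
        dm = np.zeros((5, 5))
        labels = ["A", "B", "C", "D", "E"]
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 5, ("A", "E"): 5,
            ("B", "C"): 6, ("B", "D"): 6, ("B", "E"): 6,
            ("C", "D"): 2, ("C", "E"): 6, ("D", "E"): 6,
        }
        for (a, b), v in d.items():
            i, j = labels.index(a), labels.index(b)
            dm[i, j] = dm[j, i] = v
        nj = neighbor_joining(dm, labels)
        ls_best = None
        for topo in enumerate_unrooted_topologies(labels):
            r = least_squares_fit(topo, dm, labels)
            if ls_best is None or r < ls_best[0]:
                ls_best = (r, tree_splits(topo))
        assert ls_best[1] == nj.bipartitions()
        got = nj.leaf_distances()
        for (a, b), v in d.items():
            assert got[(a, b)] == pytest.approx(v, abs=1e-9)

    def test_three_taxa_closed_form(self):
        dm = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(dm, ["x", "y", "z"])
        d = tree.leaf_distances()
        assert d[("x", "y")] == pytest.approx(3.0)
        assert d[("x", "z")] == pytest.approx(4.0)
        assert d[("y", "z")] == pytest.approx(5.0)

    def test_equal_distances_tie_break_deterministic(self):
        dm = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(dm, ["a", "b", "c", "d"])
        t2 = neighbor_joining(dm, ["a", "b", "c", "d"])
        assert t1.to_newick() == t2.to_newick()

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])
        bad = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(bad, ["a", "b", "c"])

    def test_additive_random_trees_reproduced(self):
        """NJ on any additive matrix reproduces the generating path metric."""
        rng = np.random.default_rng(13)
        for rep in range(5):
            n = 6
            labels = [f"t{i}" for i in range(n)]
            topo = enumerate_unrooted_topologies(labels)[
                int(rng.integers(0, 105))  # 105 unrooted 6-taxon topologies
            ]
            splits = sorted(tree_splits(topo), key=lambda s: sorted(s))
            leaf_len = {t: float(rng.uniform(0.2, 2.0)) for t in labels}
            split_len = {s: float(rng.uniform(0.2, 2.0)) for s in splits}
            dm = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = labels[i], labels[j]
                    v = leaf_len[a] + leaf_len[b] + sum(
                        split_len[s] for s in splits if (a in s) != (b in s)
                    )
                    dm[i, j] = dm[j, i] = v
            nj = neighbor_joining(dm, labels)
            got = nj.leaf_distances()
            for i in range(n):
                for j in range(i + 1, n):
                    key = (min(labels[i], labels[j]), max(labels[i], labels[j]))
                    assert got[key] == pytest.approx(dm[i, j], abs=1e-9)

    def test_newick_round_trips_through_dendropy(self):
        tree = neighbor_joining(self.ADDITIVE_4, ["A", "B", "C", "D"])
        nwk = tree.to_newick()
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in dt.leaf_node_iter()} == {"A", "B", "C", "D"}


class TestConsensusAndAges:
    def _msa(self, rows, taxa=None):
        taxa = taxa or [f"s{i}" for i in range(len(rows))]
        return MultipleAlignment(taxa=taxa, rows=rows)

    def test_balanced_sampling_includes_small_clade_fully(self):
        rng = np.random.default_rng(21)
        anc = "".join(rng.choice(list("ACGT"), size=100))
        rows = [evolve_k2p(anc, 0.02, rng) for _ in range(20)]
        msa = self._msa(rows)
        clades = {t: ("I" if i < 4 else "II") for i, t in enumerate(msa.taxa)}
        c1 = balanced_consensus(msa, clades, per_clade_n=4, seed=1)
        c2 = balanced_consensus(msa, clades, per_clade_n=4, seed=1)
        assert c1 == c2  # deterministic under seed
        assert len(c1) == 100

    def test_per_clade_n_at_least_clade_size_equals_plain_majority(self):
        rows = ["ACGT", "ACGT", "AGGT"]
        msa = self._msa(rows)
        clades = {t: "only" for t in msa.taxa}
        assert balanced_consensus(msa, clades, per_clade_n=10, seed=0) == \
            majority_consensus_row(msa)

    def test_tie_breaks_to_alphabetical_base(self):
        msa = self._msa(["AT", "GT"])
        assert majority_consensus_row(msa) == "AT"

    def test_empty_clade_map_rejected(self):
        msa = self._msa(["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            balanced_consensus(msa, {}, per_clade_n=1, seed=0)

    def test_age_formula(self, config):
        msa = self._msa(["A" * 100])
        # k = 0.052 should date to 2 Mya at r = 1.3e-8
        row = "G" * 5 + "A" * 95  # 5 transitions / 100 sites
        msa = MultipleAlignment(taxa=["e"], rows=[row])
        cons = "A" * 100
        ages = element_ages(msa, cons, config)
        k = ages[0].k
        assert ages[0].T == pytest.approx(k / (2 * 1.30e-8))

    def test_zero_divergence_zero_age(self, config):
        msa = self._msa(["ACGT" * 25])
        ages = element_ages(msa, "ACGT" * 25, config)
        assert ages[0].k == 0.0
        assert ages[0].T == 0.0

    def test_saturated_element_flagged_not_fatal(self, config):
        msa = self._msa(["AG", "GG"])
        ages = element_ages(msa, "AG", config)
        assert ages[0].saturated is False
        assert ages[1].saturated is True
        assert ages[1].T is None

    def test_age_histogram_totals_conserved(self):
        ages = [
            AgeEstimate("a", 0.01, 0.5e6),
            AgeEstimate("b", 0.03, 1.2e6),
            AgeEstimate("c", 0.06, 2.3e6),
            AgeEstimate("d", None, None, saturated=True),
        ]
        h = age_histogram(ages, bin=1e6)
        assert list(h["counts"]) == [1, 1, 1]
        assert h["n_excluded"] == 1
        assert h["counts"].sum() + h["n_excluded"] == len(ages)


class TestBootstrap:
    def test_two_clade_support_high(self, config):
        rng = np.random.default_rng(31)
        anc = "".join(rng.choice(list("ACGT"), size=400))
        far = evolve_k2p(anc, 0.3, rng)
        rows = [evolve_k2p(anc, 0.01, rng) for _ in range(5)] + [
            evolve_k2p(far, 0.01, rng) for _ in range(5)
        ]
        msa = MultipleAlignment(taxa=[f"x{i}" for i in range(10)], rows=rows)
        cfg = PipelineConfig(bootstrap_replicates=200, rng_seed=17)
        tree = bootstrap_support(msa, cfg)
        clade = frozenset({f"x{i}" for i in range(5, 10)})
        supports = {
            frozenset(n.leaves()): n.support
            for n in tree.internal_nodes()
            if n.support is not None
        }
        ref_side = [v for k, v in supports.items() if k == clade or
                    k == frozenset(msa.taxa) - clade]
        assert ref_side and ref_side[0] >= 95

    def test_supports_within_range_and_degenerate_ok(self, config):
        rows = ["ACGTACGTACGT"] * 5
        msa = MultipleAlignment(taxa=[f"z{i}" for i in range(5)], rows=rows)
        cfg = PipelineConfig(bootstrap_replicates=20, rng_seed=3)
        tree = bootstrap_support(msa, cfg)
        for n in tree.internal_nodes():
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0
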