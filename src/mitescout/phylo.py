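"""Kimura 2-parameter distances, consensus building, insertion dating,
neighbor-joining trees and bootstrap support.

The dating model is the standard repeat molecular clock: an element accrues
substitutions after insertion, so its K2P distance k to the family consensus
(a proxy for the ancestral sequence) converts to an insertion age
T = k / (2 r) with r the per-site per-year substitution rate (default
1.30e-8). K2P corrects transitions (P) and transversions (Q) separately:

    k = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites with a gap or ambiguity in either row are excluded pairwise. Distances
beyond the formula's domain are reported as saturated and flagged, never
capped: capping would silently distort age histograms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .align import MultipleAlignment
from .config import PipelineConfig

__all__ = [
    "SaturationError",
    "K2PResult",
    "AgeEstimate",
    "PhyloTree",
    "k2p_distance",
    "k2p_matrix",
    "majority_consensus_row",
    "balanced_consensus",
    "element_ages",
    "age_histogram",
    "neighbor_joining",
    "bootstrap_support",
]

log = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_BASES = frozenset("ACGT")
_BASE_ORDER = "ACGT"


class SaturationError(ValueError):
    """K2P distance undefined: substitution saturation."""


@dataclass
class K2PResult:
    P: float  # transition proportion per compared site
    Q: float  # transversion proportion per compared site
    k: float  # substitutions per site
    compared_sites: int


def _k2p_from_counts(transitions: int, transversions: int, compared: int) -> K2PResult:
    if compared == 0:
        raise ValueError("no comparable sites")
    P = transitions / compared
    Q = transversions / compared
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated: P={P:.4f}, Q={Q:.4f}")
    k = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, k=k, compared_sites=compared)


def k2p_distance(row_a: str, row_b: str) -> K2PResult:
    """K2P distance between two equal-length (possibly gapped) rows.

    Pairwise deletion: only sites where both rows carry an unambiguous base
    are compared.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    a = row_a.upper()
    b = row_b.upper()
    transitions = transversions = compared = 0
    for x, y in zip(a, b):
        if x not in _BASES or y not in _BASES:
            continue
        compared += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    return _k2p_from_counts(transitions, transversions, compared)


# vectorized encoding: A=0 C=1 G=2 T=3, other=255
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASE_ORDER):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_rows(rows: list[str]) -> np.ndarray:
    return np.vstack(
        [_ENCODE[np.frombuffer(r.encode(), dtype=np.uint8)] for r in rows]
    )


def k2p_matrix(msa: MultipleAlignment, columns: np.ndarray | None = None) -> np.ndarray:
    """Symmetric K2P distance matrix over all rows (pairwise deletion).

    Raises SaturationError if any pair is saturated or shares no sites.
    """
    enc = encode_rows(msa.rows)
    if columns is not None:
        enc = enc[:, columns]
    n = enc.shape[0]
    purine = (enc == 0) | (enc == 2)
    valid = enc < 4
    dm = np.zeros((n, n))
    for i in range(n):
        vi = valid[i]
        both = vi & valid[i + 1 :]
        diff = (enc[i] != enc[i + 1 :]) & both
        ti = diff & (purine[i] == purine[i + 1 :])
        compared = both.sum(axis=1)
        if (compared == 0).any():
            raise ValueError("pair with no comparable sites")
        n_ti = ti.sum(axis=1)
        n_tv = diff.sum(axis=1) - n_ti
        P = n_ti / compared
        Q = n_tv / compared
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if (w1 <= 0).any() or (w2 <= 0).any():
            raise SaturationError("saturated pair in distance matrix")
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        dm[i, i + 1 :] = d
        dm[i + 1 :, i] = d
    return dm


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def majority_consensus_row(
    msa: MultipleAlignment,
    row_indices: list[int] | None = None,
    min_occupancy: float = 0.0,
) -> str:
    """Per-column majority base in alignment coordinates.

    Gaps and ambiguity codes are ignored when voting; ties break in the fixed
    order A < C < G < T; a column with no unambiguous base becomes a gap.
    With ``min_occupancy`` > 0, a column also becomes a gap when fewer than
    that fraction of rows carry a base there — this keeps ragged insertion
    columns (contributed by a few fragmentary members) out of a family
    consensus.
    """
    rows = msa.rows if row_indices is None else [msa.rows[i] for i in row_indices]
    enc = encode_rows(list(rows))
    n = enc.shape[0]
    out = []
    counts = np.zeros((4, enc.shape[1]), dtype=int)
    for b in range(4):
        counts[b] = (enc == b).sum(axis=0)
    for j in range(enc.shape[1]):
        col = counts[:, j]
        if col.sum() == 0 or col.sum() < min_occupancy * n:
            out.append("-")
        else:
            out.append(_BASE_ORDER[int(col.argmax())])  # argmax keeps A<C<G<T ties
    return "".join(out)


def balanced_consensus(
    msa: MultipleAlignment,
    clades: dict[str, str],
    per_clade_n: int,
    seed: int,
) -> str:
    """Majority consensus over an equal-sized sample from each clade.

    Sampling min(per_clade_n, clade size) members per clade without
    replacement avoids biasing the consensus toward the most numerous clade.
    All-gap columns are dropped; the returned consensus is ungapped.
    """
    if not clades:
        raise ValueError("empty clade map")
    if per_clade_n < 1:
        raise ValueError("per_clade_n must be >= 1")
    taxon_index = {t: i for i, t in enumerate(msa.taxa)}
    by_clade: dict[str, list[str]] = {}
    for leaf, clade in clades.items():
        if leaf not in taxon_index:
            raise ValueError(f"leaf {leaf!r} not in alignment")
        by_clade.setdefault(clade, []).append(leaf)
    rng = np.random.default_rng(seed)
    sampled: list[int] = []
    for clade in sorted(by_clade):
        leaves = sorted(by_clade[clade])
        take = min(per_clade_n, len(leaves))
        chosen = rng.choice(len(leaves), size=take, replace=False)
        sampled.extend(taxon_index[leaves[i]] for i in sorted(chosen))
    row = majority_consensus_row(msa, sampled)
    return row.replace("-", "")


# ---------------------------------------------------------------------------
# insertion ages
# ---------------------------------------------------------------------------


@dataclass
class AgeEstimate:
    element_id: str
    k: float | None  # substitutions per site; None when saturated
    T: float | None  # years; None when saturated
    saturated: bool = False


def element_ages(
    msa: MultipleAlignment,
    consensus_row: str,
    config: PipelineConfig,
) -> list[AgeEstimate]:
    """Per-element K2P distance to the consensus and insertion age T = k/2r.

    ``consensus_row`` must be gap-projected into the alignment frame (same
    length as the alignment). Saturated elements are flagged, not dropped.
    """
    if len(consensus_row) != msa.length:
        raise ValueError("consensus row not in alignment coordinates")
    r = config.substitution_rate_r
    out: list[AgeEstimate] = []
    for taxon, row in zip(msa.taxa, msa.rows):
        try:
            res = k2p_distance(row, consensus_row)
        except SaturationError:
            out.append(AgeEstimate(element_id=taxon, k=None, T=None, saturated=True))
            continue
        out.append(AgeEstimate(element_id=taxon, k=res.k, T=res.k / (2.0 * r)))
    return out


def age_histogram(ages: list[AgeEstimate], bin: float = 1e6) -> dict:
    """Counts of insertion ages per [i*bin, (i+1)*bin) interval.

    Saturated/absent ages are excluded and reported in ``n_excluded`` so that
    bin totals plus exclusions always equal the input size.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    ts = [a.T for a in ages if a.T is not None]
    n_excluded = len(ages) - len(ts)
    if not ts:
        return {"edges": np.array([0.0]), "counts": np.array([], dtype=int), "n_excluded": n_excluded}
    nbins = int(max(ts) // bin) + 1
    counts = np.zeros(nbins, dtype=int)
    for t in ts:
        counts[int(t // bin)] += 1
    edges = np.arange(nbins + 1) * bin
    return {"edges": edges, "counts": counts, "n_excluded": n_excluded}


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class TreeNode:
    __slots__ = ("name", "children", "support")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple["TreeNode", float]] = []
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """An (un)rooted tree; NJ output is rooted at the final trifurcation."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(
                f"{fmt(child)}:{max(bl, 0.0):.6f}" for child, bl in node.children
            )
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the first leaf."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        n = len(all_leaves)
        out: set[frozenset] = set()

        def walk(node: TreeNode):
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                sub = walk(child)
                if 1 < len(sub) < n - 1:
                    side = all_leaves - sub if ref in sub else sub
                    out.add(side)
                below = below | sub
            return below

        walk(self.root)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode):
            if not node.is_leaf:
                out.append(node)
                for child, _ in node.children:
                    walk(child)

        walk(self.root)
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path-length metric between all leaf pairs."""
        pairs: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}  # type: ignore[dict-item]
            groups: list[dict[str, float]] = []
            for child, bl in node.children:
                sub = walk(child)
                groups.append({k: v + max(bl, 0.0) for k, v in sub.items()})
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi].items():
                        for lb, db in groups[gj].items():
                            pairs[(min(la, lb), max(la, lb))] = da + db
            merged: dict[str, float] = {}
            for g in groups:
                merged.update(g)
            return merged

        walk(self.root)
        return pairs


def neighbor_joining(dm: np.ndarray, labels: list[str]) -> PhyloTree:
    """Standard NJ agglomeration with the Q-matrix criterion.

    Deterministic tie-break: among minimal Q entries, the smallest (i, j) in
    the current active ordering is joined. Negative branch lengths are clamped
    to zero with the deficit moved to the sister branch.
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor_joining requires >= 3 taxa")
    if dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.isnan(dm).any() or np.isinf(dm).any():
        raise ValueError("distance matrix has non-finite entries")
    if not np.allclose(dm, dm.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) != n:
        raise ValueError("labels/matrix size mismatch")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    active = list(range(n))
    D = dm.copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ia, ja = min((min(i, j), max(i, j)) for i, j in ties)
        gi, gj = active[ia], active[ja]
        d_ij = sub[ia, ja]
        li = 0.5 * d_ij + (r[ia] - r[ja]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = clamp(li, lj)
        parent = TreeNode()
        parent.children = [(nodes[gi], li), (nodes[gj], lj)]
        # distances from the new node
        new_d = 0.5 * (D[gi, :] + D[gj, :] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_d)] = new_d
        D[: len(new_d), -1] = new_d
        D[-1, -1] = 0.0
        nodes.append(parent)
        new_idx = len(nodes) - 1
        active = [a for a in active if a not in (gi, gj)] + [new_idx]

    # resolve the final three nodes around an unrooted center
    x, y, z = active
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    lx = max(0.0, 0.5 * (dxy + dxz - dyz))
    ly = max(0.0, 0.5 * (dxy + dyz - dxz))
    lz = max(0.0, 0.5 * (dxz + dyz - dxy))
    root = TreeNode()
    root.children = [(nodes[x], lx), (nodes[y], ly), (nodes[z], lz)]
    return PhyloTree(root=root)


def bootstrap_support(
    msa: MultipleAlignment,
    config: PipelineConfig,
    replicates: int | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap support on internal edges.

    Column resamples are drawn with the configured seed; each replicate's K2P
    matrix feeds NJ, and support for an internal bipartition of the full-data
    tree is the percentage of successful replicates containing it. A
    saturated replicate is redrawn up to 10 times, then skipped and counted.
    """
    if len(msa) < 4:
        raise ValueError("bootstrap_support requires >= 4 taxa")
    reps = replicates if replicates is not None else config.bootstrap_replicates
    full = neighbor_joining(k2p_matrix(msa), msa.taxa)
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(config.rng_seed)
    L = msa.length
    done = skipped = 0
    for _ in range(reps):
        tree = None
        for _retry in range(10):
            cols = rng.integers(0, L, size=L)
            try:
                dm = k2p_matrix(msa, columns=cols)
            except (SaturationError, ValueError):
                continue
            tree = neighbor_joining(dm, msa.taxa)
            break
        if tree is None:
            skipped += 1
            continue
        done += 1
        reps_bps = tree.bipartitions()
        for bp in target:
            if bp in reps_bps:
                counts[bp] += 1
    if skipped:
        log.warning("bootstrap: %d replicates skipped after saturation retries", skipped)
    denom = max(done, 1)
    # attach supports to matching internal nodes
    all_leaves = frozenset(full.leaf_names)
    ref = min(all_leaves)
    n = len(all_leaves)
    for node in full.internal_nodes():
        sub = frozenset(node.leaves())
        if 1 < len(sub) < n - 1:
            side = all_leaves - sub if ref in sub else sub
            if side in counts:
                node.support = 100.0 * counts[side] / denom
    return full
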