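"""Pairwise site differences, K2P distances, neighbor-joining, bootstrap.

Distances follow the Kimura two-parameter model,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with P and Q the transition (A<->G, C<->T) and transversion proportions over
the pairwise-comparable length L.  Columns where either sequence carries a
gap or an ambiguity letter are excluded per pair (pairwise complete
deletion), so effective lengths differ between pairs.  The optional standard
error is the analytic delta-method estimate.

Neighbor-joining is the canonical Q-criterion agglomeration; ties are broken
on the lexicographically smallest (cluster-label) pair and negative branch
lengths are clamped to zero with the deficit logged.  For four taxa the
single internal edge fully determines the unrooted topology.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_TS_PAIRS = frozenset({frozenset("AG"), frozenset("CT")})
_BASES = frozenset("ACGT")


class DistanceUndefinedError(ValueError):
    """Raised when the K2P logarithms are out of domain (saturated pair)."""


@dataclass(frozen=True)
class SiteDiffSummary:
    """Pairwise transition/transversion counts over the comparable length."""

    ts: int
    tv: int
    gap_excluded: int
    compared: int

    def __post_init__(self) -> None:
        if self.ts < 0 or self.tv < 0:
            raise ValueError("ts and tv must be nonnegative")
        if self.compared < self.ts + self.tv:
            raise ValueError("compared length smaller than difference count")

    @property
    def differences(self) -> int:
        return self.ts + self.tv


@dataclass(frozen=True)
class DistanceResult:
    """K2P distance with its transition/transversion proportions."""

    p: float
    q: float
    d: float
    se: float | None = None


def count_site_differences(a: str, b: str) -> SiteDiffSummary:
    """Count Ts/Tv between two aligned rows with pairwise complete deletion.

    Columns where either row has a gap or an IUPAC ambiguity letter are
    excluded from the comparison (and counted in ``gap_excluded``).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    ts = tv = excluded = 0
    for x, y in zip(a, b):
        if x not in _BASES or y not in _BASES:
            excluded += 1
            continue
        if x == y:
            continue
        if frozenset((x, y)) in _TS_PAIRS:
            ts += 1
        else:
            tv += 1
    return SiteDiffSummary(ts=ts, tv=tv, gap_excluded=excluded, compared=len(a) - excluded)


def k2p_distance(s: SiteDiffSummary, with_se: bool = True) -> DistanceResult:
    """Kimura two-parameter distance from a pairwise difference summary.

    Raises :class:`DistanceUndefinedError` when ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0`` (the distance is undefined at saturation) or when no
    sites are comparable.
    """
    if s.compared <= 0:
        raise DistanceUndefinedError("no comparable sites: distance undefined")
    p = s.ts / s.compared
    q = s.tv / s.compared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise DistanceUndefinedError(
            f"distance undefined (saturation): P={p:.4f}, Q={q:.4f}"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    se = None
    if with_se:
        c1 = 1.0 / w1
        c2 = 1.0 / w2
        c3 = 0.5 * (c1 + c2)
        var = (c1 * c1 * p + c3 * c3 * q - (c1 * p + c3 * q) ** 2) / s.compared
        se = math.sqrt(max(var, 0.0))
    return DistanceResult(p=p, q=q, d=d, se=se)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distances plus integer difference counts over taxa."""

    taxa: tuple[str, ...]
    d: np.ndarray
    differences: np.ndarray
    results: dict[frozenset[str], DistanceResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n) or self.differences.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.d[i, j])

    @classmethod
    def from_pairs(
        cls, taxa: Sequence[str], pairs: Mapping[frozenset[str], float]
    ) -> "DistanceMatrix":
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pairs[frozenset({taxa[i], taxa[j]})]
        return cls(taxa=tuple(taxa), d=d, differences=np.zeros((n, n), dtype=int))


def build_distance_matrix(aligned: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise K2P distances and raw difference counts over aligned taxa.

    ``aligned`` maps taxon name to its gapped row; all rows must share one
    length.  Any saturated pair raises an error naming the pair.
    """
    taxa = tuple(aligned)
    if len(taxa) < 3:
        raise ValueError("at least 3 taxa required")
    n = len(taxa)
    d = np.zeros((n, n))
    diffs = np.zeros((n, n), dtype=int)
    results: dict[frozenset[str], DistanceResult] = {}
    for i in range(n):
        for j in range(i + 1, n):
            summary = count_site_differences(aligned[taxa[i]], aligned[taxa[j]])
            try:
                res = k2p_distance(summary)
            except DistanceUndefinedError as exc:
                raise DistanceUndefinedError(
                    f"pair ({taxa[i]}, {taxa[j]}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = res.d
            diffs[i, j] = diffs[j, i] = summary.differences
            results[frozenset({taxa[i], taxa[j]})] = res
    return DistanceMatrix(taxa=taxa, d=d, differences=diffs, results=results)


# --- trees ------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an unrooted tree rendered from an arbitrary (trifurcating) root."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted phylogeny with branch lengths and optional bootstrap supports."""

    root: TreeNode

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node.name or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def branch_lengths(self) -> list[float]:
        out: list[float] = []

        def walk(node: TreeNode) -> None:
            for child, length in node.children:
                out.append(length)
                walk(child)

        walk(self.root)
        return out

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each normalized to the side that excludes
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaves())
        smallest = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset({node.name})
            below = frozenset().union(*(walk(child) for child, _ in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                out.add(all_leaves - below if smallest in below else below)
            return below

        walk(self.root)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf() and node is not self.root:
                out.append(node)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        leaves = sorted(self.leaves())
        index = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def collect(node: TreeNode) -> dict[str, float]:
            """Distances from all leaves below ``node`` to ``node``."""
            if node.is_leaf():
                return {node.name or "": 0.0}
            below: dict[str, float] = {}
            groups: list[dict[str, float]] = []
            for child, length in node.children:
                sub = {k: v + length for k, v in collect(child).items()}
                groups.append(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi].items():
                        for lb, db in groups[gj].items():
                            d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
                below.update({k: v for g in groups for k, v in g.items()})
            return below

        collect(self.root)
        return DistanceMatrix(
            taxa=tuple(leaves), d=d, differences=np.zeros((n, n), dtype=int)
        )

    def to_newick(self, decimals: int = 3, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name or ""
            inner = ",".join(
                f"{fmt(child)}:{length:.{decimals}f}" for child, length in node.children
            )
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.warning("negative branch length %.6g clamped to 0 (%s)", length, context)
        return 0.0
    return length


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor-joining on a distance matrix (>= 3 taxa).

    Q(i, j) = (n - 2) d(i, j) - r_i - r_j; the minimal-Q pair is joined, with
    ties broken on the lexicographically smallest pair of cluster labels
    (a cluster is labelled by its smallest leaf).  Branch lengths use the
    standard split formula; negative lengths are clamped to zero.
    """
    if len(D.taxa) < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    if not np.all(np.isfinite(D.d)):
        raise ValueError("distance matrix contains non-finite entries")

    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in D.taxa}
    dist: dict[frozenset[str], float] = {}
    labels = sorted(D.taxa)
    for i, a in enumerate(D.taxa):
        for j in range(i + 1, len(D.taxa)):
            dist[frozenset({a, D.taxa[j]})] = float(D.d[i, j])

    while len(labels) > 3:
        n = len(labels)
        r = {a: sum(dist[frozenset({a, b})] for b in labels if b != a) for a in labels}
        best_pair: tuple[str, str] | None = None
        best_q = math.inf
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (n - 2) * dist[frozenset({a, b})] - r[a] - r[b]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best_pair is None or (a, b) < best_pair)
                ):
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair  # type: ignore[misc]
        dab = dist[frozenset({a, b})]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        la = _clamp(la, f"edge to {a}")
        lb = _clamp(lb, f"edge to {b}")
        new = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        new_label = min(a, b)
        for c in labels:
            if c in (a, b):
                continue
            dc = 0.5 * (dist[frozenset({a, c})] + dist[frozenset({b, c})] - dab)
            dist[frozenset({new_label, c})] = dc
        labels = sorted([c for c in labels if c not in (a, b)] + [new_label])
        nodes.pop(a)
        nodes.pop(b)
        nodes[new_label] = new

    a, b, c = labels
    dab = dist[frozenset({a, b})]
    dac = dist[frozenset({a, c})]
    dbc = dist[frozenset({b, c})]
    la = _clamp(0.5 * (dab + dac - dbc), f"edge to {a}")
    lb = _clamp(0.5 * (dab + dbc - dac), f"edge to {b}")
    lc = _clamp(0.5 * (dac + dbc - dab), f"edge to {c}")
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root)


@dataclass(frozen=True)
class SplitComparison:
    """Robinson–Foulds-style comparison of two unrooted trees."""

    shared: int
    only_first: int
    only_second: int

    @property
    def symmetric_difference(self) -> int:
        return self.only_first + self.only_second


def compare_splits(t1: PhyloTree, t2: PhyloTree) -> SplitComparison:
    """Shared and unique nontrivial splits between trees on the same leaves."""
    l1, l2 = set(t1.leaves()), set(t2.leaves())
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    s1, s2 = t1.splits(), t2.splits()
    return SplitComparison(
        shared=len(s1 & s2), only_first=len(s1 - s2), only_second=len(s2 - s1)
    )


# --- bootstrap --------------------------------------------------------------

_CODE_EXCLUDED, _CODE_SAME, _CODE_TS, _CODE_TV = 0, 1, 2, 3


def _pair_codes(a: str, b: str) -> np.ndarray:
    """Per-column comparison codes for one taxon pair (for fast resampling)."""
    codes = np.empty(len(a), dtype=np.uint8)
    for idx, (x, y) in enumerate(zip(a, b)):
        if x not in _BASES or y not in _BASES:
            codes[idx] = _CODE_EXCLUDED
        elif x == y:
            codes[idx] = _CODE_SAME
        elif frozenset((x, y)) in _TS_PAIRS:
            codes[idx] = _CODE_TS
        else:
            codes[idx] = _CODE_TV
    return codes


def bootstrap_support(
    aligned: Mapping[str, str],
    n_reps: int = 1000,
    seed: int | None = None,
    drop_warn_fraction: float = 0.10,
) -> PhyloTree:
    """NJ tree from ``aligned`` with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; distances and
    the NJ tree are recomputed per replicate and each internal split's
    support is the percentage of valid replicates containing it.  Replicates
    with an undefined (saturated) distance are dropped and counted; a
    warning is emitted when more than ``drop_warn_fraction`` are dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa = tuple(aligned)
    ncol = len(next(iter(aligned.values())))
    if ncol < 1:
        raise ValueError("alignment has no columns")
    rng = np.random.default_rng(seed)

    base = neighbor_joining(build_distance_matrix(aligned))
    pairs = [
        (i, j, _pair_codes(aligned[taxa[i]], aligned[taxa[j]]))
        for i in range(len(taxa))
        for j in range(i + 1, len(taxa))
    ]

    split_counts: dict[frozenset[str], int] = {s: 0 for s in base.splits()}
    dropped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        n = len(taxa)
        d = np.zeros((n, n))
        ok = True
        for i, j, codes in pairs:
            c = codes[idx]
            counts = np.bincount(c, minlength=4)
            summary_compared = int(counts[1] + counts[2] + counts[3])
            try:
                res = k2p_distance(
                    SiteDiffSummary(
                        ts=int(counts[2]),
                        tv=int(counts[3]),
                        gap_excluded=int(counts[0]),
                        compared=summary_compared,
                    ),
                    with_se=False,
                )
            except DistanceUndefinedError:
                ok = False
                break
            d[i, j] = d[j, i] = res.d
        if not ok:
            dropped += 1
            continue
        rep_tree = neighbor_joining(
            DistanceMatrix(taxa=taxa, d=d, differences=np.zeros((n, n), dtype=int))
        )
        for s in rep_tree.splits():
            if s in split_counts:
                split_counts[s] += 1

    valid = n_reps - dropped
    if dropped > drop_warn_fraction * n_reps:
        logger.warning("%d of %d bootstrap replicates dropped (undefined distances)", dropped, n_reps)
    if valid == 0:
        raise DistanceUndefinedError("all bootstrap replicates had undefined distances")

    all_leaves = frozenset(base.leaves())
    smallest = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset({node.name})
        below = frozenset().union(*(annotate(child) for child, _ in node.children))
        if node is not base.root and 2 <= len(below) <= len(all_leaves) - 2:
            split = all_leaves - below if smallest in below else below
            node.support = 100.0 * split_counts[split] / valid
        return below

    annotate(base.root)
    return base
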