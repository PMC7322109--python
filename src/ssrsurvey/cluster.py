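"""Genetic similarity and UPGMA dendrograms from marker band profiles.

Co-dominant genotype calls are expanded into a binary band matrix (one
column per observed (locus, allele)); pairwise genetic similarity
coefficients (GSC) are computed over mutually scored columns (pairwise
deletion of columns from loci where either individual is missing); and the
1 - GSC distances are clustered by UPGMA (size-weighted average linkage)
into an ultrametric dendrogram with deterministic lexicographic
tie-breaking.  A merge at distance d sits at node height d/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "BandMatrix",
    "SimilarityMatrix",
    "TreeNode",
    "Dendrogram",
    "band_matrix",
    "similarity",
    "similarity_matrix",
    "upgma",
    "cut_clusters",
]

SIMILARITY_METHODS = ("simple_matching", "dice", "jaccard")


@dataclass
class BandMatrix:
    """Binary presence/absence of every observed (locus, allele) band.

    ``values[i, j]`` is 1 iff individual i carries band j; ``scored[i, j]``
    is False where the underlying locus call is missing for individual i.
    """

    ids: list[str]
    columns: list[tuple[str, int]]
    values: np.ndarray
    scored: np.ndarray


def band_matrix(matrix: GenotypeMatrix) -> BandMatrix:
    columns: list[tuple[str, int]] = []
    for locus in matrix.loci:
        alleles = set()
        for ind in matrix.individuals:
            call = matrix.call(ind, locus)
            if call is not MISSING:
                alleles.update(call)
        columns.extend((locus, a) for a in sorted(alleles))
    n, m = len(matrix.individuals), len(columns)
    values = np.zeros((n, m), dtype=bool)
    scored = np.ones((n, m), dtype=bool)
    col_index = {col: j for j, col in enumerate(columns)}
    for i, ind in enumerate(matrix.individuals):
        for locus in matrix.loci:
            call = matrix.call(ind, locus)
            if call is MISSING:
                for (l, a), j in col_index.items():
                    if l == locus:
                        scored[i, j] = False
            else:
                for allele in call:
                    values[i, col_index[(locus, allele)]] = True
    return BandMatrix(
        ids=list(matrix.individuals), columns=columns, values=values, scored=scored
    )


def similarity(
    a: np.ndarray,
    b: np.ndarray,
    mask_a: Optional[np.ndarray] = None,
    mask_b: Optional[np.ndarray] = None,
    method: str = "simple_matching",
) -> float:
    """GSC between two binary band rows over mutually scored columns.

    simple_matching = (m11 + m00) / total; dice = 2 m11 / (2 m11 + m10 + m01);
    jaccard = m11 / (m11 + m10 + m01).
    """
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    ok = np.ones(a.shape, dtype=bool)
    if mask_a is not None:
        ok &= np.asarray(mask_a, dtype=bool)
    if mask_b is not None:
        ok &= np.asarray(mask_b, dtype=bool)
    if not ok.any():
        raise ValueError("no mutually scored columns")
    av, bv = a[ok], b[ok]
    m11 = int(np.sum(av & bv))
    m00 = int(np.sum(~av & ~bv))
    m10 = int(np.sum(av & ~bv))
    m01 = int(np.sum(~av & bv))
    if method == "simple_matching":
        return (m11 + m00) / (m11 + m00 + m10 + m01)
    if method == "dice":
        denom = 2 * m11 + m10 + m01
        return 1.0 if denom == 0 else 2 * m11 / denom
    denom = m11 + m10 + m01
    return 1.0 if denom == 0 else m11 / denom


@dataclass
class SimilarityMatrix:
    """Symmetric GSC matrix with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be exactly 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("entries outside [0, 1]")
        self.values = v


def similarity_matrix(band: BandMatrix, method: str = "simple_matching") -> SimilarityMatrix:
    n = len(band.ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = similarity(
                band.values[i],
                band.values[j],
                band.scored[i],
                band.scored[j],
                method=method,
            )
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids=list(band.ids), values=values)


@dataclass
class TreeNode:
    height: float
    name: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]


@dataclass
class Dendrogram:
    """Ultrametric binary merge tree; leaf heights are 0."""

    root: TreeNode
    ids: list[str]

    def __post_init__(self) -> None:
        names = sorted(l.name for l in self.root.leaves())
        if names != sorted(self.ids):
            raise ValueError("leaf set does not match ids")
        self._check_monotone(self.root)

    @staticmethod
    def _check_monotone(node: TreeNode) -> None:
        for child in node.children:
            if child.height > node.height + 1e-9:
                raise ValueError("heights must be non-decreasing toward the root")
            Dendrogram._check_monotone(child)

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{branch:.10g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{branch:.10g}"

        if self.root.is_leaf:
            return f"{self.root.name};"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cophenetic_distance(self, a: str, b: str) -> float:
        """Twice the height of the lowest common ancestor of leaves a and b."""

        def walk(node: TreeNode) -> tuple[set[str], Optional[float]]:
            if node.is_leaf:
                return {node.name}, None
            found = None
            members: set[str] = set()
            for child in node.children:
                sub, hit = walk(child)
                if hit is not None:
                    found = hit
                members |= sub
            if found is not None:
                return members, found
            if a in members and b in members:
                return members, 2.0 * node.height
            return members, None

        if a == b:
            return 0.0
        _, hit = walk(self.root)
        if hit is None:
            raise ValueError(f"leaves {a!r}, {b!r} not both in tree")
        return hit


def upgma(sim: SimilarityMatrix) -> Dendrogram:
    """UPGMA on distances d = 1 - GSC.

    Merges the closest cluster pair at each step (ties broken by the
    lexicographically smallest pair of cluster representative ids, each
    cluster represented by its smallest member id); the merged node sits at
    height d/2; inter-cluster distances are size-weighted averages.
    """
    n = len(sim.ids)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = 1.0 - sim.values[i, j]
    clusters: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, name=sim.ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    reps = {i: sim.ids[i] for i in range(n)}
    next_id = n
    while len(clusters) > 1:
        best = None
        for key, d in dist.items():
            i, j = sorted(key)
            pair_rep = tuple(sorted((reps[i], reps[j])))
            cand = (d, pair_rep)
            if best is None or cand < best[0:2]:
                best = (d, pair_rep, i, j)
        d, _, i, j = best
        if reps[j] < reps[i]:
            i, j = j, i
        node = TreeNode(height=d / 2.0, children=[clusters[i], clusters[j]])
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            di = dist.pop(frozenset((i, k)))
            dj = dist.pop(frozenset((j, k)))
            dist[frozenset((new, k))] = (
                sizes[i] * di + sizes[j] * dj
            ) / (sizes[i] + sizes[j])
        dist.pop(frozenset((i, j)))
        clusters.pop(i)
        clusters.pop(j)
        clusters[new] = node
        sizes[new] = sizes.pop(i) + sizes.pop(j)
        reps[new] = min(reps.pop(i), reps.pop(j))
    return Dendrogram(root=next(iter(clusters.values())), ids=list(sim.ids))


def cut_clusters(tree: Dendrogram, similarity_threshold: float) -> list[set[str]]:
    """Partition of individuals obtained by cutting at GSC ``similarity_threshold``.

    The cut height is (1 - threshold)/2, matching the distance-to-height
    convention of :func:`upgma`.
    """
    if not (0.0 <= similarity_threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    cut_height = (1.0 - similarity_threshold) / 2.0
    groups: list[set[str]] = []

    def walk(node: TreeNode) -> None:
        if node.height <= cut_height + 1e-12:
            groups.append({l.name for l in node.leaves()})
        else:
            for child in node.children:
                walk(child)

    walk(tree.root)
    return groups
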