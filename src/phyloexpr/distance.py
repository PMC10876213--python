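"""Expression distance matrices, principal coordinates analysis with convex-
hull areas, and bootstrap neighbor-joining phenograms.

The sample-to-sample distance is the root-mean-square log2 fold change over a
fixed set of most-variable genes; PCoA is classical (Torgerson) scaling with
negative eigenvalues reported rather than corrected; phenograms use canonical
Saitou-Nei neighbor joining with deterministic tie-breaking, and node support
is the fraction of gene-resampled replicates containing each bipartition of
the full-data tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .normalize import top_variable_genes

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "Phenogram",
    "logfc_distance",
    "pcoa",
    "hull_area",
    "neighbor_joining",
    "bootstrap_support",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    df: pd.DataFrame

    def __post_init__(self):
        a = self.df.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1] or list(self.df.index) != list(self.df.columns):
            raise ValueError("distance matrix must be square with matching labels")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.abs(np.diag(a)) > 1e-12).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (a < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def ids(self) -> list[str]:
        return list(self.df.index)

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)


def logfc_distance(expr: pd.DataFrame, genes) -> DistanceMatrix:
    """RMS log2 fold change between samples over a fixed gene set:
    d(a, b) = sqrt(mean_g (x_ga - x_gb)^2) on the log2 scale."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    X = expr.loc[genes].to_numpy(dtype=float).T  # samples x genes
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).mean(axis=2)
    d = np.sqrt(sq)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(pd.DataFrame(d, index=expr.columns, columns=expr.columns))


# ---------------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # items x axes
    eigenvalues: np.ndarray  # all, descending
    proportion_explained: np.ndarray  # over positive eigenvalues, percent
    n_negative: int


def pcoa(D: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical scaling: double-center -1/2 D^2, eigendecompose, scale
    eigenvectors by sqrt(eigenvalue).  Negative eigenvalues are counted and
    excluded from the percent-variance denominators, never corrected."""
    d = D.values()
    n = d.shape[0]
    B = -0.5 * d ** 2
    B = B - B.mean(axis=0, keepdims=True) - B.mean(axis=1, keepdims=True) + B.mean()
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-10
    pos = evals > tol
    n_neg = int((evals < -tol).sum())
    rank = int(pos.sum())
    if n_axes is None:
        n_axes = rank
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but only {rank} positive eigenvalues; "
            "truncating", UserWarning, stacklevel=2)
        n_axes = rank
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    prop = np.zeros_like(evals)
    pos_sum = evals[pos].sum()
    if pos_sum > 0:
        prop[pos] = evals[pos] / pos_sum * 100.0
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=D.ids, columns=[f"Axis{i + 1}" for i in range(n_axes)]
        ),
        eigenvalues=evals,
        proportion_explained=prop[:n_axes],
        n_negative=n_neg,
    )


def hull_area(
    coords: pd.DataFrame, groups: pd.Series, axes: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Convex-hull (shoelace) area per group on a pair of ordination axes,
    plus areas relative to the largest group.  Groups with fewer than three
    points, or collinear points, get area 0 with a warning."""
    if axes is None:
        axes = tuple(coords.columns[:2])
    xy = coords.loc[:, list(axes)]
    rows = []
    for name, members in groups.groupby(groups).groups.items():
        pts = xy.loc[[m for m in members if m in xy.index]].to_numpy()
        area = 0.0
        if pts.shape[0] < 3:
            warnings.warn(f"group {name!r} has <3 points: area 0", UserWarning,
                          stacklevel=2)
        else:
            try:
                area = float(ConvexHull(pts).volume)  # 2-D volume is area
            except QhullError:
                warnings.warn(f"group {name!r} is degenerate (collinear): area 0",
                              UserWarning, stacklevel=2)
        rows.append({"group": name, "area": area})
    out = pd.DataFrame(rows)
    amax = out["area"].max()
    out["relative_area"] = out["area"] / amax if amax > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def is_leaf(self):
        return not self.children

    def newick(self, support=None) -> str:
        return self._nwk(support) + ";"

    def _nwk(self, support) -> str:
        if self.is_leaf():
            return self.label
        inner = ",".join(f"{c._nwk(support)}:{bl:.10g}" for c, bl in self.children)
        lab = ""
        if support is not None:
            s = support.get(id(self))
            if s is not None:
                lab = f"{s:.3f}"
        return f"({inner}){lab}"

    def leaf_labels(self) -> frozenset:
        if self.is_leaf():
            return frozenset([self.label])
        out = set()
        for c, _ in self.children:
            out |= c.leaf_labels()
        return frozenset(out)


@dataclass
class Phenogram:
    """Unrooted NJ tree over samples/species with optional bootstrap support
    per internal bipartition (fractions in [0, 1])."""

    root: _Node
    tips: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized as the side not containing
        the lexicographically smallest tip."""
        anchor = min(self.tips)
        full = frozenset(self.tips)
        out = set()

        def walk(node):
            for child, _ in node.children:
                below = child.leaf_labels()
                if 1 < len(below) < len(self.tips) - 1:
                    side = below if anchor not in below else full - below
                    out.add(side)
                walk(child)

        walk(self.root)
        return out

    def newick(self, with_support: bool = False) -> str:
        if not with_support or not self.supports:
            return self.root.newick()
        anchor = min(self.tips)
        full = frozenset(self.tips)
        by_id = {}

        def walk(node):
            for child, _ in node.children:
                below = child.leaf_labels()
                if 1 < len(below) < len(self.tips) - 1:
                    side = below if anchor not in below else full - below
                    if side in self.supports:
                        by_id[id(child)] = self.supports[side]
                walk(child)

        walk(self.root)
        return self.root.newick(support=by_id)


def neighbor_joining(D: DistanceMatrix) -> Phenogram:
    """Canonical Saitou-Nei NJ.

    Iteratively joins the pair minimizing Q = (n-2) d_ij - r_i - r_j, with
    ties broken by the smallest (row, col) index pair in the current matrix.
    Negative estimated branch lengths are clamped to zero with the deficit
    moved to the sibling edge.
    """
    ids = D.ids
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 items")
    d = D.values().copy()
    nodes = [_Node(label=i) for i in ids]

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (row, col) with i < j on ties: scan upper triangle in order
        qmin = Q.min()
        i, j = next(
            (a, b)
            for a in range(m)
            for b in range(a + 1, m)
            if Q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin))
        )
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        dk = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    # final three-way join: lengths from the three-point formulas
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = _Node(children=[(nodes[0], max(la, 0.0)),
                           (nodes[1], max(lb, 0.0)),
                           (nodes[2], max(lc, 0.0))])
    return Phenogram(root=root, tips=ids)


def tree_bipartitions(tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of a :class:`~phyloexpr.io.Phylogeny`,
    canonicalized like :meth:`Phenogram.bipartitions`."""
    tips = tree.tip_labels
    anchor = min(tips)
    full = frozenset(tips)
    out = set()
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if 1 < len(below) < len(tips) - 1:
            out.add(below if anchor not in below else full - below)
    return out


def rf_distance(a: set[frozenset], b: set[frozenset]) -> int:
    """Robinson-Foulds distance between two canonical bipartition sets."""
    return len(a ^ b)


def bootstrap_support(
    expr: pd.DataFrame,
    genes_selector=500,
    n_boot: int = 1000,
    seed: int = 0,
) -> Phenogram:
    """Gene-resampling bootstrap of the NJ phenogram.

    ``genes_selector`` is an explicit gene list, a callable on the matrix, or
    an int n meaning the top-n most variable genes.  The full-data tree is
    returned with, for each of its internal bipartitions, the fraction of
    replicates (genes resampled with replacement) whose NJ tree contains it.
    """
    if callable(genes_selector):
        genes = list(genes_selector(expr))
    elif isinstance(genes_selector, int):
        genes = top_variable_genes(expr, min(genes_selector, expr.shape[0]))
    else:
        genes = list(genes_selector)
    if len(genes) < 2:
        raise ValueError("bootstrap requires at least 2 genes")

    base = neighbor_joining(logfc_distance(expr, genes))
    target = base.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    garr = np.array(genes, dtype=object)
    for _ in range(n_boot):
        resample = garr[rng.integers(0, len(genes), size=len(genes))]
        rep = neighbor_joining(logfc_distance(expr, list(resample)))
        found = rep.bipartitions()
        for b in target:
            if b in found:
                counts[b] += 1
    base.supports = {b: counts[b] / n_boot for b in target}
    return base
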