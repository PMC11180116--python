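"""Phylogeny handling: distances, PCoA eigenvectors, Moran's I, crown ages.

The comparative machinery here supports phylogenetic eigenvector regression
(PVR): patristic distances between the tips of a dated tree are double-centred
as in principal coordinates analysis, and the eigenvectors of the resulting
inner-product matrix serve as predictors that absorb phylogenetic structure.
Crown ages (age of the most recent common ancestor of a clade's living
species) feed the clade-age and paleotemperature models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "EigenvectorBasis",
    "read_newick",
    "read_newick_string",
    "write_newick",
    "read_clade_map",
    "write_clade_map",
    "double_centre",
    "cophenetic_distances",
    "pcoa_eigenvectors",
    "morans_i",
    "MoranResult",
    "crown_age",
    "clade_crown_ages",
]


class PhyloError(ValueError):
    """Invalid tree, labels, or distance input."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in millions of years.

    ``clade_map`` optionally assigns each tip a ``(family, order)`` pair;
    families must nest within orders (each family maps to exactly one order).
    """

    tree: dendropy.Tree
    clade_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tree.is_rooted = True  # analyses assume a rooted, dated tree
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PhyloError(f"duplicate tip labels: {dupes[:10]}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node.parent_node is None:
                continue  # root edge may be lengthless
            if edge.length is None:
                raise PhyloError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise PhyloError(f"negative branch length {edge.length}")
        if self.clade_map:
            missing = [l for l in labels if l not in self.clade_map]
            if missing:
                raise PhyloError(f"tips missing from clade_map: {missing[:10]}")
            fam_to_order: dict[str, str] = {}
            for fam, order in self.clade_map.values():
                if fam_to_order.setdefault(fam, order) != order:
                    raise PhyloError(f"family {fam!r} assigned to multiple orders")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def families(self) -> dict[str, list[str]]:
        """Tip lists per family (requires clade_map)."""
        out: dict[str, list[str]] = {}
        for tip, (fam, _) in self.clade_map.items():
            out.setdefault(fam, []).append(tip)
        return out

    def orders(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tip, (_, order) in self.clade_map.items():
            out.setdefault(order, []).append(tip)
        return out

    def height(self) -> float:
        """Maximum root-to-tip path length (My)."""
        _, depths = _node_depths(self.tree)
        return max(depths[leaf] for leaf in self.tree.leaf_node_iter())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        _, depths = _node_depths(self.tree)
        tip_depths = [depths[leaf] for leaf in self.tree.leaf_node_iter()]
        return max(tip_depths) - min(tip_depths) <= tol * max(max(tip_depths), 1.0)


@dataclass
class DistanceMatrix:
    """Symmetric patristic-distance matrix over tip labels (My)."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise PhyloError(f"distance matrix shape {self.D.shape} != ({n}, {n})")
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise PhyloError("distance matrix not symmetric")
        if np.any(np.diag(self.D) != 0):
            raise PhyloError("distance matrix diagonal not zero")
        if np.any(self.D < 0):
            raise PhyloError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise PhyloError("distance CSV must have identical row and column labels")
        return cls(list(df.index), df.to_numpy(dtype=float))


@dataclass
class EigenvectorBasis:
    """Positive-eigenvalue PCoA axes of a double-centred distance matrix.

    Columns of ``V`` are unit-norm, mutually orthogonal, mean-centred, and
    ordered by descending eigenvalue. The sign of each column is fixed so its
    first nonzero entry is positive, making runs reproducible across linear
    algebra backends.
    """

    labels: list[str]
    V: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise PhyloError("eigenvalues must be non-increasing")

    @property
    def k(self) -> int:
        return self.V.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"V{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.V, index=self.labels, columns=cols)


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(path, clade_map: dict[str, tuple[str, str]] | None = None) -> Phylogeny:
    """Read a Newick tree with branch lengths.

    Unlabeled internal nodes are allowed; every non-root edge must carry a
    length. Malformed input raises with the parser's position information.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise PhyloError(f"malformed Newick in {path}: {exc}") from exc
    return Phylogeny(tree, clade_map or {})


def read_newick_string(s: str, clade_map: dict[str, tuple[str, str]] | None = None) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(
            data=s, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise PhyloError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree, clade_map or {})


def write_newick(phylo: Phylogeny, path) -> None:
    phylo.tree.write(path=str(path), schema="newick", suppress_rooting=True,
                     unquoted_underscores=True)


def read_clade_map(path) -> dict[str, tuple[str, str]]:
    """CSV with columns species,family,order -> tip -> (family, order)."""
    df = pd.read_csv(path)
    required = {"species", "family", "order"}
    if not required.issubset(df.columns):
        raise PhyloError(f"clade map CSV needs columns {sorted(required)}, got {list(df.columns)}")
    return {r.species: (r.family, r.order) for r in df.itertuples()}


def write_clade_map(clade_map: dict[str, tuple[str, str]], path) -> None:
    rows = [{"species": sp, "family": fo[0], "order": fo[1]} for sp, fo in clade_map.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Distances and eigenvectors


def _node_depths(tree: dendropy.Tree):
    """Distance of every node from the root; returns (root, {node: depth})."""
    depths: dict = {}
    root = tree.seed_node
    depths[root] = 0.0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        length = node.edge.length or 0.0
        depths[node] = depths[node.parent_node] + length
    return root, depths


def cophenetic_distances(phylo: Phylogeny) -> DistanceMatrix:
    """Pairwise patristic distances: sum of branch lengths tip-to-tip."""
    labels = phylo.tip_labels
    n = len(labels)
    if n < 2:
        raise PhyloError("need >=2 tips for a distance matrix")
    pdm = phylo.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in phylo.tree.taxon_namespace}
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D)


def double_centre(D: np.ndarray) -> np.ndarray:
    """Gower transform B = -1/2 * J * (D squared elementwise) * J."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D * D) @ J


def pcoa_eigenvectors(dm: DistanceMatrix, rel_tol: float = 1e-10) -> EigenvectorBasis:
    """PCoA of the distance matrix; retain positive-eigenvalue axes only.

    Axes with eigenvalue <= ``rel_tol`` times the largest eigenvalue are
    discarded. Columns are unit-norm (not rescaled by sqrt-eigenvalue), which
    leaves downstream regressions invariant to the scaling convention.
    """
    if np.all(dm.D == 0):
        raise PhyloError("degenerate distances: all zero")
    B = double_centre(dm.D)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > rel_tol * eigvals[0]
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    for j in range(eigvecs.shape[1]):  # deterministic sign convention
        col = eigvecs[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            eigvecs[:, j] = -col
    return EigenvectorBasis(dm.labels, eigvecs, eigvals)


# ---------------------------------------------------------------------------
# Moran's I


@dataclass
class MoranResult:
    I: float
    expected: float
    p_value: float | None
    n_permutations: int


def _moran_statistic(x: np.ndarray, W: np.ndarray) -> float:
    n = x.size
    xc = x - x.mean()
    denom = float(xc @ xc)
    s0 = W.sum()
    return float(n / s0 * (xc @ W @ xc) / denom)


def morans_i(
    x,
    dm: DistanceMatrix,
    weighting: str = "inverse",
    n_permutations: int = 999,
    seed: int | None = 0,
    alternative: str = "greater",
) -> MoranResult:
    """Phylogenetic autocorrelation of tip values ``x``.

    Weights are either inverse patristic distance (``"inverse"``, default) or
    ``1 - D/Dmax`` (``"linear"``); the diagonal is zero. The p-value comes
    from permuting values across tips; ``alternative="greater"`` tests for
    positive autocorrelation (similarity of close relatives).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n != len(dm.labels):
        raise PhyloError(f"x has {n} values but distance matrix has {len(dm.labels)} tips")
    if np.ptp(x) == 0:
        raise PhyloError("zero variance in x: Moran's I undefined")
    D = dm.D
    with np.errstate(divide="ignore"):
        if weighting == "inverse":
            W = np.where(D > 0, 1.0 / np.where(D > 0, D, 1.0), 0.0)
        elif weighting == "linear":
            W = 1.0 - D / D.max()
        else:
            raise PhyloError(f"unknown weighting {weighting!r}")
    np.fill_diagonal(W, 0.0)
    I_obs = _moran_statistic(x, W)
    expected = -1.0 / (n - 1)
    p = None
    if n_permutations > 0:
        if n < 3:
            raise PhyloError("permutation test needs >=3 tips")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            I_perm = _moran_statistic(rng.permutation(x), W)
            if alternative == "greater":
                count += I_perm >= I_obs
            elif alternative == "two-sided":
                count += abs(I_perm - expected) >= abs(I_obs - expected)
            else:
                raise PhyloError(f"unknown alternative {alternative!r}")
        p = (1 + count) / (n_permutations + 1)
    return MoranResult(I_obs, expected, p, n_permutations)


# ---------------------------------------------------------------------------
# Crown ages


def crown_age(phylo: Phylogeny, tip_set, ultrametric_tol: float = 1e-6) -> float:
    """Age (My before present) of the MRCA of ``tip_set``.

    For a singleton the crown is undefined; the stem age (depth of the
    terminal branch's parent) is returned with a warning. On non-ultrametric
    trees node age is the mean distance to the node's descendant tips.
    """
    tip_set = list(tip_set)
    if not tip_set:
        raise PhyloError("empty tip set")
    labels = set(phylo.tip_labels)
    unknown = [t for t in tip_set if t not in labels]
    if unknown:
        raise PhyloError(f"unknown tip label(s): {unknown[:10]}")
    if not phylo.is_ultrametric(ultrametric_tol):
        warnings.warn("tree is not ultrametric; crown ages use mean distance to tips")
    if len(tip_set) == 1:
        warnings.warn(f"singleton clade {tip_set[0]!r}: returning stem age, not crown age")
        leaf = next(l for l in phylo.tree.leaf_node_iter() if l.taxon.label == tip_set[0])
        node = leaf.parent_node
        if node is None:  # single-tip tree
            return 0.0
    else:
        node = phylo.tree.mrca(taxon_labels=tip_set)
    return _node_age(phylo.tree, node)


def _node_age(tree: dendropy.Tree, node) -> float:
    _, depths = _node_depths(tree)
    tips = node.leaf_nodes()
    return float(np.mean([depths[t] - depths[node] for t in tips]))


def clade_crown_ages(phylo: Phylogeny, level: str) -> dict[str, float]:
    """Crown age per family or order, from the clade_map annotations."""
    if level not in ("family", "order"):
        raise PhyloError(f"level must be 'family' or 'order', got {level!r}")
    clades = phylo.families() if level == "family" else phylo.orders()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {name: crown_age(phylo, tips) for name, tips in clades.items()}
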