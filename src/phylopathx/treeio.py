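"""Trees: Newick I/O, classification-derived topologies, distances, covariances.

The phylogeny is the source of the among-taxon covariance structure used by
every statistical routine in this package.  Trees may come from a Newick
string or be built from a nested classification table (e.g. a Glottolog-style
language classification), in which case each classification level contributes
one unit of branch length and tips are padded so the tree is ultrametric.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "CovarianceStructure",
    "read_newick",
    "tree_from_classification",
    "patristic_distances",
    "covariance",
    "read_classification_table",
]

DEFAULT_BRANCH_LENGTH = 1.0


class Phylogeny:
    """A rooted tree with labelled tips and non-negative branch lengths.

    Polytomies are allowed.  Tip order is fixed at construction and all
    matrices returned by this class follow that order.
    """

    def __init__(self, tree: dendropy.Tree):
        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 2:
            raise ValueError("a phylogeny needs at least 2 tips")
        labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
        if any(lb is None for lb in labels):
            raise ValueError("every tip must carry a label")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length!r}")
        self._tree = tree
        self.tips: list[str] = labels
        self._tip_index = {lb: i for i, lb in enumerate(labels)}
        self._cov: np.ndarray | None = None
        self._pat: np.ndarray | None = None
        self._contrast: np.ndarray | None = None

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return read_newick(text)

    # -- basic accessors ----------------------------------------------

    def __len__(self) -> int:
        return len(self.tips)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def write_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- matrices -----------------------------------------------------

    def _depths(self) -> dict:
        depth = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            length = node.edge.length
            if length is None:
                length = DEFAULT_BRANCH_LENGTH
            depth[node] = depth[node.parent_node] + length
        return depth

    def _compute_matrices(self) -> None:
        n = len(self.tips)
        depth = self._depths()
        cov = np.zeros((n, n))
        tip_depth = np.zeros(n)
        # postorder sweep: tips below each internal node share its depth
        leafsets: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = self._tip_index[node.taxon.label]
                tip_depth[i] = depth[node]
                leafsets[node] = [i]
                continue
            child_sets = [leafsets.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a, b in itertools.combinations(child_sets, 2):
                cov[np.ix_(a, b)] = d
                cov[np.ix_(b, a)] = d
            leafsets[node] = [i for s in child_sets for i in s]
        np.fill_diagonal(cov, tip_depth)
        pat = tip_depth[:, None] + tip_depth[None, :] - 2.0 * cov
        np.fill_diagonal(pat, 0.0)
        self._cov, self._pat = cov, pat

    def brownian_covariance(self) -> np.ndarray:
        """Shared root-to-MRCA path lengths (the Brownian-motion VCV)."""
        if self._cov is None:
            self._compute_matrices()
        return self._cov.copy()

    def patristic_matrix(self) -> np.ndarray:
        if self._pat is None:
            self._compute_matrices()
        return self._pat.copy()

    def contrast_weights(self) -> np.ndarray:
        """Rows of tip weights giving sister-clade contrasts at internal nodes.

        Nodal values are means of daughter values computed tips-to-root, so
        each nodal value is a fixed linear combination of tip states.  Each
        row ``w`` of the returned matrix represents one unordered pair of
        daughters at an internal node; ``|w @ states|`` is that pair's
        contribution to the observed sum of sister-clade differences.
        Polytomies contribute all unordered daughter pairs.
        """
        if self._contrast is not None:
            return self._contrast.copy()
        n = len(self.tips)
        vec: dict = {}
        rows: list[np.ndarray] = []
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                v = np.zeros(n)
                v[self._tip_index[node.taxon.label]] = 1.0
                vec[node] = v
                continue
            child_vecs = [vec.pop(ch) for ch in node.child_nodes()]
            for a, b in itertools.combinations(child_vecs, 2):
                rows.append(a - b)
            vec[node] = np.mean(child_vecs, axis=0)
        self._contrast = np.asarray(rows)
        return self._contrast.copy()

    def subset_covariance(self, labels: Sequence[str]) -> np.ndarray:
        """Brownian VCV restricted to ``labels`` (pruning = taking a submatrix)."""
        idx = [self._tip_index[lb] for lb in labels]
        return self.brownian_covariance()[np.ix_(idx, idx)]

    def subset_patristic(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self._tip_index[lb] for lb in labels]
        return self.patristic_matrix()[np.ix_(idx, idx)]


@dataclass
class CovarianceStructure:
    """A taxa x taxa covariance matrix with its correlation transform.

    ``transform`` is one of ``none`` (Brownian), ``lambda`` (Pagel's lambda
    multiplying the off-diagonals) or ``ou`` (Ornstein-Uhlenbeck-style decay
    ``exp(-alpha * d_ij)`` of correlations with patristic distance).
    """

    matrix: np.ndarray
    transform: str
    parameter: float | None
    tips: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("covariance diagonal must be positive")
        self.matrix = m


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Missing branch lengths are filled with 1.0 (a warning is emitted);
    duplicate tip labels are an error.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy errors carry line/column positions
        raise ValueError(f"Newick parse error: {exc}") from exc
    filled = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = DEFAULT_BRANCH_LENGTH
            filled += 1
    if filled:
        warnings.warn(
            f"{filled} branch length(s) missing; filled with "
            f"{DEFAULT_BRANCH_LENGTH}",
            UserWarning,
            stacklevel=2,
        )
    return Phylogeny(tree)


def tree_from_classification(
    rows: Mapping[str, Sequence[str]], grafen: bool = False
) -> Phylogeny:
    """Build a tree from nested classifications (taxon -> list of group names).

    Taxa sharing a prefix of groups share an internal node.  Each level
    contributes one unit of branch length; tip edges are stretched so every
    root-to-tip depth equals ``max levels + 1`` (the tree is ultrametric).
    Groups containing a single taxon collapse onto their tip, so singleton
    families attach directly at the root.  The construction is invariant to
    the order of ``rows``.

    With ``grafen=True`` branch lengths are replaced by Grafen's (1989)
    scaling: each node's height is proportional to its clade size minus one.
    """
    if not rows:
        raise ValueError("empty classification")
    for taxon, levels in rows.items():
        if len(levels) == 0:
            raise ValueError(f"taxon {taxon!r} has an empty classification")
    max_levels = max(len(levels) for levels in rows.values())
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    node_for_path: dict = {(): tree.seed_node}
    for taxon in sorted(rows, key=lambda t: (tuple(rows[t]), t)):
        levels = tuple(rows[taxon])
        for k in range(1, len(levels) + 1):
            path = levels[:k]
            if path not in node_for_path:
                node_for_path[path] = node_for_path[path[:-1]].new_child(
                    edge_length=1.0
                )
        pad = float(max_levels - len(levels))
        leaf = node_for_path[levels].new_child(edge_length=1.0 + pad)
        leaf.taxon = ns.new_taxon(label=taxon)
    tree.suppress_unifurcations()
    if grafen:
        _apply_grafen(tree)
    return Phylogeny(tree)


def _apply_grafen(tree: dendropy.Tree) -> None:
    n = sum(1 for _ in tree.leaf_node_iter())
    size: dict = {}
    for node in tree.postorder_node_iter():
        size[node] = 1 if node.is_leaf() else sum(size[c] for c in node.child_nodes())
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        h_parent = (size[node.parent_node] - 1) / (n - 1)
        h_node = 0.0 if node.is_leaf() else (size[node] - 1) / (n - 1)
        node.edge.length = h_parent - h_node


def patristic_distances(tree: Phylogeny) -> np.ndarray:
    """Symmetric zero-diagonal matrix of tip-to-tip path lengths."""
    return tree.patristic_matrix()


def covariance(
    tree: Phylogeny, transform: str = "none", parameter: float | None = None
) -> CovarianceStructure:
    """Phylogenetic covariance under a correlation-parameter transform.

    ``none``   -> Brownian VCV (shared root-to-MRCA path lengths).
    ``lambda`` -> off-diagonals multiplied by ``parameter`` in [0, 1].
    ``ou``     -> correlations decay as ``exp(-parameter * d_ij)`` with the
                  patristic distance ``d_ij``; the diagonal keeps the
                  Brownian tip variances (``parameter`` >= 0).
    """
    brown = tree.brownian_covariance()
    if transform == "none":
        mat = brown
        parameter = None
    elif transform == "lambda":
        if parameter is None or not 0.0 <= parameter <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {parameter!r}")
        mat = brown * parameter
        np.fill_diagonal(mat, np.diag(brown))
    elif transform == "ou":
        if parameter is None or parameter < 0:
            raise ValueError(f"alpha must be >= 0, got {parameter!r}")
        d = tree.patristic_matrix()
        sd = np.sqrt(np.diag(brown))
        mat = np.outer(sd, sd) * np.exp(-parameter * d)
        np.fill_diagonal(mat, np.diag(brown))
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return CovarianceStructure(
        matrix=mat, transform=transform, parameter=parameter, tips=tuple(tree.tips)
    )


def read_classification_table(path, sep: str = "\t"):
    """Read a classification table into the mapping ``tree_from_classification``
    expects.

    Two layouts are supported: a ``taxon`` column followed by ``level1..levelK``
    columns (empty trailing cells allowed), or a ``taxon`` column plus a single
    ``classification`` column of semicolon-delimited group names.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("classification table needs a taxon column plus levels")
    taxa = df.iloc[:, 0]
    rows: dict[str, list[str]] = {}
    if df.shape[1] == 2 and df.iloc[:, 1].str.contains(";").any():
        for taxon, cell in zip(taxa, df.iloc[:, 1]):
            rows[taxon] = [p.strip() for p in str(cell).split(";") if p.strip()]
    else:
        for _, rec in df.iterrows():
            levels = [v for v in rec.iloc[1:] if isinstance(v, str) and v.strip()]
            rows[rec.iloc[0]] = levels
    return rows
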