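"""Read, validate, and write skull bone-contact networks and phylogenies.

A skull is modeled as an undirected, unweighted graph: nodes are bones,
links are physical contacts (sutures and synchondroses).  The on-disk
interchange form is a labeled binary adjacency matrix (CSV), with a
tab-separated edge list and GraphML as alternatives.  Phylogenies are
Newick trees with branch lengths in time units (Myr for calibrated trees).

Bone labels follow the convention ``<base>_l`` / ``<base>_r`` for paired
bilateral bones (e.g. ``par_l``, ``par_r``) and a bare base name for
unpaired midline bones (e.g. ``occ``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SkullNetwork",
    "PhyloTree",
    "ValidationError",
    "TreeParseError",
    "read_adjacency",
    "write_network",
    "read_tree",
    "split_side",
    "FORMATS",
]

FORMATS = ("csv_matrix", "edge_list", "graphml")

SIDE_SUFFIXES = ("_l", "_r")


class ValidationError(ValueError):
    """A network or tree violates a structural invariant."""


class TreeParseError(ValueError):
    """A Newick string could not be parsed."""


def split_side(bone: str) -> tuple[str, str | None]:
    """Split a bone label into (base, side); side is ``'l'``, ``'r'`` or None."""
    for suf in SIDE_SUFFIXES:
        if bone.endswith(suf):
            return bone[: -len(suf)], suf[-1]
    return bone, None


@dataclass(frozen=True)
class SkullNetwork:
    """One taxon's bone-contact network.

    Parameters
    ----------
    taxon_name : str
        Taxon label.
    bones : tuple of str
        Ordered, unique bone labels.
    adjacency : ndarray
        Square symmetric 0/1 matrix with zero diagonal; ``adjacency[i, j] == 1``
        iff bones ``i`` and ``j`` are in physical contact.  The graph must be
        connected: a skull is a single articulated unit, so a disconnected
        matrix signals a coding error and is rejected.
    """

    taxon_name: str
    bones: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        bones = tuple(str(b) for b in self.bones)
        object.__setattr__(self, "bones", bones)
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency must be square, got shape {a.shape}")
        if a.shape[0] != len(bones):
            raise ValidationError(
                f"{len(bones)} bone labels but adjacency is {a.shape[0]}x{a.shape[0]}"
            )
        if len(set(bones)) != len(bones):
            dups = sorted({b for b in bones if bones.count(b) > 1})
            raise ValidationError(f"duplicate bone labels: {dups}")
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))][0]
            i, j = np.argwhere(a == bad)[0]
            raise ValidationError(
                f"non-binary entry {bad!r} at ({bones[i]}, {bones[j]}); "
                "contacts are coded 1/0"
            )
        a = a.astype(np.int8)
        asym = np.argwhere(a != a.T)
        if asym.size:
            i, j = asym[0]
            raise ValidationError(
                f"asymmetric adjacency: A[{bones[i]}, {bones[j]}] != "
                f"A[{bones[j]}, {bones[i]}]"
            )
        if np.any(np.diag(a) != 0):
            i = int(np.argwhere(np.diag(a) != 0)[0][0])
            raise ValidationError(f"nonzero diagonal at bone {bones[i]}: no self-contacts")
        if len(bones) >= 2:
            g = nx.from_numpy_array(a)
            if not nx.is_connected(g):
                comps = [
                    sorted(bones[i] for i in comp)
                    for comp in nx.connected_components(g)
                ]
                raise ValidationError(
                    f"network is disconnected; components: {comps}"
                )
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)

    # -- basic descriptors -------------------------------------------------

    @property
    def n_bones(self) -> int:
        return len(self.bones)

    @property
    def n_contacts(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        """Degree (number of contacts) per bone, in ``bones`` order."""
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        """Sorted undirected edge list as (bone, bone) label pairs."""
        out = []
        for i, j in zip(*np.triu_indices(self.n_bones, k=1)):
            if self.adjacency[i, j]:
                pair = tuple(sorted((self.bones[i], self.bones[j])))
                out.append(pair)
        return sorted(out)

    def neighbors(self, bone: str) -> tuple[str, ...]:
        i = self.bones.index(bone)
        return tuple(self.bones[j] for j in np.flatnonzero(self.adjacency[i]))

    def has_edge(self, u: str, v: str) -> bool:
        return bool(self.adjacency[self.bones.index(u), self.bones.index(v)])

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.bones)
        g.add_edges_from(self.edges())
        g.graph["taxon_name"] = self.taxon_name
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, taxon_name: str | None = None) -> "SkullNetwork":
        bones = tuple(str(n) for n in g.nodes())
        a = nx.to_numpy_array(g, nodelist=list(g.nodes()), dtype=np.int8)
        name = taxon_name or g.graph.get("taxon_name", "unnamed")
        return cls(name, bones, a)

    @classmethod
    def from_edges(
        cls,
        taxon_name: str,
        bones: Sequence[str],
        edges: Iterable[tuple[str, str]],
    ) -> "SkullNetwork":
        bones = tuple(bones)
        idx = {b: i for i, b in enumerate(bones)}
        a = np.zeros((len(bones), len(bones)), dtype=np.int8)
        for u, v in edges:
            i, j = idx[u], idx[v]
            a[i, j] = a[j, i] = 1
        return cls(taxon_name, bones, a)

    def relabeled(self, mapping: Mapping[str, str]) -> "SkullNetwork":
        """Return a copy with bone labels renamed through ``mapping``."""
        bones = tuple(mapping.get(b, b) for b in self.bones)
        return SkullNetwork(self.taxon_name, bones, np.array(self.adjacency))


# ---------------------------------------------------------------------------
# Network readers / writers
# ---------------------------------------------------------------------------


def read_adjacency(
    path: str | os.PathLike,
    format: str = "csv_matrix",
    taxon_name: str | None = None,
    label_map: Mapping[str, str] | None = None,
) -> SkullNetwork:
    """Read and validate a skull network.

    ``csv_matrix`` expects a labeled square matrix: first row and first column
    are bone labels (identical sets, same order), cells strictly ``0``/``1``.
    ``edge_list`` expects two tab-separated label columns, one undirected edge
    per line (duplicates collapsed).  ``graphml`` is read via networkx.

    ``label_map`` optionally renames incoming labels before validation, to
    normalize external deposits to the ``_l``/``_r`` side convention.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    name = taxon_name or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    if format == "csv_matrix":
        df = pd.read_csv(path, index_col=0)
        rows = [str(x) for x in df.index]
        cols = [str(x) for x in df.columns]
        if rows != cols:
            raise ValidationError(
                f"row labels and column labels differ: {rows} vs {cols}"
            )
        net = SkullNetwork(name, tuple(rows), df.to_numpy())
    elif format == "edge_list":
        edges: set[tuple[str, str]] = set()
        nodes: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected two tab-separated labels"
                    )
                u, v = parts
                for n in (u, v):
                    if n not in nodes:
                        nodes.append(n)
                edges.add(tuple(sorted((u, v))))
        net = SkullNetwork.from_edges(name, nodes, edges)
    else:  # graphml
        g = nx.read_graphml(path)
        net = SkullNetwork.from_networkx(nx.Graph(g), taxon_name=name)
    if label_map:
        net = net.relabeled(label_map)
    return net


def write_network(net: SkullNetwork, path: str | os.PathLike, format: str = "csv_matrix") -> None:
    """Write a validated network; ``read_adjacency`` round-trips it exactly."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "csv_matrix":
        df = pd.DataFrame(net.adjacency, index=net.bones, columns=net.bones)
        df.to_csv(path)
    elif format == "edge_list":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in net.edges():
                fh.write(f"{u}\t{v}\n")
    else:
        nx.write_graphml(net.to_networkx(), path)


# ---------------------------------------------------------------------------
# Phylogenies
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted phylogeny with branch lengths, backed by a dendropy tree.

    Branch lengths must be nonnegative where present; operations that need
    them (contrasts, Brownian-motion covariances) raise if any relevant
    branch is missing or nonpositive.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise ValidationError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dups}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        self._tip_labels = tuple(labels)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parser error types
            msg = str(exc)
            if "multiple" in msg.lower() or "duplicate" in msg.lower():
                raise ValidationError(f"duplicate tip labels: {msg}") from exc
            raise TreeParseError(f"malformed Newick: {msg}") from exc
        return cls(tree)

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def is_bifurcating(self) -> bool:
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) != 2:
                return False
        return True

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def require_branch_lengths(self, positive: bool = True) -> None:
        """Raise unless every non-root branch has a (positive) length."""
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None:
                raise ValidationError("tree has branches without lengths")
            if positive and bl <= 0:
                raise ValidationError(f"nonpositive branch length {bl}")

    def vcv(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Brownian-motion covariance: shared root-to-MRCA path length per tip pair.

        Returns tip labels (tree leaf order) and the matrix ``C`` with
        ``C[i, j]`` the depth of the most recent common ancestor of tips
        ``i`` and ``j`` and ``C[i, i]`` the root-to-tip distance.
        """
        self.require_branch_lengths(positive=False)
        leaves = list(self._tree.leaf_node_iter())
        depth: dict[int, float] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            base = depth[id(parent)] if parent is not None else 0.0
            bl = node.edge.length or 0.0
            depth[id(node)] = base + (bl if parent is not None else 0.0)
        # root-to-tip distances
        d_root = np.array([depth[id(leaf)] for leaf in leaves])
        pdm = self._tree.phylogenetic_distance_matrix()
        n = len(leaves)
        c = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                if i == j:
                    c[i, i] = d_root[i]
                else:
                    dij = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
                    c[i, j] = c[j, i] = 0.5 * (d_root[i] + d_root[j] - dij)
        labels = tuple(leaf.taxon.label for leaf in leaves)
        return labels, c


def read_tree(path: str | os.PathLike) -> PhyloTree:
    """Read a Newick tree file into a validated :class:`PhyloTree`."""
    with open(path, encoding="utf-8") as fh:
        return PhyloTree.from_newick(fh.read())
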