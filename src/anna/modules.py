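"""Connectivity-module identification in bone-contact networks.

Modules are groups of bones with more contacts among themselves than to
the rest of the skull.  The procedure is deterministic:

1. compute the pairwise topological overlap (TO), a normalized count of
   shared neighbors, ``TO_ij = J(n_i, n_j) / min_k(i, j)``;
2. hierarchically cluster the bones on the dissimilarity ``1 - TO``;
3. cut the dendrogram at every cluster count ``1..N``, score each
   partition with Newman's modularity ``Q``, and keep the partition with
   the highest ``Q`` (ties: fewest modules);
4. summarize modularity strength as ``M = n_modules * Q``.

The two-cluster cut of the same dendrogram (its first split) defines the
two *macromodules* — in skulls, the facial and cranial regions.  Helper
routines detect left/right *specular* module pairs and assign anatomical
module-type labels (neurocranial, midfacial, palatal, premaxillary) from
anchor bones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .network_io import SkullNetwork, split_side

__all__ = [
    "TOMatrix",
    "Dendrogram",
    "PartitionResult",
    "MacromoduleResult",
    "SpecularPair",
    "topological_overlap",
    "hierarchical_modules",
    "newman_q",
    "modularity_strength",
    "macromodules",
    "detect_specular",
    "label_modules",
    "TO_CONVENTIONS",
    "LINKAGES",
]

logger = logging.getLogger(__name__)

TO_CONVENTIONS = ("open_neighborhood", "raw_degree", "gtom1")
LINKAGES = ("average", "complete", "single")

#: anchor bone (base name) -> module-type label, in priority order
ANCHOR_PRIORITY = (("occ", "neurocranial"), ("eth", "midfacial"),
                   ("pal", "palatal"), ("pmx", "premaxillary"))


@dataclass(frozen=True)
class TOMatrix:
    """Symmetric topological-overlap matrix; entries in [0, 1], diagonal 1."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    convention: str = "open_neighborhood"


@dataclass(frozen=True)
class Dendrogram:
    """Hierarchical merge sequence on dissimilarity ``1 - TO``.

    ``linkage_matrix`` is in scipy ``linkage`` format; leaf ``i`` is
    ``labels[i]``.
    """

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray = field(repr=False)
    method: str = "average"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Cluster index per leaf for the ``n_clusters``-group cut."""
        if n_clusters == len(self.labels):
            return np.arange(len(self.labels))
        return sch.cut_tree(self.linkage_matrix, n_clusters=n_clusters).ravel()


@dataclass
class PartitionResult:
    """A module assignment with its dendrogram, Q and M = n_modules * Q."""

    bones: tuple[str, ...]
    assignment: dict[str, int]
    n_modules: int
    q: float
    dendrogram: Dendrogram | None = None
    q_by_cluster_count: tuple[float, ...] | None = None
    module_labels: dict[int, str] | None = None
    specular_pairs: list["SpecularPair"] | None = None

    def __post_init__(self) -> None:
        missing = set(self.bones) - set(self.assignment)
        if missing:
            raise ValueError(f"assignment misses bones: {sorted(missing)}")
        if self.n_modules != len(set(self.assignment[b] for b in self.bones)):
            raise ValueError("n_modules inconsistent with assignment")

    @property
    def m(self) -> float:
        """Modularity strength, exactly ``n_modules * q``."""
        return self.n_modules * self.q

    def modules(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for bone, mod in self.assignment.items():
            out.setdefault(mod, set()).add(bone)
        return {k: frozenset(v) for k, v in sorted(out.items())}

    def labels_vector(self) -> np.ndarray:
        return np.array([self.assignment[b] for b in self.bones])


@dataclass(frozen=True)
class MacromoduleResult:
    """The two-cluster (first-split) regions and module containment."""

    macromodules: tuple[frozenset[str], frozenset[str]]
    containment: dict[int, object]  # module id -> macromodule index or "straddles"
    is_refinement: bool


@dataclass(frozen=True)
class SpecularPair:
    """Two modules that mirror each other under the left/right suffix swap."""

    module_a: int
    module_b: int
    arbitrary_bones: tuple[str, ...]  # unpaired bones assigned to one side


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------


def topological_overlap(net: SkullNetwork, convention: str = "open_neighborhood") -> TOMatrix:
    """Pairwise topological overlap of all bones.

    All conventions share the numerator idea "neighbors in common" and the
    denominator "lowest connectivity of the pair"; they differ in whether
    the pair itself counts:

    - ``open_neighborhood`` (default): both the shared-neighbor count and
      the neighborhood sizes exclude the pair, so two mutually adjacent
      bones that share all other neighbors score exactly 1 and bones with
      disjoint neighborhoods score 0.
    - ``raw_degree``: shared neighbors over ``min(k_i, k_j)`` with raw
      degrees.
    - ``gtom1``: the Yip–Horvath generalized TOM with one-step
      neighborhoods, ``(J_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij)``.
    """
    if convention not in TO_CONVENTIONS:
        raise ValueError(f"convention must be one of {TO_CONVENTIONS}")
    if net.n_bones < 2:
        raise ValueError("topological overlap requires at least 2 bones")
    a = net.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    shared = a @ a  # shared[i, j] = # common neighbors (diag of A is 0)
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        if convention == "open_neighborhood":
            denom = min_k - a  # pair-excluded neighborhood sizes
            to = np.where(denom > 0, shared / denom, 0.0)
            # two bones joined only to each other: neighborhoods identical by
            # vacuity (only possible as a 2-bone network)
            both_empty = (a > 0) & (np.add.outer(k, k) == 2)
            to = np.where(both_empty, 1.0, to)
        elif convention == "raw_degree":
            to = np.where(min_k > 0, shared / min_k, 0.0)
        else:  # gtom1
            denom = min_k + 1.0 - a
            to = (shared + a) / denom
    np.fill_diagonal(to, 1.0)
    to = np.clip(0.5 * (to + to.T), 0.0, 1.0)
    return TOMatrix(net.bones, to, convention)


# ---------------------------------------------------------------------------
# Newman's Q and partition selection
# ---------------------------------------------------------------------------


def _q_from_labels(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Q = sum_c (e_c - a_c^2): within-module edge fraction minus the
    degree-preserving random expectation."""
    two_k = float(adjacency.sum())
    if two_k == 0:
        return 0.0
    deg = adjacency.sum(axis=1)
    q = 0.0
    for mod in np.unique(labels):
        idx = np.flatnonzero(labels == mod)
        e_c = adjacency[np.ix_(idx, idx)].sum() / two_k
        a_c = deg[idx].sum() / two_k
        q += e_c - a_c * a_c
    return float(q)


def newman_q(net: SkullNetwork, assignment: Mapping[str, int]) -> float:
    """Newman's modularity of a bone-to-module assignment.

    Equals ``(1/2K) * sum_ij [A_ij - k_i k_j / 2K] * delta(m_i, m_j)`` over
    all ordered pairs.  A single-module assignment scores exactly 0.
    """
    missing = [b for b in net.bones if b not in assignment]
    if missing:
        raise ValueError(f"assignment misses bones: {missing}")
    labels = np.array([assignment[b] for b in net.bones])
    return _q_from_labels(net.adjacency.astype(np.float64), labels)


def hierarchical_modules(
    net: SkullNetwork,
    linkage: str = "average",
    to_convention: str = "open_neighborhood",
) -> PartitionResult:
    """Identify connectivity modules by TO clustering + Q maximization.

    Builds the dendrogram on ``1 - TO`` with the given linkage, scores the
    partition at every cluster count ``1..N`` with Newman's Q, and returns
    the highest-Q partition (ties broken toward fewer modules, which on a
    dendrogram is the lower cut).  Fully deterministic given the network.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = net.n_bones
    adjacency = net.adjacency.astype(np.float64)
    to = topological_overlap(net, convention=to_convention)
    dissim = 1.0 - to.values
    np.fill_diagonal(dissim, 0.0)
    z = sch.linkage(squareform(dissim, checks=False), method=linkage)
    dendro = Dendrogram(net.bones, z, method=linkage)

    cuts = sch.cut_tree(z, n_clusters=list(range(1, n + 1)))  # (n_leaves, n_cuts)
    q_by_k = np.array(
        [_q_from_labels(adjacency, cuts[:, col]) for col in range(n)]
    )
    best_q = q_by_k.max()
    # ties toward fewest modules (lowest cluster count = lowest cut)
    best_col = int(np.flatnonzero(q_by_k >= best_q - 1e-12)[0])
    labels = cuts[:, best_col]
    # renumber modules by first appearance for stable ids
    remap: dict[int, int] = {}
    assignment = {}
    for bone, lab in zip(net.bones, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[bone] = remap[lab]
    return PartitionResult(
        bones=net.bones,
        assignment=assignment,
        n_modules=len(remap),
        q=float(q_by_k[best_col]),
        dendrogram=dendro,
        q_by_cluster_count=tuple(q_by_k),
    )


def modularity_strength(partition: PartitionResult) -> float:
    """Modularity strength ``M = n_modules * Q``."""
    return partition.m


# ---------------------------------------------------------------------------
# Macromodules, specular modules, anatomical labels
# ---------------------------------------------------------------------------


def macromodules(partition: PartitionResult) -> MacromoduleResult:
    """The two regions at the first split of the dendrogram.

    Each connectivity module of the optimal partition is reported as
    contained in one macromodule; modules whose bones straddle the first
    split are flagged ``"straddles"``.
    """
    if partition.dendrogram is None:
        raise ValueError("partition carries no dendrogram")
    if len(partition.bones) < 2:
        raise ValueError("macromodules require at least 2 bones")
    two_cut = partition.dendrogram.cut(2)
    sets: list[set[str]] = [set(), set()]
    for bone, lab in zip(partition.bones, two_cut):
        sets[int(lab)].add(bone)
    macro = (frozenset(sets[0]), frozenset(sets[1]))
    containment: dict[int, object] = {}
    refinement = True
    for mod_id, bones in partition.modules().items():
        inside = [i for i in (0, 1) if bones <= macro[i]]
        if inside:
            containment[mod_id] = inside[0]
        else:
            containment[mod_id] = "straddles"
            refinement = False
    return MacromoduleResult(macro, containment, refinement)


def _sided_split(bones: frozenset[str]) -> tuple[set[tuple[str, str]], set[str]]:
    sided, unpaired = set(), set()
    for b in bones:
        base, side = split_side(b)
        if side is None:
            unpaired.add(b)
        else:
            sided.add((base, side))
    return sided, unpaired


def detect_specular(partition: PartitionResult, net: SkullNetwork) -> list[SpecularPair]:
    """Find left/right mirror-image module pairs.

    Two modules are specular when their sided bone sets map onto each other
    under the ``_l`` <-> ``_r`` swap.  Unpaired midline bones are ignored in
    the matching — they are equally connected to both sides, so their
    assignment to one member of the pair is arbitrary — and are reported as
    such.  Networks without side suffixes yield an empty list.
    """
    mods = partition.modules()
    pairs: list[SpecularPair] = []
    swap = {"l": "r", "r": "l"}
    ids = sorted(mods)
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a_sided, a_unp = _sided_split(mods[ids[ai]])
            b_sided, b_unp = _sided_split(mods[ids[bi]])
            if not a_sided or not b_sided:
                continue
            mirrored = {(base, swap[s]) for base, s in a_sided}
            if mirrored == b_sided:
                pairs.append(
                    SpecularPair(
                        ids[ai], ids[bi], tuple(sorted(a_unp | b_unp))
                    )
                )
    return pairs


def label_modules(partition: PartitionResult) -> dict[int, str]:
    """Heuristic anatomical module-type labels from anchor bones.

    occipital (``occ``) anchors the neurocranial module; ethmoid (``eth``)
    the midfacial; both palatines (``pal_l`` + ``pal_r``, or an unpaired
    ``pal``) the palatal, absent a higher anchor; a premaxilla (``pmx``)
    the premaxillary, absent all others.  Anchor priority:
    occ > eth > pal > pmx; conflicts are logged.  A one-sided module gets a
    ``_l``/``_r`` suffix on its label.
    """
    out: dict[int, str] = {}
    for mod_id, bones in partition.modules().items():
        bases = {}
        for b in bones:
            base, side = split_side(b)
            bases.setdefault(base, set()).add(side)
        hits = []
        for anchor, label in ANCHOR_PRIORITY:
            if anchor not in bases:
                continue
            if anchor == "pal" and not (
                {"l", "r"} <= bases["pal"] or None in bases["pal"]
            ):
                continue
            hits.append(label)
        label = hits[0] if hits else "unlabeled"
        if len(hits) > 1:
            logger.info(
                "module %d contains several anchors (%s); keeping %s",
                mod_id, ", ".join(hits), label,
            )
        sided = [s for _, s_set in bases.items() for s in s_set if s is not None]
        if len(sided) >= 2 and len(set(sided)) == 1:
            label = f"{label}_{sided[0]}"
        out[mod_id] = label
    return out
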