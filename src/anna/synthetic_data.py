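"""Synthetic skull networks, phylogenies, and evolving traits.

These generators produce inputs with the statistical structure the
analysis assumes — bilaterally symmetric, connected, binary bone-contact
networks at the scale of real mammalian skulls (roughly 20–25 bones, a
quarter of all possible contacts realized), ultrametric pure-birth trees,
and continuous traits evolving by Brownian motion — so every pipeline
stage can be exercised and calibrated without external data.  They match
scale and structure, not bone-by-bone anatomy.

Bilateral symmetry is enforced by sampling left-side and cross-side
contacts and mirroring them, because left/right specular modules can only
arise in symmetric networks.  Connectivity is repaired by adding minimal
bridging contacts between components (mirrored), rather than rejecting,
to keep generation fast at low densities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network_io import PhyloTree, SkullNetwork, split_side

__all__ = [
    "SyntheticSkullSpec",
    "generate_skull",
    "generate_study_corpus",
    "generate_planted_network",
    "perturb_network",
    "generate_tree",
    "simulate_bm_trait",
    "PAIRED_BONES",
    "MIDLINE_BONES",
    "DEFAULT_MODULAR_LAYOUT",
]

#: default base names for bilateral bone pairs (suffixed _l / _r)
PAIRED_BONES = ("par", "tem", "zyg", "lac", "nas", "nch", "pal", "pmx", "max")
#: default names for unpaired midline bones
MIDLINE_BONES = ("occ", "sph", "eth", "vom", "fro", "bas")

#: two-region (cranial = 0 / facial = 1) layout used by the study corpus
DEFAULT_MODULAR_LAYOUT: dict[str, int] = {
    "par": 0, "tem": 0, "zyg": 0, "occ": 0, "sph": 0, "bas": 0,
    "lac": 1, "nas": 1, "nch": 1, "pal": 1, "pmx": 1, "max": 1,
    "eth": 1, "vom": 1, "fro": 1,
}


@dataclass(frozen=True)
class SyntheticSkullSpec:
    """Recipe for one synthetic skull network.

    ``modular_layout`` optionally plants a block structure: a map from
    bone base name (paired bases and midline names) to a block id, plus
    within/between-block contact probabilities.  Without a layout, contact
    orbits are sampled uniformly until ``target_density`` is reached.
    ``asymmetry_rate`` flips individual one-sided contacts after mirroring
    (default 0: perfectly symmetric).
    """

    n_pairs: int = 9
    n_midline: int = 6
    target_density: float = 0.25
    seed: int = 0
    modular_layout: Mapping[str, int] | None = None
    p_within: float = 0.9
    p_between: float = 0.05
    asymmetry_rate: float = 0.0
    paired_names: tuple[str, ...] = PAIRED_BONES
    midline_names: tuple[str, ...] = MIDLINE_BONES

    def __post_init__(self) -> None:
        if 2 * self.n_pairs + self.n_midline < 3:
            raise ValueError("need at least 3 bones in total")
        if not 0.0 < self.target_density < 1.0:
            raise ValueError("target_density must be in (0, 1)")

    @property
    def n_bones(self) -> int:
        return 2 * self.n_pairs + self.n_midline

    def bone_names(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(paired base names, midline names), extended with b##/m## if needed."""
        paired = list(self.paired_names[: self.n_pairs])
        while len(paired) < self.n_pairs:
            paired.append(f"b{len(paired) + 1:02d}")
        midline = list(self.midline_names[: self.n_midline])
        while len(midline) < self.n_midline:
            midline.append(f"m{len(midline) + 1:02d}")
        return tuple(paired), tuple(midline)


def _edge_orbits(paired: Sequence[str], midline: Sequence[str]):
    """Enumerate orbits of potential contacts under the l/r mirror swap.

    Each orbit is (base_u, base_v, edges): adding an orbit adds every edge
    in it, keeping the network bilaterally symmetric.
    """
    orbits = []
    for a, b in itertools.combinations(paired, 2):
        orbits.append((a, b, ((f"{a}_l", f"{b}_l"), (f"{a}_r", f"{b}_r"))))
        orbits.append((a, b, ((f"{a}_l", f"{b}_r"), (f"{a}_r", f"{b}_l"))))
    for a in paired:
        orbits.append((a, a, ((f"{a}_l", f"{a}_r"),)))
    for m in midline:
        for a in paired:
            orbits.append((m, a, ((m, f"{a}_l"), (m, f"{a}_r"))))
    for m1, m2 in itertools.combinations(midline, 2):
        orbits.append((m1, m2, ((m1, m2),)))
    return orbits


def _components(bones: Sequence[str], edges: set[tuple[str, str]]) -> list[set[str]]:
    adj: dict[str, set[str]] = {b: set() for b in bones}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set[str] = set()
    comps = []
    for b in bones:
        if b in seen:
            continue
        stack, comp = [b], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def generate_skull(spec: SyntheticSkullSpec) -> SkullNetwork:
    """Generate a bilaterally symmetric, connected, binary skull network.

    Deterministic given ``spec.seed``.  Contacts are chosen per mirror
    orbit; with a planted layout each orbit is kept with probability
    ``p_within`` (endpoints in the same block) or ``p_between``, otherwise
    orbits are added in random order until the density target is met.
    """
    rng = np.random.default_rng(spec.seed)
    paired, midline = spec.bone_names()
    bones = tuple(
        [f"{a}_l" for a in paired] + [f"{a}_r" for a in paired] + list(midline)
    )
    orbits = _edge_orbits(paired, midline)
    edges: set[tuple[str, str]] = set()
    if spec.modular_layout is not None:
        layout = spec.modular_layout
        missing = [b for b in (*paired, *midline) if b not in layout]
        if missing:
            raise ValueError(f"modular_layout misses bones: {missing}")
        for base_u, base_v, orbit_edges in orbits:
            p = spec.p_within if layout[base_u] == layout[base_v] else spec.p_between
            if rng.random() < p:
                edges.update(tuple(sorted(e)) for e in orbit_edges)
    else:
        n = len(bones)
        k_target = round(spec.target_density * n * (n - 1) / 2)
        order = rng.permutation(len(orbits))
        for pos in order:
            if len(edges) >= k_target:
                break
            edges.update(tuple(sorted(e)) for e in orbits[pos][2])
    # connectivity repair: bridge components with mirrored minimal contacts
    comps = _components(bones, edges)
    while len(comps) > 1:
        main, other = comps[0], comps[1]
        candidates = [
            (bu, bv, oe)
            for bu, bv, oe in orbits
            if any(e[0] in main and e[1] in other or e[0] in other and e[1] in main
                   for e in (tuple(sorted(x)) for x in oe))
        ]
        bu, bv, orbit_edges = candidates[int(rng.integers(len(candidates)))]
        edges.update(tuple(sorted(e)) for e in orbit_edges)
        comps = _components(bones, edges)
    if spec.asymmetry_rate > 0:
        sided = [
            e for bu, bv, oe in orbits for e in (tuple(sorted(x)) for x in oe)
            if split_side(e[0])[1] or split_side(e[1])[1]
        ]
        for e in sided:
            if rng.random() < spec.asymmetry_rate:
                edges.symmetric_difference_update({e})
        # a flip may disconnect; re-repair
        comps = _components(bones, edges)
        while len(comps) > 1:
            bu, bv, orbit_edges = orbits[int(rng.integers(len(orbits)))]
            edges.update(tuple(sorted(e)) for e in orbit_edges)
            comps = _components(bones, edges)
    name = f"synthetic_{spec.seed}"
    return SkullNetwork.from_edges(name, bones, edges)


def generate_study_corpus(
    n_taxa: int = 20,
    seed: int = 0,
    p_within: float = 0.40,
    p_between: float = 0.10,
) -> dict[str, SkullNetwork]:
    """A corpus of skull networks at the scale of real mammalian skulls.

    Each taxon ``t1..tN`` gets 8 or 9 bilateral pairs and 5 or 6 midline
    bones (21-24 bones in total, varying across taxa) with a planted
    cranial/facial two-region layout (:data:`DEFAULT_MODULAR_LAYOUT`) at
    within/between-region contact probabilities chosen to give an overall
    density near one quarter of all possible contacts.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    corpus: dict[str, SkullNetwork] = {}
    for i in range(n_taxa):
        spec = SyntheticSkullSpec(
            n_pairs=int(rng.integers(8, 10)),
            n_midline=int(rng.integers(5, 7)),
            seed=int(rng.integers(0, 2**31 - 1)),
            modular_layout=DEFAULT_MODULAR_LAYOUT,
            p_within=p_within,
            p_between=p_between,
        )
        net = generate_skull(spec)
        corpus[f"t{i + 1}"] = SkullNetwork(f"t{i + 1}", net.bones, np.array(net.adjacency))
    return corpus


def generate_planted_network(
    block_sizes: Sequence[int] = (12, 12),
    p_in: float = 0.9,
    p_out: float = 0.05,
    seed: int = 0,
    taxon_name: str | None = None,
) -> tuple[SkullNetwork, dict[str, int]]:
    """Planted-partition benchmark graph (no bilateral structure).

    Returns the connected network and the planted block membership.
    Within-block pairs are joined with probability ``p_in``, between-block
    pairs with ``p_out``; components are bridged minimally if needed.
    """
    rng = np.random.default_rng(seed)
    n = sum(block_sizes)
    labels = tuple(f"n{i + 1:02d}" for i in range(n))
    blocks: dict[str, int] = {}
    pos = 0
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            blocks[labels[pos]] = b
            pos += 1
    edges: set[tuple[str, str]] = set()
    for u, v in itertools.combinations(labels, 2):
        p = p_in if blocks[u] == blocks[v] else p_out
        if rng.random() < p:
            edges.add((u, v))
    comps = _components(labels, edges)
    while len(comps) > 1:
        u = sorted(comps[0])[int(rng.integers(len(comps[0])))]
        v = sorted(comps[1])[int(rng.integers(len(comps[1])))]
        edges.add(tuple(sorted((u, v))))
        comps = _components(labels, edges)
    net = SkullNetwork.from_edges(taxon_name or f"planted_{seed}", labels, edges)
    return net, blocks


def perturb_network(
    net: SkullNetwork,
    op: str,
    target: str | tuple[str, str],
    seed: int = 0,
) -> SkullNetwork:
    """Evolutionary perturbation: lose a bone or fuse two adjacent bones.

    ``lose_bone`` deletes the node (rejected if that disconnects the
    skull); ``fuse_bones`` merges two adjacent bones into one whose
    contacts are the union of both neighborhoods (their mutual contact
    disappears, duplicate contacts collapse).
    """
    if op == "lose_bone":
        if not isinstance(target, str) or target not in net.bones:
            raise ValueError(f"unknown bone {target!r}")
        keep = [b for b in net.bones if b != target]
        edges = [(u, v) for u, v in net.edges() if target not in (u, v)]
        if len(_components(keep, set(edges))) > 1:
            raise ValueError(f"removing {target!r} disconnects the skull")
        return SkullNetwork.from_edges(net.taxon_name, keep, edges)
    if op == "fuse_bones":
        u, v = target  # type: ignore[misc]
        if not net.has_edge(u, v):
            raise ValueError(f"bones {u!r} and {v!r} are not in contact; cannot fuse")
        base_u, side_u = split_side(u)
        base_v, _ = split_side(v)
        merged = base_u if base_u == base_v else f"{u}-{v}"
        keep = [b for b in net.bones if b not in (u, v)]
        bones = tuple(keep) + (merged,)
        edges = set()
        for a, b in net.edges():
            a2 = merged if a in (u, v) else a
            b2 = merged if b in (u, v) else b
            if a2 != b2:
                edges.add(tuple(sorted((a2, b2))))
        return SkullNetwork.from_edges(net.taxon_name, bones, edges)
    raise ValueError(f"unknown perturbation {op!r}")


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children", "birth", "length")

    def __init__(self, birth: float):
        self.label: str | None = None
        self.children: list["_Node"] = []
        self.birth = birth
        self.length = 0.0


def generate_tree(
    n_tips: int,
    model: str = "yule",
    seed: int = 0,
    height: float | None = 1.0,
) -> PhyloTree:
    """Simulate a pure-birth (Yule) bifurcating tree.

    Lineages split at unit rate; simulation stops when ``n_tips`` lineages
    exist (plus one final exponential stretch so the last branches have
    positive length).  By default the tree is rescaled to unit
    root-to-tip height so calibrations are comparable across seeds; pass
    ``height=None`` to keep raw coalescent-time units.  Deterministic
    given ``seed``; tips are labeled ``t1..tN``.
    """
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = _Node(0.0)
    active: list[_Node] = []
    for _ in range(2):
        child = _Node(0.0)
        root.children.append(child)
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(int(rng.integers(len(active))))
        parent.length = t - parent.birth
        for _ in range(2):
            child = _Node(t)
            parent.children.append(child)
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for i, leaf in enumerate(active):
        leaf.length = t - leaf.birth
    # deterministic tip labeling by a preorder walk
    counter = itertools.count(1)

    def _label(node: _Node) -> None:
        if not node.children:
            node.label = f"t{next(counter)}"
        for ch in node.children:
            _label(ch)

    _label(root)
    scale = (height / t) if height is not None else 1.0

    def _newick(node: _Node) -> str:
        if not node.children:
            return f"{node.label}:{node.length * scale:.10g}"
        inner = ",".join(_newick(ch) for ch in node.children)
        return f"({inner}):{node.length * scale:.10g}"

    newick = f"({','.join(_newick(ch) for ch in root.children)});"
    return PhyloTree.from_newick(newick)


def simulate_bm_trait(
    tree: PhyloTree,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
) -> "pd.Series":
    """Brownian-motion trait simulation along the tree.

    Each branch adds an independent normal increment with variance
    ``sigma2 * branch_length``; returns tip values as a pandas Series
    indexed by tip label.  Deterministic given ``seed``.
    """
    import pandas as pd

    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    tree.require_branch_lengths(positive=False)
    rng = np.random.default_rng(seed)
    dt = tree.dendropy_tree
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in dt.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[id(node)] = root_value
            continue
        bl = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(sigma2 * bl)) if bl > 0 else 0.0
        values[id(node)] = values[id(parent)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="trait").loc[list(tree.tip_labels)]
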