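import itertools

import numpy as np
import pytest

from anna import PhyloTree, SkullNetwork


def make_net(name, bones, edges):
    return SkullNetwork.from_edges(name, bones, edges)


@pytest.fixture
def path3():
    return make_net("path3", ["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def triangle():
    return make_net("triangle", ["a", "b", "c"],
                    [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def k4():
    bones = ["a", "b", "c", "d"]
    return make_net("k4", bones, list(itertools.combinations(bones, 2)))


@pytest.fixture
def c4():
    return make_net("c4", ["a", "b", "c", "d"],
                    [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def star4():
    return make_net("star4", ["hub", "x", "y", "z"],
                    [("hub", "x"), ("hub", "y"), ("hub", "z")])


@pytest.fixture
def barbell():
    # two triangles joined by one edge: 6 nodes, 7 edges
    return make_net(
        "barbell", list("abcdef"),
        [("a", "b"), ("a", "c"), ("b", "c"),
         ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")],
    )


@pytest.fixture
def two_cliques():
    bones = [f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)]
    edges = (list(itertools.combinations(bones[:4], 2))
             + list(itertools.combinations(bones[4:], 2))
             + [("x0", "y0")])
    return make_net("two_cliques", bones, edges)


def random_connected_net(n, p, seed):
    """Erdos-Renyi graph patched to connectivity; used as a generic fixture."""
    rng = np.random.default_rng(seed)
    labels = [f"v{i}" for i in range(n)]
    edges = {
        (labels[i], labels[j])
        for i in range(n) for j in range(i + 1, n)
        if rng.random() < p
    }
    # chain-patch for connectivity
    order = rng.permutation(n)
    reached = {labels[order[0]]}
    adj = {l: set() for l in labels}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    for idx in order[1:]:
        lbl = labels[idx]
        stack, comp = [lbl], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        if not comp & reached:
            anchor = sorted(reached)[int(rng.integers(len(reached)))]
            edges.add(tuple(sorted((lbl, anchor))))
            adj[lbl].add(anchor)
            adj[anchor].add(lbl)
        reached |= comp
    return make_net(f"rand{n}_{seed}", labels, edges)


@pytest.fixture
def balanced4_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
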