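"""Phylogenetic comparative statistics.

Two phylogenetic-signal tests and the contrasts machinery used to test
whether modularity and complexity co-evolve:

- **Abouheif's Cmean** — a Moran's-I-type autocorrelation of a tip trait
  under the topology-only Abouheif proximity matrix, with a permutation
  test (trait values shuffled across tips).
- **Blomberg's K** — the observed ratio of among-tip to
  phylogenetically-corrected trait variance, scaled by its Brownian-motion
  expectation; K near 1 indicates Brownian-like signal.  Permutation test
  as above.
- **Felsenstein's phylogenetic independent contrasts (PIC)** and the
  Pearson correlation of two contrast vectors, computed through the origin
  (contrast signs are arbitrary, so the regression has no intercept) with
  significance from the t distribution on ``n_contrasts - 1`` degrees of
  freedom.

Permutation p-values use the add-one convention ``(b + 1) / (m + 1)``.
Abouheif's test is one-sided for positive autocorrelation by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network_io import PhyloTree, ValidationError

__all__ = [
    "SignalTestResult",
    "CorrelationResult",
    "DegenerateTraitError",
    "abouheif_weights",
    "abouheif_cmean_stat",
    "abouheif_cmean",
    "blomberg_k_stat",
    "blomberg_k",
    "independent_contrasts",
    "pic_correlation",
]

ALTERNATIVES = ("greater", "less", "two-sided")


class DegenerateTraitError(ValueError):
    """The trait is constant across tips; the test statistic is undefined."""


@dataclass(frozen=True)
class SignalTestResult:
    parameter: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str
    alternative: str = "greater"


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    r: float
    p_value: float
    n_contrasts: int
    method: str


def _align_trait(tree: PhyloTree, trait: Mapping[str, float] | pd.Series) -> np.ndarray:
    """Trait values in tree leaf order; error lists any taxon mismatch."""
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    tips = set(tree.tip_labels)
    taxa = set(trait)
    if tips != taxa:
        missing = sorted(tips - taxa)
        extra = sorted(taxa - tips)
        raise ValidationError(
            f"trait/tree taxon mismatch: missing from trait {missing}, "
            f"not in tree {extra}"
        )
    return np.array([float(trait[t]) for t in tree.tip_labels])


def _perm_pvalue(obs: float, perm: np.ndarray, alternative: str) -> float:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    eps = 1e-12
    if alternative == "greater":
        b = int(np.sum(perm >= obs - eps))
    elif alternative == "less":
        b = int(np.sum(perm <= obs + eps))
    else:
        b = int(np.sum(np.abs(perm) >= abs(obs) - eps))
    return (b + 1) / (len(perm) + 1)


# ---------------------------------------------------------------------------
# Abouheif's Cmean
# ---------------------------------------------------------------------------


def abouheif_weights(tree: PhyloTree) -> tuple[tuple[str, ...], np.ndarray]:
    """Row-normalized Abouheif proximity matrix.

    The raw proximity of tips i and j is one over the product of the
    numbers of direct descendants of every interior node on the path
    between them (both tips excluded, their MRCA included); the diagonal
    is zero.  Uses topology only — branch lengths play no role.
    """
    dt = tree.dendropy_tree
    leaves = list(dt.leaf_node_iter())
    n = len(leaves)
    if n < 3:
        raise ValidationError("Abouheif's test requires at least 3 tips")
    anc: list[list] = []
    for leaf in leaves:
        chain = []
        node = leaf.parent_node
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc.append(chain)
    dd = {id(node): len(node.child_nodes()) for node in dt.preorder_node_iter()}
    a = np.zeros((n, n))
    for i in range(n):
        anc_ids = {id(node): pos for pos, node in enumerate(anc[i])}
        for j in range(i + 1, n):
            # walk j's ancestors until the MRCA
            path_nodes = []
            for node in anc[j]:
                if id(node) in anc_ids:
                    mrca_pos = anc_ids[id(node)]
                    path_nodes.extend(anc[i][:mrca_pos])
                    path_nodes.append(node)
                    break
                path_nodes.append(node)
            prod = 1.0
            for node in path_nodes:
                prod *= dd[id(node)]
            a[i, j] = a[j, i] = 1.0 / prod
    w = a / a.sum(axis=1, keepdims=True)
    labels = tuple(leaf.taxon.label for leaf in leaves)
    return labels, w


def abouheif_cmean_stat(tree: PhyloTree, trait: Mapping[str, float] | pd.Series) -> float:
    """Abouheif's Cmean for one trait (no test)."""
    x = _align_trait(tree, trait)
    _, w = abouheif_weights(tree)
    xc = x - x.mean()
    ss = float(xc @ xc)
    if ss == 0:
        raise DegenerateTraitError("trait is constant across tips")
    return float(xc @ w @ xc / ss)


def abouheif_cmean(
    tree: PhyloTree,
    trait: Mapping[str, float] | pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    parameter: str = "",
) -> SignalTestResult:
    """Permutation test of phylogenetic signal via Abouheif's Cmean.

    Trait values are shuffled across tips ``n_perm`` times with the given
    seed; the p-value is ``(b + 1) / (n_perm + 1)`` where ``b`` counts
    permuted statistics at least as extreme as the observed one
    (one-sided greater by default).
    """
    x = _align_trait(tree, trait)
    _, w = abouheif_weights(tree)
    xc = x - x.mean()
    ss = float(xc @ xc)
    if ss == 0:
        raise DegenerateTraitError("trait is constant across tips")
    obs = float(xc @ w @ xc / ss)
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, x.size)), axis=1)
    perms = xc[idx]  # (n_perm, n)
    stats_perm = np.einsum("ij,jk,ik->i", perms, w, perms) / ss
    p = _perm_pvalue(obs, stats_perm, alternative)
    name = parameter or getattr(trait, "name", "") or "trait"
    return SignalTestResult(name, obs, p, n_perm, seed, "abouheif", alternative)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


def _blomberg_parts(tree: PhyloTree) -> tuple[tuple[str, ...], np.ndarray, float]:
    tree.require_branch_lengths(positive=True)
    labels, c = tree.vcv()
    n = len(labels)
    c_inv = np.linalg.inv(c)
    one = np.ones(n)
    denom_1c1 = float(one @ c_inv @ one)
    expected = (np.trace(c) - n / denom_1c1) / (n - 1)
    return labels, c_inv, expected


def _k_statistic(x: np.ndarray, c_inv: np.ndarray, expected: float) -> float:
    n = x.size
    one = np.ones(n)
    ahat = float(one @ c_inv @ x) / float(one @ c_inv @ one)
    d = x - ahat
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ c_inv @ d) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k_stat(tree: PhyloTree, trait: Mapping[str, float] | pd.Series) -> float:
    """Blomberg's K for one trait (no test)."""
    x = _align_trait(tree, trait)
    if np.var(x) == 0:
        raise DegenerateTraitError("trait is constant across tips")
    labels, c_inv, expected = _blomberg_parts(tree)
    order = [tree.tip_labels.index(lbl) for lbl in labels]
    return float(_k_statistic(x[order], c_inv, expected))


def blomberg_k(
    tree: PhyloTree,
    trait: Mapping[str, float] | pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    parameter: str = "",
) -> SignalTestResult:
    """Permutation test of phylogenetic signal via Blomberg's K.

    K is the observed ratio of the among-tip mean squared deviation from
    the phylogenetic (GLS) mean to the phylogenetically corrected one,
    divided by its expectation under Brownian motion on the same tree.
    """
    x = _align_trait(tree, trait)
    if np.var(x) == 0:
        raise DegenerateTraitError("trait is constant across tips")
    labels, c_inv, expected = _blomberg_parts(tree)
    order = [tree.tip_labels.index(lbl) for lbl in labels]
    xo = x[order]
    obs = _k_statistic(xo, c_inv, expected)
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, xo.size)), axis=1)
    perms = xo[idx]
    one = np.ones(xo.size)
    s1 = c_inv @ one
    ahats = perms @ s1 / float(one @ s1)
    d = perms - ahats[:, None]
    mse0 = (d * d).sum(axis=1)
    mse = np.einsum("ij,jk,ik->i", d, c_inv, d)
    k_perm = (mse0 / mse) / expected
    p = _perm_pvalue(obs, k_perm, alternative)
    name = parameter or getattr(trait, "name", "") or "trait"
    return SignalTestResult(name, float(obs), p, n_perm, seed, "blomberg", alternative)


# ---------------------------------------------------------------------------
# Phylogenetic independent contrasts
# ---------------------------------------------------------------------------


def independent_contrasts(
    tree: PhyloTree, trait: Mapping[str, float] | pd.Series
) -> np.ndarray:
    """Felsenstein's standardized contrasts (one per internal node).

    Recursive pruning: at each internal node with children carrying
    (value, branch length) pairs ``(x1, v1), (x2, v2)``, the contrast is
    ``(x1 - x2) / sqrt(v1 + v2)``; the node's value is the
    variance-weighted mean of the children and its effective branch length
    is extended by ``v1 v2 / (v1 + v2)``.  Requires a fully bifurcating
    tree with positive branch lengths; polytomies are rejected.
    """
    if not tree.is_bifurcating():
        raise ValidationError(
            "tree contains polytomies; resolve them before computing contrasts"
        )
    tree.require_branch_lengths(positive=True)
    x = _align_trait(tree, trait)
    values = dict(zip(tree.tip_labels, x))
    dt = tree.dendropy_tree
    node_state: dict[int, tuple[float, float]] = {}
    contrasts: list[float] = []
    for node in dt.postorder_node_iter():
        bl = node.edge.length if node.parent_node is not None else 0.0
        if node.is_leaf():
            node_state[id(node)] = (values[node.taxon.label], float(bl))
            continue
        (x1, v1), (x2, v2) = (node_state[id(ch)] for ch in node.child_nodes())
        contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
        xk = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        vk = float(bl) + v1 * v2 / (v1 + v2)
        node_state[id(node)] = (xk, vk)
    return np.array(contrasts)


def pic_correlation(
    tree: PhyloTree,
    traits: pd.DataFrame,
    x: str,
    y: str,
    through_origin: bool = True,
    alternative: str = "two-sided",
) -> CorrelationResult:
    """Pearson correlation of the PICs of two trait columns.

    Contrast signs are arbitrary, so the default correlation is computed
    through the origin, ``r = sum(uw) / sqrt(sum(u^2) sum(w^2))``, with a
    t test on ``n_contrasts - 1`` degrees of freedom.  A with-intercept
    variant is selectable for sensitivity analysis.
    """
    for col in (x, y):
        if col not in traits.columns:
            raise KeyError(f"trait column {col!r} not in table")
    u = independent_contrasts(tree, traits[x])
    w = independent_contrasts(tree, traits[y])
    if u.size < 3:
        raise ValidationError("fewer than 3 contrasts; cannot test correlation")
    if through_origin:
        denom = np.sqrt(float(u @ u) * float(w @ w))
        if denom == 0:
            raise DegenerateTraitError("all contrasts are zero for one trait")
        r = float(u @ w / denom)
        df = u.size - 1
        method = "pic-pearson-through-origin"
    else:
        r = float(np.corrcoef(u, w)[0, 1])
        df = u.size - 2
        method = "pic-pearson-with-intercept"
    if abs(r) >= 1.0:
        t_stat = np.inf * np.sign(r)
    else:
        t_stat = r * np.sqrt(df / (1.0 - r * r))
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    elif alternative == "greater":
        p = float(stats.t.sf(t_stat, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t_stat, df))
    else:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    return CorrelationResult(x, y, r, p, int(u.size), method)
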