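"""Per-network morphological complexity metrics.

Five parameters summarize the complexity of a bone-contact network:

- ``N`` — number of bones (nodes),
- ``K`` — number of contacts (links),
- ``D`` — density of connections, ``D = 2K / (N(N-1))``,
- ``C`` — average clustering coefficient (mean over all nodes of the
  Watts–Strogatz local coefficient ``c_i = 2*tri_i / (k_i (k_i - 1))``,
  with ``c_i = 0`` for nodes of degree < 2),
- ``H`` — heterogeneity (anisomerism) of connections, by default the
  ratio of the population variance to the mean of the degree sequence.

N and K measure complexity as number of parts; D and C as richness of
interaction; H as disparity among parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_io import SkullNetwork

__all__ = [
    "ComplexityProfile",
    "density",
    "clustering",
    "heterogeneity",
    "complexity_profile",
    "UndefinedMetricError",
]

VARIANCE_KINDS = ("population", "sample")
DISPERSIONS = ("variance_over_mean", "sd_over_mean")


class UndefinedMetricError(ValueError):
    """The metric is undefined for this network size."""


@dataclass(frozen=True)
class ComplexityProfile:
    """The five complexity parameters of one network."""

    N: int
    K: int
    D: float
    C: float
    H: float

    def as_dict(self) -> dict[str, float]:
        return {"N": self.N, "K": self.K, "D": self.D, "C": self.C, "H": self.H}


def density(net: SkullNetwork) -> float:
    """Fraction of realized contacts: ``2K / (N(N-1))``."""
    n = net.n_bones
    if n < 2:
        raise UndefinedMetricError("density requires at least 2 bones")
    return 2.0 * net.n_contacts / (n * (n - 1))


def clustering(net: SkullNetwork) -> float:
    """Average local clustering coefficient over all nodes.

    Nodes of degree < 2 contribute 0, keeping N as the denominator.
    """
    if net.n_bones < 1:
        raise UndefinedMetricError("clustering requires at least 1 bone")
    return float(nx.average_clustering(net.to_networkx(), count_zeros=True))


def heterogeneity(
    net: SkullNetwork,
    variance_kind: str = "population",
    dispersion: str = "variance_over_mean",
) -> float:
    """Degree heterogeneity: dispersion of the degree sequence over its mean.

    The default is population variance / mean.  ``sd_over_mean`` (the
    coefficient of variation, used by part of the anatomical-network
    literature) and sample variance are selectable; the pipeline records
    which convention was used.
    """
    if variance_kind not in VARIANCE_KINDS:
        raise ValueError(f"variance_kind must be one of {VARIANCE_KINDS}")
    if dispersion not in DISPERSIONS:
        raise ValueError(f"dispersion must be one of {DISPERSIONS}")
    if net.n_bones < 2:
        raise UndefinedMetricError("heterogeneity requires at least 2 bones")
    k = net.degrees().astype(float)
    ddof = 0 if variance_kind == "population" else 1
    var = float(np.var(k, ddof=ddof))
    spread = np.sqrt(var) if dispersion == "sd_over_mean" else var
    return spread / float(np.mean(k))


def complexity_profile(
    net: SkullNetwork,
    variance_kind: str = "population",
    dispersion: str = "variance_over_mean",
) -> ComplexityProfile:
    """Bundle N, K, D, C, H for one network (deterministic)."""
    return ComplexityProfile(
        N=net.n_bones,
        K=net.n_contacts,
        D=density(net),
        C=clustering(net),
        H=heterogeneity(net, variance_kind=variance_kind, dispersion=dispersion),
    )
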