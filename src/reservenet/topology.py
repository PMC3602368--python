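"""Classical network-topology metrics for dispersal graphs.

Covers the standard descriptive suite for a reserve network: node degree,
connected components and their orders, isolated nodes, articulation (cut)
points, shortest-path betweenness centrality, local clustering
coefficients, and a Poisson goodness-of-fit check on the degree
distribution (a Poisson degree law is the signature of a random — as
opposed to scale-free — network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import DispersalGraph

__all__ = [
    "ComponentSummary",
    "components",
    "betweenness",
    "clustering",
    "node_metrics",
    "degree_histogram",
    "PoissonFit",
    "poisson_fit",
]

#: components below this order count as "small" in comparisons
SMALL_COMPONENT_ORDER = 10


@dataclass(frozen=True)
class ComponentSummary:
    """Connected components of a dispersal graph and derived counts."""

    components: tuple[frozenset[str], ...]
    articulation_points: frozenset[str]

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.components)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_isolated(self) -> int:
        return sum(1 for c in self.components if len(c) == 1)

    @property
    def largest_order(self) -> int:
        return max(self.orders, default=0)

    @property
    def smallest_order(self) -> int:
        return min(self.orders, default=0)

    @property
    def mean_order(self) -> float:
        return float(np.mean(self.orders)) if self.components else 0.0

    @property
    def sd_order(self) -> float:
        # ddof=1 to match how network tables usually report ± sd
        if self.n_components < 2:
            return 0.0
        return float(np.std(self.orders, ddof=1))

    def component_of(self) -> dict[str, int]:
        """Map node id -> component index (components sorted largest first)."""
        return {nid: i for i, comp in enumerate(self.components) for nid in comp}

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "n_isolated": self.n_isolated,
            "largest_order": self.largest_order,
            "smallest_order": self.smallest_order,
            "mean_order": self.mean_order,
            "sd_order": self.sd_order,
            "orders": list(self.orders),
            "n_articulation_points": len(self.articulation_points),
            "articulation_points": sorted(self.articulation_points),
        }


def components(graph: DispersalGraph) -> ComponentSummary:
    """Connected components, ordered largest-first, plus articulation points.

    An articulation point is a node whose removal increases the number of
    components; an isolated node is an order-1 component.
    """
    g = graph.graph
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )
    return ComponentSummary(
        components=tuple(comps),
        articulation_points=frozenset(nx.articulation_points(g)),
    )


def betweenness(graph: DispersalGraph) -> dict[str, float]:
    """Unweighted shortest-path betweenness centrality per node.

    Normalized globally by (n−1)(n−2)/2 with n the total node count of the
    graph — not per component — so values from multi-component networks
    average into a single network-level figure.  Pairs in different
    components contribute nothing; tied shortest paths split their
    contribution equally.
    """
    g = graph.graph
    n = g.number_of_nodes()
    if n < 3:
        return {nid: 0.0 for nid in g.nodes}
    return {nid: float(v) for nid, v in nx.betweenness_centrality(g, normalized=True).items()}


def clustering(graph: DispersalGraph) -> tuple[dict[str, float], float]:
    """Local clustering coefficient per node, plus the network mean.

    Degree-<2 nodes get coefficient 0 and are included in the mean, so a
    single mean stays defined on fragmented graphs dominated by isolated
    sites.
    """
    g = graph.graph
    cc = {nid: float(v) for nid, v in nx.clustering(g).items()}
    mean = float(np.mean(list(cc.values()))) if cc else 0.0
    return cc, mean


def node_metrics(graph: DispersalGraph) -> pd.DataFrame:
    """Per-node metric table: degree, betweenness, clustering, component id."""
    summary = components(graph)
    comp_of = summary.component_of()
    bc = betweenness(graph)
    cc, _ = clustering(graph)
    ids = sorted(graph.node_ids)
    return pd.DataFrame(
        {
            "site_id": ids,
            "degree": [graph.graph.degree[i] for i in ids],
            "betweenness": [bc[i] for i in ids],
            "clustering": [cc[i] for i in ids],
            "component_id": [comp_of[i] for i in ids],
        }
    )


def degree_histogram(graph: DispersalGraph) -> dict[int, int]:
    degrees = [d for _, d in graph.graph.degree]
    if not degrees:
        return {}
    vals, counts = np.unique(degrees, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass(frozen=True)
class PoissonFit:
    """Chi-square goodness of fit of degrees to a Poisson law."""

    lambda_hat: float
    gof_statistic: float
    p_value: float
    dof: int
    n_bins: int
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "accepted", bool(self.p_value > 0.05))


MIN_FIT_N = 20
MIN_EXPECTED = 5.0


def poisson_fit(degrees: np.ndarray | list[int]) -> PoissonFit:
    """Fit Poisson(λ̂ = mean degree) and test by chi-square on pooled bins.

    Degree counts are binned on 0..max; adjacent bins are pooled until every
    expected Poisson frequency is ≥ 5 (the upper tail mass is folded into
    the last bin).  Degrees of freedom = bins − 2 (one for the total, one
    for the estimated λ).

    Raises
    ------
    ValueError
        Fewer than 20 degrees (fit refused), or fewer than 3 pooled bins
        (fit undefined, e.g. all degrees identical).
    """
    degrees = np.asarray(degrees, dtype=int)
    n = degrees.size
    if n < MIN_FIT_N:
        raise ValueError(f"need at least {MIN_FIT_N} degrees for a Poisson fit, got {n}")
    lam = float(degrees.mean())

    kmax = int(degrees.max())
    observed = np.bincount(degrees, minlength=kmax + 1).astype(float)
    expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * n
    expected[kmax] += stats.poisson.sf(kmax, lam) * n  # fold the upper tail

    obs_bins: list[float] = []
    exp_bins: list[float] = []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= MIN_EXPECTED:
            obs_bins.append(o_acc)
            exp_bins.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0:
        if exp_bins:
            obs_bins[-1] += o_acc
            exp_bins[-1] += e_acc
        else:
            obs_bins, exp_bins = [o_acc], [e_acc]

    n_bins = len(exp_bins)
    dof = n_bins - 2
    if dof < 1:
        raise ValueError(
            f"degree distribution too concentrated for a chi-square fit ({n_bins} pooled bins)"
        )
    obs_arr = np.array(obs_bins)
    exp_arr = np.array(exp_bins)
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    p = float(stats.chi2.sf(chi2, dof))
    return PoissonFit(lambda_hat=lam, gof_statistic=chi2, p_value=p, dof=dof, n_bins=n_bins)
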