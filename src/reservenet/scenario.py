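"""Current-vs-future scenario comparison for a reserve network.

Applies the future-suitability scenario (pure range contraction: a site
can be lost but never gained), rebuilds the dispersal graph, recomputes
the topology and habitat-connectivity suites on both epochs, books which
components were wholly lost or split, and runs the lost-vs-retained
statistical comparisons.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityIndices,
    ProbabilityKernel,
    connectivity_indices,
    d_metrics,
)
from .core import (
    DispersalGraph,
    DistanceMatrix,
    DistanceMode,
    Epoch,
    Site,
    build_graph,
    pairwise_distances,
    suitable_in,
)
from .stats import PermutationResult, mann_whitney_u, permutation_test, spearman
from .topology import ComponentSummary, components, node_metrics

__all__ = ["ScenarioComparison", "compare_scenarios", "component_change", "round_pct"]


def round_pct(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for reported percentages (14.745 -> 14.75)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ScenarioComparison:
    """Everything the current-vs-future comparison produces."""

    species_name: str
    dispersal_km: float
    n_current: int
    n_future: int
    lost_ids: frozenset[str]
    retained_ids: frozenset[str]
    current_graph: DispersalGraph = field(repr=False)
    future_graph: DispersalGraph = field(repr=False)
    current_summary: ComponentSummary = field(repr=False)
    future_summary: ComponentSummary = field(repr=False)
    current_metrics: pd.DataFrame = field(repr=False)
    future_metrics: pd.DataFrame = field(repr=False)
    current_indices: ConnectivityIndices = field(repr=False)
    future_indices: ConnectivityIndices = field(repr=False)
    components_lost: int
    split_events: int
    lost_by_component: dict[int, int] = field(repr=False)
    change: dict = field(repr=False)
    tests: dict = field(repr=False)

    @property
    def n_lost(self) -> int:
        return self.n_current - self.n_future

    @property
    def pct_lost(self) -> float:
        if self.n_current == 0:
            return 0.0
        return 100.0 * self.n_lost / self.n_current

    def to_dict(self) -> dict:
        """JSON-ready report with stable keys."""
        return {
            "species_name": self.species_name,
            "dispersal_km": self.dispersal_km,
            "nodes": {
                "current": self.n_current,
                "future": self.n_future,
                "losses": self.n_lost,
                "pct_lost": round_pct(self.pct_lost),
            },
            "components": {
                "current": self.current_summary.to_dict(),
                "future": self.future_summary.to_dict(),
                "components_lost": self.components_lost,
                "split_events": self.split_events,
                "lost_by_component": {str(k): v for k, v in sorted(self.lost_by_component.items())},
            },
            "indices": {
                "current": self.current_indices.to_dict(),
                "future": self.future_indices.to_dict(),
                "dA_pct": round_pct(self.change["dA_pct"]),
                "dECA_pct": round_pct(self.change["dECA_pct"]),
                "weaker_impact": self.change["weaker_impact"],
            },
            "tests": self.tests,
        }


def component_change(
    current_summary: ComponentSummary,
    future_summary: ComponentSummary,
    lost_ids: frozenset[str] | set[str],
) -> dict:
    """Count components wholly lost and components split by node loss.

    A current component is lost when none of its nodes persist; it is split
    when its surviving nodes fall into more than one future component.
    """
    future_comp_of = future_summary.component_of()
    components_lost = 0
    split_events = 0
    lost_by_component: dict[int, int] = {}
    for ci, comp in enumerate(current_summary.components):
        n_lost_here = sum(1 for nid in comp if nid in lost_ids)
        if n_lost_here:
            lost_by_component[ci] = n_lost_here
        survivors = comp - set(lost_ids)
        if not survivors:
            components_lost += 1
            continue
        future_ids = {future_comp_of[nid] for nid in survivors}
        if len(future_ids) > 1:
            split_events += 1
    return {
        "components_lost": components_lost,
        "split_events": split_events,
        "lost_by_component": lost_by_component,
    }


def _lost_retained_tests(
    comparison_metrics: pd.DataFrame,
    gbc_current: dict[str, float],
    lost_ids: frozenset[str],
    current_summary: ComponentSummary,
    n_perm: int,
    seed: int,
) -> dict:
    """Lost-vs-retained comparisons on the current network's node values.

    Permutation tests for degree, betweenness and GBC; Mann–Whitney for the
    clustering coefficient and for the orders of components that lost nodes
    versus those left intact; Spearman for losses-per-component vs order.
    """
    df = comparison_metrics.set_index("site_id")
    lost_mask = df.index.isin(lost_ids)
    tests: dict = {}
    if lost_mask.any() and (~lost_mask).any():
        rng = np.random.default_rng(seed)
        series = {
            "degree": df["degree"].to_numpy(dtype=float),
            "betweenness": df["betweenness"].to_numpy(dtype=float),
        }
        if gbc_current:
            series["gbc"] = df.index.map(gbc_current).to_numpy(dtype=float)
        for name, values in series.items():
            res: PermutationResult = permutation_test(
                values[lost_mask],
                values[~lost_mask],
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            tests[name] = res.to_dict()
        cl = df["clustering"].to_numpy(dtype=float)
        tests["clustering_mwu"] = mann_whitney_u(cl[lost_mask], cl[~lost_mask])

    # component-level: which components lost nodes, and how many
    orders = np.array(current_summary.orders, dtype=float)
    losses_per_comp = np.zeros(len(orders))
    comp_of = current_summary.component_of()
    for nid in lost_ids:
        losses_per_comp[comp_of[nid]] += 1
    affected = losses_per_comp > 0
    if affected.any() and (~affected).any():
        tests["component_order_mwu"] = mann_whitney_u(orders[affected], orders[~affected])
    if len(orders) >= 3 and np.ptp(orders) > 0 and np.ptp(losses_per_comp) > 0:
        tests["losses_vs_order_spearman"] = spearman(losses_per_comp, orders)
    return tests


def compare_scenarios(
    sites: list[Site],
    dispersal_km: float,
    kernel: ProbabilityKernel | None = None,
    species_name: str = "species",
    topology_distances: DistanceMatrix | None = None,
    habitat_distances: DistanceMatrix | None = None,
    n_perm: int = 999,
    seed: int = 0,
    with_stats: bool = True,
    with_gbc: bool = True,
) -> ScenarioComparison:
    """Full current-vs-future comparison for one species.

    The topology graph uses centroid distances at the dispersal threshold;
    the habitat indices use edge-approximated distances and the
    negative-exponential kernel (half distance = dispersal distance unless
    a kernel is given).  Either distance matrix can be overridden.
    """
    current_sites = suitable_in(sites, Epoch.CURRENT)
    if not current_sites:
        raise ValueError("no currently suitable sites")
    # pure contraction: ignore future-only suitability
    future_sites = [s for s in current_sites if s.suitable_future]
    kernel = kernel or ProbabilityKernel(half_distance_km=dispersal_km)

    if topology_distances is None:
        topology_distances = pairwise_distances(current_sites, DistanceMode.CENTROID)
    g_cur = build_graph(current_sites, topology_distances, dispersal_km, Epoch.CURRENT)
    g_fut = build_graph(current_sites, topology_distances, dispersal_km, Epoch.FUTURE)

    sum_cur = components(g_cur)
    sum_fut = components(g_fut)
    met_cur = node_metrics(g_cur)
    met_fut = node_metrics(g_fut)

    idx_cur = connectivity_indices(
        current_sites, kernel, distances=habitat_distances, with_gbc=with_gbc
    )
    idx_fut = connectivity_indices(
        future_sites, kernel, distances=habitat_distances, with_gbc=with_gbc
    )
    change = d_metrics(idx_cur, idx_fut)

    lost_ids = frozenset(s.site_id for s in current_sites if not s.suitable_future)
    retained_ids = frozenset(s.site_id for s in future_sites)
    comp_change = component_change(sum_cur, sum_fut, lost_ids)

    tests: dict = {}
    if with_stats:
        tests = _lost_retained_tests(met_cur, idx_cur.gbc_ha2, lost_ids, sum_cur, n_perm, seed)

    return ScenarioComparison(
        species_name=species_name,
        dispersal_km=float(dispersal_km),
        n_current=len(current_sites),
        n_future=len(future_sites),
        lost_ids=lost_ids,
        retained_ids=retained_ids,
        current_graph=g_cur,
        future_graph=g_fut,
        current_summary=sum_cur,
        future_summary=sum_fut,
        current_metrics=met_cur,
        future_metrics=met_fut,
        current_indices=idx_cur,
        future_indices=idx_fut,
        components_lost=comp_change["components_lost"],
        split_events=comp_change["split_events"],
        lost_by_component=comp_change["lost_by_component"],
        change=change,
        tests=tests,
    )
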