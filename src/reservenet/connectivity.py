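"""Habitat-weighted connectivity indices: max-product paths, ECA and GBC.

The probability-of-connectivity family treats every pair of habitat
patches as exchanging dispersers with probability ``p*_ij`` — the best
achievable product of per-step dispersal probabilities over any chain of
intermediate patches — and weights that probability by the patch areas:

    PC_num = Σ_i Σ_j a_i · a_j · p*_ij        (ha², includes i = j, p*_ii = 1)
    ECA    = sqrt(PC_num)                     (ha)

ECA is the area of the single patch that would give the same connectivity
value: it equals the total habitat area when everything is perfectly
connected, and sqrt(Σ a_i²) when all patches are mutually unreachable.

Generalized Betweenness Centrality (GBC) re-weights classical betweenness
ecologically: node k accumulates ``a_i·a_j·p*_ij`` over every patch pair
whose optimal (maximum-product) path passes through k.

Per-step probabilities come from a negative-exponential dispersal kernel;
paths are optimal over the complete pairwise graph — any patch may serve
as a stepping stone, irrespective of the topological threshold graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .core import DistanceMatrix, DistanceMode, Site, pairwise_distances

__all__ = [
    "ProbabilityKernel",
    "ConnectivityIndices",
    "max_product_paths",
    "eca",
    "gbc",
    "connectivity_indices",
    "d_metrics",
]

# relative tolerance for deciding that two path lengths tie
_TIE_RTOL = 1e-9
_TIE_ATOL = 1e-9


@dataclass(frozen=True)
class ProbabilityKernel:
    """Negative-exponential dispersal kernel anchored at its half distance.

    ``p(d) = exp(−k·d)`` with ``k = ln 2 / half_distance_km``, so the
    probability of a direct step is 1 at distance 0 and exactly 0.5 at the
    half distance.  Anchoring the kernel at the species' *median* dispersal
    distance makes p(median) = 0.5 by construction.
    """

    half_distance_km: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.half_distance_km) and self.half_distance_km > 0):
            raise ValueError("half_distance_km must be positive and finite")

    @property
    def decay_per_km(self) -> float:
        return math.log(2.0) / self.half_distance_km

    def probability(self, distance_km: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-self.decay_per_km * np.asarray(distance_km, dtype=float))


@dataclass(frozen=True)
class ConnectivityIndices:
    """Network-level habitat connectivity indices plus per-node GBC."""

    pc_numerator_ha2: float
    eca_ha: float
    total_area_ha: float
    gbc_ha2: dict[str, float] = field(repr=False)
    kernel: ProbabilityKernel | None = None

    def to_dict(self) -> dict:
        return {
            "pc_numerator_ha2": self.pc_numerator_ha2,
            "eca_ha": self.eca_ha,
            "total_area_ha": self.total_area_ha,
        }


def max_product_paths(distances: DistanceMatrix, kernel: ProbabilityKernel) -> np.ndarray:
    """Maximum product-of-step-probabilities between every pair of sites.

    Every site pair is a candidate step (complete weighted graph).  The
    maximum product path is the minimum-weight path under weights
    ``−log p = k·d``; since the weight is proportional to distance, this is
    a metric shortest-path problem solved exactly with Dijkstra.  Returns
    the symmetric matrix ``p*`` with unit diagonal, in the order of
    ``distances.ids``.
    """
    d_opt = _optimal_path_lengths(distances.d)
    p_star = np.exp(-kernel.decay_per_km * d_opt)
    np.fill_diagonal(p_star, 1.0)
    return p_star


def _optimal_path_lengths(d: np.ndarray) -> np.ndarray:
    """All-pairs minimum path length treating every pair as an edge.

    −log p is proportional to distance for the negative-exponential kernel,
    so one distance-space shortest path serves every kernel.
    """
    if d.shape[0] == 1:
        return np.zeros((1, 1))
    return shortest_path(d, method="D", directed=False)


def _areas_in_matrix_order(sites: Sequence[Site], ids: Sequence[str]) -> np.ndarray:
    by_id = {s.site_id: s for s in sites}
    missing = [sid for sid in ids if sid not in by_id]
    if missing:
        raise KeyError(f"sites missing for matrix ids: {missing}")
    return np.array([by_id[sid].area_ha for sid in ids], dtype=float)


def eca(
    sites: Sequence[Site],
    p_star: np.ndarray,
    ids: Sequence[str],
    kernel: ProbabilityKernel | None = None,
    gbc_ha2: Mapping[str, float] | None = None,
) -> ConnectivityIndices:
    """PC numerator and Equivalent Connected Area from a p* matrix.

    ``pc_numerator = Σ_i Σ_j a_i a_j p*_ij`` over all ordered pairs
    including i = j (p*_ii = 1), and ``ECA = sqrt(pc_numerator)``, so a
    single patch of area a has ECA = a exactly.
    """
    if len(ids) == 0:
        return ConnectivityIndices(0.0, 0.0, 0.0, dict(gbc_ha2 or {}), kernel)
    a = _areas_in_matrix_order(sites, ids)
    pc_num = float(a @ p_star @ a)
    return ConnectivityIndices(
        pc_numerator_ha2=pc_num,
        eca_ha=math.sqrt(pc_num),
        total_area_ha=float(a.sum()),
        gbc_ha2=dict(gbc_ha2 or {}),
        kernel=kernel,
    )


def gbc(
    sites: Sequence[Site],
    distances: DistanceMatrix,
    kernel: ProbabilityKernel,
) -> dict[str, float]:
    """Generalized Betweenness Centrality per site, in ha².

    ``GBC(k) = Σ_{i<j, i≠k≠j} a_i a_j p*_ij`` over pairs whose optimal
    maximum-product path passes through k.  Node k lies on an optimal i–j
    path iff ``L(i,k) + L(k,j) = L(i,j)`` for the optimal path lengths L;
    when several optimal paths tie, the pair contributes to every node on
    at least one of them.
    """
    ids = distances.ids
    a = _areas_in_matrix_order(sites, ids)
    d_opt = _optimal_path_lengths(distances.d)
    p_star = np.exp(-kernel.decay_per_km * d_opt)
    np.fill_diagonal(p_star, 1.0)

    n = len(ids)
    weight = np.outer(a, a) * p_star
    out: dict[str, float] = {}
    for k in range(n):
        through_k = np.isclose(
            d_opt[:, k][:, None] + d_opt[k, :][None, :],
            d_opt,
            rtol=_TIE_RTOL,
            atol=_TIE_ATOL,
        )
        through_k[k, :] = False
        through_k[:, k] = False
        np.fill_diagonal(through_k, False)
        # each unordered pair appears twice in the symmetric sum
        out[ids[k]] = float((weight * through_k).sum() / 2.0)
    return out


def connectivity_indices(
    sites: Sequence[Site],
    kernel: ProbabilityKernel,
    distances: DistanceMatrix | None = None,
    distance_mode: DistanceMode | str = DistanceMode.EDGE_APPROX,
    with_gbc: bool = True,
) -> ConnectivityIndices:
    """One-call ECA + GBC for a site list.

    Distances default to the edge-to-edge approximation (patches as
    equivalent-area discs); pass ``distances`` to override.
    """
    if len(sites) == 0:
        return ConnectivityIndices(0.0, 0.0, 0.0, {}, kernel)
    if distances is None:
        distances = pairwise_distances(sites, mode=distance_mode)
    else:
        distances = distances.subset([s.site_id for s in sites])
    p_star = max_product_paths(distances, kernel)
    g = gbc(sites, distances, kernel) if with_gbc else {}
    return eca(sites, p_star, distances.ids, kernel=kernel, gbc_ha2=g)


def d_metrics(current: ConnectivityIndices, future: ConnectivityIndices) -> dict:
    """Relative changes in habitat area (dA) and connectivity (dECA), %.

    ``dECA > dA`` flags a weaker-than-proportional connectivity impact:
    the network lost less connectivity than its sheer area loss predicts.
    """
    if current.total_area_ha <= 0:
        raise ValueError("current total area is zero: dA undefined")
    if current.eca_ha <= 0:
        raise ValueError("current ECA is zero: dECA undefined")
    d_a = 100.0 * (future.total_area_ha - current.total_area_ha) / current.total_area_ha
    d_eca = 100.0 * (future.eca_ha - current.eca_ha) / current.eca_ha
    return {"dA_pct": d_a, "dECA_pct": d_eca, "weaker_impact": bool(d_eca > d_a)}
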