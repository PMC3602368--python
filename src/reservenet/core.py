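"""Domain types and dispersal-threshold graph construction.

A reserve network is modelled as a set of protected sites, each reduced to
its centroid on an already-projected plane (km) with an associated habitat
area (ha).  Two sites are considered connected for a species when the
distance between them does not exceed the species' median dispersal
distance; the resulting undirected graph is the object every downstream
metric operates on.

Coordinates are planar throughout: no geodesy or CRS handling is done here,
projection is an upstream concern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Site",
    "DistanceMode",
    "Epoch",
    "DistanceMatrix",
    "DispersalGraph",
    "pairwise_distances",
    "build_graph",
]

#: 1 km^2 = 100 ha
HA_PER_KM2 = 100.0


class DistanceMode(str, Enum):
    """How inter-site distances are measured.

    ``centroid``
        Euclidean distance between site centroids.
    ``edge_approx``
        Centroid distance minus the equivalent-circle radii of both sites
        (floored at zero) — a cheap stand-in for edge-to-edge patch distance
        that treats each site as a disc of its habitat area.
    ``matrix``
        Distances are not computed; the caller supplies a matrix.
    """

    CENTROID = "centroid"
    EDGE_APPROX = "edge_approx"
    MATRIX = "matrix"


class Epoch(str, Enum):
    CURRENT = "current"
    FUTURE = "future"


@dataclass(frozen=True)
class Site:
    """One protected site: centroid, habitat area and suitability flags.

    Parameters
    ----------
    site_id
        Unique identifier within a site table.
    x, y
        Planar centroid coordinates in km (projected upstream).
    area_ha
        Habitat area within the site, hectares; must be positive.
    suitable_current, suitable_future
        Whether the site is predicted suitable for the species now and
        under the future scenario.
    """

    site_id: str
    x: float
    y: float
    area_ha: float
    suitable_current: bool = True
    suitable_future: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"site {self.site_id!r}: non-finite coordinates")
        if not (math.isfinite(self.area_ha) and self.area_ha > 0):
            raise ValueError(f"site {self.site_id!r}: area must be positive, got {self.area_ha}")

    @property
    def radius_km(self) -> float:
        """Radius of the circle with this site's habitat area."""
        return math.sqrt(self.area_ha / HA_PER_KM2 / math.pi)


def check_unique_ids(sites: Sequence[Site]) -> None:
    seen: set[str] = set()
    for s in sites:
        if s.site_id in seen:
            raise ValueError(f"duplicate site_id {s.site_id!r}")
        seen.add(s.site_id)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix (km) over an ordered id list."""

    ids: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match id list")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("self-distances must be zero")
        object.__setattr__(self, "d", d)

    def index_of(self, site_id: str) -> int:
        try:
            return self.ids.index(site_id)
        except ValueError:
            raise KeyError(f"unknown site_id {site_id!r}") from None

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self.index_of(a), self.index_of(b)])

    def subset(self, keep: Iterable[str]) -> "DistanceMatrix":
        """Restrict to the given ids, preserving this matrix's order."""
        keep_set = set(keep)
        idx = [i for i, sid in enumerate(self.ids) if sid in keep_set]
        missing = keep_set - {self.ids[i] for i in idx}
        if missing:
            raise KeyError(f"ids not in matrix: {sorted(missing)}")
        return DistanceMatrix(
            ids=tuple(self.ids[i] for i in idx),
            d=self.d[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class DispersalGraph:
    """Undirected graph over suitable sites under a dispersal threshold.

    ``graph`` is a networkx Graph whose nodes are site ids carrying the
    ``site`` attribute (the :class:`Site`) and whose edges carry
    ``distance_km``.
    """

    graph: nx.Graph = field(repr=False)
    threshold_km: float
    distance_mode: DistanceMode
    epoch: Epoch

    @property
    def node_ids(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def site(self, site_id: str) -> Site:
        return self.graph.nodes[site_id]["site"]


def pairwise_distances(
    sites: Sequence[Site], mode: DistanceMode | str = DistanceMode.CENTROID
) -> DistanceMatrix:
    """Compute the pairwise distance matrix between sites.

    In ``edge_approx`` mode each site is treated as a disc of its habitat
    area and the distance is ``max(0, centroid distance − r_i − r_j)`` with
    ``r = sqrt(area_km² / π)``; overlapping discs give distance 0.
    """
    mode = DistanceMode(mode)
    if mode is DistanceMode.MATRIX:
        raise ValueError("mode='matrix' means a precomputed matrix must be supplied by the caller")
    if len(sites) == 0:
        raise ValueError("at least one site is required")
    check_unique_ids(sites)

    xy = np.array([[s.x, s.y] for s in sites], dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    if mode is DistanceMode.EDGE_APPROX:
        r = np.array([s.radius_km for s in sites], dtype=float)
        d = np.maximum(0.0, d - r[:, None] - r[None, :])
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=tuple(s.site_id for s in sites), d=d)


def suitable_in(sites: Sequence[Site], epoch: Epoch | str) -> list[Site]:
    epoch = Epoch(epoch)
    if epoch is Epoch.CURRENT:
        return [s for s in sites if s.suitable_current]
    return [s for s in sites if s.suitable_future]


def build_graph(
    sites: Sequence[Site],
    distances: DistanceMatrix,
    dispersal_km: float,
    epoch: Epoch | str = Epoch.CURRENT,
    distance_mode: DistanceMode | str = DistanceMode.CENTROID,
) -> DispersalGraph:
    """Build the dispersal-threshold graph for one epoch.

    Nodes are the sites suitable in ``epoch``; an edge joins two nodes iff
    their distance is ≤ ``dispersal_km`` (inclusive).  Sites unsuitable in
    the epoch are dropped entirely.
    """
    if dispersal_km <= 0:
        raise ValueError("dispersal distance must be positive")
    epoch = Epoch(epoch)
    check_unique_ids(sites)
    chosen = suitable_in(sites, epoch)

    g = nx.Graph()
    for s in chosen:
        g.add_node(s.site_id, site=s)
    if not chosen:
        warnings.warn(f"no sites suitable in epoch {epoch.value!r}: empty graph", stacklevel=2)

    ids = [s.site_id for s in chosen]
    idx = {sid: distances.index_of(sid) for sid in ids}
    for a in range(len(ids)):
        ia = idx[ids[a]]
        for b in range(a + 1, len(ids)):
            dist = distances.d[ia, idx[ids[b]]]
            if dist <= dispersal_km:
                g.add_edge(ids[a], ids[b], distance_km=float(dist))
    return DispersalGraph(
        graph=g,
        threshold_km=float(dispersal_km),
        distance_mode=DistanceMode(distance_mode),
        epoch=epoch,
    )
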