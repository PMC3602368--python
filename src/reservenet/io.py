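"""Readers and writers for site tables, distance matrices and reports.

All on-disk formats are plain delimited text (UTF-8, comma-separated,
decimal point).  European-style comma decimals in a site table are
handled by ``decimal_comma=True`` on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import DispersalGraph, DistanceMatrix, Site
from .scenario import ScenarioComparison

__all__ = [
    "SITE_COLUMNS",
    "RunConfig",
    "read_sites",
    "write_sites",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_graph",
    "write_report",
]

SITE_COLUMNS = ("site_id", "x_km", "y_km", "area_ha", "suitable_current", "suitable_future")


@dataclasses.dataclass
class RunConfig:
    """Configuration for one single-species pipeline run."""

    species_name: str = "species"
    dispersal_km: float = 90.0
    distance_mode: str = "centroid"
    kernel_half_distance_km: float | None = None  # default: dispersal_km
    n_perm: int = 999
    seed: int = 0
    sites_path: str | None = None
    distance_matrix_path: str | None = None
    output_dir: str = "reservenet_out"

    def __post_init__(self) -> None:
        if self.dispersal_km <= 0:
            raise ValueError("dispersal_km must be positive")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _parse_bool(raw: str, line_no: int, column: str) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    raise ValueError(f"line {line_no}: column {column!r} must be 0 or 1, got {raw!r}")


def read_sites(path: str | Path, decimal_comma: bool = False) -> list[Site]:
    """Read a site table CSV; errors name the offending line."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    unknown = set(df.columns) - set(SITE_COLUMNS)
    if unknown:
        raise ValueError(f"{path}: unknown columns {sorted(unknown)}")

    sites: list[Site] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        sid = row.site_id
        if sid in seen:
            raise ValueError(f"{path}: line {line_no}: duplicate site_id {sid!r}")
        seen.add(sid)
        try:
            nums = {}
            for col in ("x_km", "y_km", "area_ha"):
                raw = getattr(row, col)
                if decimal_comma:
                    raw = raw.replace(",", ".")
                nums[col] = float(raw)
            site = Site(
                site_id=sid,
                x=nums["x_km"],
                y=nums["y_km"],
                area_ha=nums["area_ha"],
                suitable_current=_parse_bool(row.suitable_current, line_no, "suitable_current"),
                suitable_future=_parse_bool(row.suitable_future, line_no, "suitable_future"),
            )
        except ValueError as exc:
            if "line" in str(exc):
                raise
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
        sites.append(site)
    return sites


def write_sites(sites: Sequence[Site], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "x_km": [s.x for s in sites],
            "y_km": [s.y for s in sites],
            "area_ha": [s.area_ha for s in sites],
            "suitable_current": [int(s.suitable_current) for s in sites],
            "suitable_future": [int(s.suitable_future) for s in sites],
        }
    ).to_csv(path, index=False)


def read_distance_matrix(
    path: str | Path, expected_ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Read a square distance-matrix CSV (first row/column = site ids)."""
    df = pd.read_csv(path, index_col=0)
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise ValueError(f"{path}: row ids do not match column ids")
    if expected_ids is not None and set(ids) != set(expected_ids):
        raise ValueError(f"{path}: matrix ids do not match the site table")
    return DistanceMatrix(ids=ids, d=df.to_numpy(dtype=float))


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.d, index=list(matrix.ids), columns=list(matrix.ids)).to_csv(path)


def write_graph(graph: DispersalGraph, edge_path: str | Path, node_path: str | Path) -> None:
    """Export a dispersal graph as edge-list and node-list CSVs."""
    edges = sorted((min(u, v), max(u, v), d["distance_km"]) for u, v, d in graph.graph.edges(data=True))
    pd.DataFrame(edges, columns=["source", "target", "distance_km"]).to_csv(edge_path, index=False)
    nodes = sorted(graph.node_ids)
    pd.DataFrame({"site_id": nodes}).to_csv(node_path, index=False)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_report(comparison: ScenarioComparison, out_dir: str | Path) -> dict[str, Path]:
    """Write the full scenario report: JSON summary, metric and GBC CSVs,
    edge/node lists for both epochs.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["comparison"] = out / "comparison.json"
    paths["comparison"].write_text(
        json.dumps(comparison.to_dict(), indent=2, sort_keys=True, cls=_ReportEncoder) + "\n"
    )
    for epoch, metrics in (("current", comparison.current_metrics), ("future", comparison.future_metrics)):
        p = out / f"node_metrics_{epoch}.csv"
        metrics.to_csv(p, index=False)
        paths[f"node_metrics_{epoch}"] = p
    for epoch, graph in (("current", comparison.current_graph), ("future", comparison.future_graph)):
        e, n = out / f"edges_{epoch}.csv", out / f"nodes_{epoch}.csv"
        write_graph(graph, e, n)
        paths[f"edges_{epoch}"], paths[f"nodes_{epoch}"] = e, n
    gbc_df = pd.DataFrame(
        sorted(comparison.current_indices.gbc_ha2.items()), columns=["site_id", "gbc_ha2"]
    )
    paths["gbc"] = out / "gbc_current.csv"
    gbc_df.to_csv(paths["gbc"], index=False)
    return paths
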