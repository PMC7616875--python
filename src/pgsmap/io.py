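"""Reading and writing the pipeline's file formats.

Everything on disk is plain text: delimited tables (tab by default, the
delimiter is sniffed on read), GeoJSON for geometries and node-valued maps,
JSON for manifests. Every run writes a manifest recording the seed, a hash
of the configuration and the hashes of input files, sufficient to reproduce
any output exactly.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from pgsmap.errors import ConfigError
from pgsmap.grid import AnalysisGrid
from pgsmap.local import LocalFitMap

__all__ = [
    "read_table",
    "write_table",
    "read_region_geojson",
    "write_region_geojson",
    "grid_to_geojson",
    "write_grid",
    "map_to_geojson",
    "write_map",
    "read_map",
    "points_geojson",
    "file_sha256",
    "config_hash",
    "write_manifest",
]


def read_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited text table with a header; sniff the delimiter when
    not given."""
    path = Path(path)
    if sep is None:
        with open(path, newline="") as fh:
            sample = fh.read(4096)
        try:
            sep = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
        except csv.Error:
            sep = "\t"
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
    return path


def read_region_geojson(path):
    """Load the study-region polygon from a GeoJSON file (Feature,
    FeatureCollection or bare geometry)."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "FeatureCollection":
        obj = obj["features"][0]
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    geom = shape(obj)
    if geom.geom_type != "Polygon":
        raise ConfigError(f"region file holds a {geom.geom_type}, expected Polygon")
    return geom


def write_region_geojson(polygon, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    feature = {"type": "Feature", "geometry": mapping(polygon), "properties": {}}
    path.write_text(json.dumps({"type": "FeatureCollection", "features": [feature]}))
    return path


def points_geojson(coords, properties: list[dict]) -> dict:
    """GeoJSON FeatureCollection of points with per-point properties."""
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": props,
        }
        for (x, y), props in zip(np.asarray(coords, dtype=float), properties)
    ]
    return {"type": "FeatureCollection", "features": feats}


def grid_to_geojson(grid: AnalysisGrid) -> dict:
    props = [{"node": i} for i in range(grid.n_nodes)]
    return points_geojson(grid.nodes, props)


def write_grid(grid: AnalysisGrid, geojson_path, edges_path) -> None:
    """Grid nodes as GeoJSON points plus the adjacency as a sparse edge
    list (tab-delimited i, j with i < j)."""
    Path(geojson_path).parent.mkdir(parents=True, exist_ok=True)
    Path(geojson_path).write_text(json.dumps(grid_to_geojson(grid)))
    edges = [(i, j) for i, nbrs in enumerate(grid.adjacency) for j in nbrs if i < j]
    write_table(pd.DataFrame(edges, columns=["i", "j"]), edges_path)


def map_to_geojson(fit_map: LocalFitMap) -> dict:
    tab = fit_map.table
    props = [
        {
            "node": int(i),
            "beta": None if not np.isfinite(r.beta) else float(r.beta),
            "se": None if not np.isfinite(r.se) else float(r.se),
            "n_effective": None if not np.isfinite(r.n_effective) else float(r.n_effective),
            "converged": bool(r.converged),
        }
        for i, r in tab.iterrows()
    ]
    return points_geojson(tab[["x", "y"]].to_numpy(), props)


def write_map(fit_map: LocalFitMap, tsv_path, geojson_path=None) -> None:
    write_table(fit_map.table.reset_index(), tsv_path)
    if geojson_path is not None:
        Path(geojson_path).write_text(json.dumps(map_to_geojson(fit_map)))


def read_map(path) -> pd.DataFrame:
    """Node-indexed map table written by :func:`write_map`."""
    df = read_table(path)
    if "node" not in df.columns:
        raise ConfigError(f"map table {path} lacks a 'node' column")
    return df.set_index("node")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(out_dir, config: dict, seed: int, inputs: dict | None = None, outputs=()) -> Path:
    from pgsmap import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "inputs": {str(k): file_sha256(v) for k, v in (inputs or {}).items() if Path(v).exists()},
        "outputs": [str(p) for p in outputs],
    }
    path = Path(out_dir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
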