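"""Study-bundle persistence: plain-text tables, GAL adjacency, GeoJSON.

A bundle directory holds ``areas.csv`` (area_id, subarea, degurba),
``adjacency.gal`` (GAL neighbour-list format), ``population.csv`` (long
format), ``exposure.csv``, ``deaths.csv``, optionally
``deaths_strata.csv`` (province-wide stratum counts used by internal
standardisation), ``areas.geojson`` (polygons) and ``truth.json``
(synthetic bundles only), plus ``manifest.json`` with checksums and
provenance.  Loading re-validates the schema; malformed input (asymmetric
adjacency, missing areas, negative counts) is rejected, never repaired.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import AreaLattice, StudyBundle

SCHEMA_VERSION = 1


def write_gal(adjacency: set[tuple[int, int]], n: int, path: Path) -> None:
    nbrs: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in sorted(adjacency):
        nbrs[i].append(j)
        nbrs[j].append(i)
    lines = [str(n)]
    for i in range(n):
        lines.append(f"{i} {len(nbrs[i])}")
        lines.append(" ".join(str(j) for j in sorted(nbrs[i])))
    path.write_text("\n".join(lines) + "\n")


def read_gal(path: Path) -> tuple[int, set[tuple[int, int]]]:
    tokens = path.read_text().split("\n")
    header = tokens[0].split()
    n = int(header[-1]) if len(header) > 1 else int(header[0])
    directed: set[tuple[int, int]] = set()
    k = 1
    while k < len(tokens):
        line = tokens[k].strip()
        k += 1
        if not line:
            continue
        node, deg = (int(v) for v in line.split())
        neigh = []
        if deg > 0:
            neigh = [int(v) for v in tokens[k].split()]
            k += 1
            if len(neigh) != deg:
                raise ValueError(f"GAL: node {node} lists {len(neigh)} of {deg} neighbours")
        for j in neigh:
            if j == node:
                raise ValueError(f"GAL: self-neighbour on node {node}")
            directed.add((node, j))
    for i, j in directed:
        if (j, i) not in directed:
            raise ValueError(f"GAL: one-directional edge {i}->{j}; adjacency must be symmetric")
    return n, {(min(i, j), max(i, j)) for i, j in directed}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_bundle(bundle: StudyBundle, path: str | Path, seed: int | None = None) -> Path:
    """Write a bundle directory with manifest; returns the directory path."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lat = bundle.lattice
    areas = pd.DataFrame(
        {
            "area_id": lat.area_ids,
            "subarea": lat.subarea,
            "degurba": lat.degurba,
        }
    )
    if lat.coords is not None:
        areas["x"] = lat.coords[:, 0]
        areas["y"] = lat.coords[:, 1]
    areas.to_csv(path / "areas.csv", index=False)
    write_gal(lat.adjacency, lat.n_areas, path / "adjacency.gal")
    bundle.population.to_csv(path / "population.csv", index=False)
    bundle.exposure.to_csv(path / "exposure.csv", index=False)
    files = ["areas.csv", "adjacency.gal", "population.csv", "exposure.csv"]
    if bundle.deaths is not None:
        bundle.deaths.to_csv(path / "deaths.csv", index=False)
        files.append("deaths.csv")
    if bundle.deaths_strata is not None:
        bundle.deaths_strata.to_csv(path / "deaths_strata.csv", index=False)
        files.append("deaths_strata.csv")
    if bundle.truth is not None:
        (path / "truth.json").write_text(json.dumps(bundle.truth, indent=1))
        files.append("truth.json")
    if lat.polygons is not None:
        from shapely.geometry import mapping

        features = [
            {
                "type": "Feature",
                "properties": {"area_id": int(i)},
                "geometry": mapping(poly),
            }
            for i, poly in enumerate(lat.polygons)
        ]
        (path / "areas.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )
        files.append("areas.geojson")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_areas": int(lat.n_areas),
        "years": [int(y) for y in bundle.years],
        "seed": seed,
        "files": {f: _sha256(path / f) for f in files},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def load_bundle(path: str | Path) -> StudyBundle:
    """Load and validate a bundle directory written by :func:`save_bundle`."""
    path = Path(path)
    for required in ("areas.csv", "adjacency.gal", "population.csv", "exposure.csv"):
        if not (path / required).exists():
            raise FileNotFoundError(f"bundle is missing {required}")
    areas = pd.read_csv(path / "areas.csv")
    n = len(areas)
    if sorted(areas["area_id"].tolist()) != list(range(n)):
        raise ValueError("areas.csv must enumerate area_id 0..n-1")
    n_gal, adjacency = read_gal(path / "adjacency.gal")
    if n_gal != n:
        raise ValueError(f"adjacency.gal lists {n_gal} areas, areas.csv {n}")
    coords = None
    if {"x", "y"}.issubset(areas.columns):
        coords = areas[["x", "y"]].to_numpy()
    polygons = None
    geo = path / "areas.geojson"
    if geo.exists():
        from shapely.geometry import shape

        fc = json.loads(geo.read_text())
        by_id = {f["properties"]["area_id"]: shape(f["geometry"]) for f in fc["features"]}
        polygons = [by_id[i] for i in range(n)]
    lattice = AreaLattice(
        n_areas=n,
        subarea=areas["subarea"].to_numpy(dtype=str),
        degurba=areas["degurba"].to_numpy(dtype=str),
        adjacency=adjacency,
        coords=coords,
        polygons=polygons,
    )
    population = pd.read_csv(path / "population.csv")
    exposure = pd.read_csv(path / "exposure.csv")
    years = tuple(sorted(int(y) for y in exposure["year"].unique()))
    deaths = deaths_strata = truth = None
    if (path / "deaths.csv").exists():
        deaths = pd.read_csv(path / "deaths.csv")
        missing = set(range(n)) - set(deaths["area_id"].unique().tolist())
        if missing:
            raise ValueError(f"deaths.csv missing area ids {sorted(missing)}")
    if (path / "deaths_strata.csv").exists():
        deaths_strata = pd.read_csv(path / "deaths_strata.csv")
    if (path / "truth.json").exists():
        truth = json.loads((path / "truth.json").read_text())
    bundle = StudyBundle(
        lattice=lattice,
        years=years,
        population=population,
        exposure=exposure,
        deaths=deaths,
        deaths_strata=deaths_strata,
        truth=truth,
    )
    bundle.validate()
    return bundle
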