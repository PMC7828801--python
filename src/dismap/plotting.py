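"""Choropleth rendering of RR and exceedance-probability summaries.

RR maps are binned at {<0.75, 0.75–1.00, 1.00–1.25, >1.25} and PP maps at
{<0.10, 0.10–0.90, >0.90}; one raster image and one value-annotated GeoJSON
are written per year so the results stay inspectable without the plotting
stack.  When the lattice carries no polygons, a graph-layout scatter is
drawn instead (with a warning).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import PatchCollection
from matplotlib.patches import Polygon as MplPolygon

from .synthetic import AreaLattice

SCHEMES = {
    "rr_bins": {
        "edges": [-np.inf, 0.75, 1.00, 1.25, np.inf],
        "labels": ["RR < 0.75", "0.75–1.00", "1.00–1.25", "RR > 1.25"],
        "colors": ["#f7fbff", "#c6dbef", "#fc9272", "#a50f15"],
    },
    "pp_bins": {
        "edges": [-np.inf, 0.10, 0.90, np.inf],
        "labels": ["PP < 0.10", "0.10–0.90", "PP > 0.90"],
        "colors": ["#f7fbff", "#c6dbef", "#a50f15"],
    },
}


def bin_values(values: np.ndarray, scheme: str) -> np.ndarray:
    """Bin index per area for the given scheme (0 = lowest bin)."""
    cfg = SCHEMES[scheme]
    return np.digitize(values, cfg["edges"][1:-1], right=False)


def render_choropleth(
    values: pd.DataFrame,
    lattice: AreaLattice,
    scheme: str,
    outdir: str | Path,
    value_col: str | None = None,
    prefix: str | None = None,
) -> list[Path]:
    """Render one map per year; returns the written image paths.

    ``values`` must have columns ``area_id``, ``year`` and the value column
    (``rr_median`` for scheme ``rr_bins``, ``pp`` for ``pp_bins`` by default).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if value_col is None:
        value_col = {"rr_bins": "rr_median", "pp_bins": "pp"}[scheme]
    prefix = prefix or scheme
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SCHEMES[scheme]
    have_polys = lattice.polygons is not None
    if not have_polys:
        warnings.warn("lattice has no polygons; falling back to graph layout")
        import networkx as nx

        pos = (
            {i: tuple(lattice.coords[i]) for i in range(lattice.n_areas)}
            if lattice.coords is not None
            else nx.spring_layout(lattice.graph(), seed=0)
        )
    paths = []
    for year, g in values.groupby("year"):
        g = g.sort_values("area_id")
        v = g[value_col].to_numpy()
        bins = bin_values(v, scheme)
        fig, ax = plt.subplots(figsize=(6, 5))
        if have_polys:
            patches, colors = [], []
            for aid, b in zip(g["area_id"].to_numpy(), bins):
                poly = lattice.polygons[int(aid)]
                xy = np.asarray(poly.exterior.coords)
                patches.append(MplPolygon(xy, closed=True))
                colors.append(cfg["colors"][int(b)])
            pc = PatchCollection(patches, facecolor=colors, edgecolor="grey", lw=0.3)
            ax.add_collection(pc)
            ax.autoscale_view()
        else:
            xs = [pos[i][0] for i in g["area_id"]]
            ys = [pos[i][1] for i in g["area_id"]]
            ax.scatter(xs, ys, c=[cfg["colors"][int(b)] for b in bins], s=60,
                       edgecolors="grey")
        handles = [
            plt.Line2D([], [], marker="s", ls="", color=c, label=l)
            for c, l in zip(cfg["colors"], cfg["labels"])
        ]
        ax.legend(handles=handles, loc="lower right", fontsize=7)
        ax.set_title(f"{value_col} — {year}")
        ax.set_aspect("equal")
        ax.axis("off")
        img = outdir / f"{prefix}_{year}.png"
        fig.savefig(img, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(img)
        # value-annotated polygons, inspectable without matplotlib
        if have_polys:
            from shapely.geometry import mapping

            features = []
            for aid, val, b in zip(g["area_id"].to_numpy(), v, bins):
                features.append(
                    {
                        "type": "Feature",
                        "properties": {
                            "area_id": int(aid),
                            value_col: float(val),
                            "bin": cfg["labels"][int(b)],
                        },
                        "geometry": mapping(lattice.polygons[int(aid)]),
                    }
                )
            (outdir / f"{prefix}_{year}.geojson").write_text(
                json.dumps({"type": "FeatureCollection", "features": features})
            )
    return paths
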