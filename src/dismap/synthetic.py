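"""Synthetic study-bundle generator for areal disease-mapping analyses.

The target data structure is a small-area mortality study: ~190 municipalities
partitioned into three contiguous subareas, yearly cardiovascular death counts,
a fixed reference population stratified by gender and twenty age classes, an
annual-mean PM2.5 exposure surface that is strongly spatially autocorrelated,
and a degree-of-urbanisation label per area.  Every downstream stage of the
pipeline (standardisation, spatial statistics, hierarchical models, model
selection) is testable against bundles produced here, with the generating
parameters stored in a ``truth`` block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from scipy.spatial import Voronoi

try:  # polygons are optional decoration; the analysis only needs the graph
    from shapely.geometry import Polygon
except ImportError:  # pragma: no cover
    Polygon = None

GENDERS = ("M", "F")
N_AGE_CLASSES = 20
DEFAULT_YEARS = tuple(range(2010, 2016))

#: Per-year (mean, SD) calibration of the exposure generator, µg/m³.
DEFAULT_PM25_CALIBRATION: dict[int, tuple[float, float]] = {
    2010: (21.28, 5.37),
    2011: (22.48, 6.11),
    2012: (23.58, 6.49),
    2013: (19.40, 5.77),
    2014: (17.52, 5.08),
    2015: (21.38, 6.33),
}

#: EU annual limit value for PM2.5, µg/m³.
PM25_ANNUAL_LIMIT = 25.0


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class AreaLattice:
    """Areal units with contiguity graph, subarea and urbanisation labels.

    ``adjacency`` is a set of unordered ``(i, j)`` pairs with ``i < j``;
    the graph must be symmetric, irreflexive and connected, and each subarea
    must induce a connected subgraph.
    """

    n_areas: int
    subarea: np.ndarray          # categorical 'A'/'B'/'C' per area
    degurba: np.ndarray          # 'urban' / 'peri-urban' / 'rural' per area
    adjacency: set[tuple[int, int]]
    coords: np.ndarray | None = None        # (n, 2) planar point per area
    polygons: list | None = None            # shapely Polygon per area, optional

    @property
    def area_ids(self) -> np.ndarray:
        return np.arange(self.n_areas)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.adjacency)
        return g

    def adjacency_matrix(self):
        from scipy import sparse

        if not self.adjacency:
            return sparse.csr_matrix((self.n_areas, self.n_areas))
        rows, cols = zip(*self.adjacency)
        i = np.array(rows + cols)
        j = np.array(cols + rows)
        return sparse.csr_matrix(
            (np.ones(i.size), (i, j)), shape=(self.n_areas, self.n_areas)
        )

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_areas, dtype=int)
        for i, j in self.adjacency:
            deg[i] += 1
            deg[j] += 1
        return deg

    def validate(self) -> None:
        n = self.n_areas
        for i, j in self.adjacency:
            if i == j:
                raise ValueError(f"self-loop on area {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) outside 0..{n - 1}")
            if i > j:
                raise ValueError("adjacency pairs must be stored with i < j")
        if len(self.subarea) != n or len(self.degurba) != n:
            raise ValueError("label arrays must have one entry per area")
        if n > 1 and not nx.is_connected(self.graph()):
            raise ValueError("contiguity graph is not connected")
        g = self.graph()
        for lab in np.unique(self.subarea):
            members = np.flatnonzero(self.subarea == lab)
            if len(members) and not nx.is_connected(g.subgraph(members)):
                raise ValueError(f"subarea {lab} is not contiguous")


@dataclass
class StudyBundle:
    """Aligned population / exposure / death tables over areas × years."""

    lattice: AreaLattice
    years: tuple[int, ...]
    population: pd.DataFrame     # area_id, year, gender, age_class, count
    exposure: pd.DataFrame       # area_id, year, pm25
    deaths: pd.DataFrame | None = None          # area_id, year, deaths
    deaths_strata: pd.DataFrame | None = None   # year, gender, age_class, deaths
    truth: dict | None = None

    def population_totals(self) -> pd.DataFrame:
        """Total population per (area_id, year)."""
        return (
            self.population.groupby(["area_id", "year"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "population"})
        )

    def validate(self) -> None:
        self.lattice.validate()
        areas = set(self.lattice.area_ids.tolist())
        years = set(self.years)
        for name, df, col in [
            ("population", self.population, "count"),
            ("exposure", self.exposure, "pm25"),
            ("deaths", self.deaths, "deaths"),
        ]:
            if df is None:
                continue
            missing_a = areas - set(df["area_id"].unique().tolist())
            if missing_a:
                raise ValueError(f"{name} table missing areas {sorted(missing_a)}")
            extra_a = set(df["area_id"].unique().tolist()) - areas
            if extra_a:
                raise ValueError(f"{name} table has unknown areas {sorted(extra_a)}")
            if set(df["year"].unique().tolist()) != years:
                raise ValueError(f"{name} table year set differs from bundle years")
            if (df[col] < 0).any():
                raise ValueError(f"negative values in {name}.{col}")
        tot = self.population_totals()
        if (tot["population"] <= 0).any():
            raise ValueError("every area-year must have positive population")
        if (self.exposure["pm25"] <= 0).any():
            raise ValueError("exposure must be strictly positive")
        if self.deaths is not None:
            m = self.deaths.merge(tot, on=["area_id", "year"])
            if (m["deaths"] > m["population"]).any():
                raise ValueError("deaths exceed population in some area-year")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Allocate ``total`` integer units proportionally to ``weights``.

    Hamilton/largest-remainder apportionment: exact column sum, deterministic.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    raw = w / w.sum() * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _subarea_labels(n: int) -> list[str]:
    return [chr(ord("A") + k) for k in range(n)]


def _grow_subareas(
    coords: np.ndarray,
    adjacency: set[tuple[int, int]],
    sizes: Sequence[int],
    rng: Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Partition the lattice into contiguous regions of exact sizes.

    Projects the points onto a direction and cuts the sorted order into
    slabs; retries with rotated/jittered directions until every slab induces
    a connected subgraph (for random planar lattices this succeeds quickly).
    """
    n = coords.shape[0]
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for i, j in adjacency:
        nbrs[i].append(j)
        nbrs[j].append(i)

    def connected(members: np.ndarray) -> bool:
        mset = set(members.tolist())
        if not mset:
            return True
        stack = [members[0]]
        seen = {int(members[0])}
        while stack:
            v = stack.pop()
            for u in nbrs[v]:
                if u in mset and u not in seen:
                    seen.add(u)
                    stack.append(u)
        return len(seen) == len(mset)

    labels = np.array(_subarea_labels(len(sizes)))
    bounds = np.cumsum([0] + list(sizes))
    for attempt in range(max_tries):
        theta = 0.0 if attempt == 0 else rng.uniform(0.0, math.pi)
        proj = coords @ np.array([math.cos(theta), math.sin(theta)])
        proj = proj + rng.normal(scale=1e-9, size=n)
        order = np.argsort(proj)
        out = np.empty(n, dtype=object)
        ok = True
        for k in range(len(sizes)):
            members = order[bounds[k] : bounds[k + 1]]
            out[members] = labels[k]
            if not connected(members):
                ok = False
                break
        if ok:
            return out.astype(str)
    raise RuntimeError("could not partition the lattice into contiguous subareas")


def _voronoi_lattice(n: int, rng: Generator, aspect: float = 1.25):
    """Random seeded Voronoi tessellation of a rectangle.

    Contiguity (shared cell edges) is obtained from the Voronoi ridges after
    mirroring the points across the four rectangle sides, which also bounds
    every original cell inside the rectangle.
    """
    width, height = aspect, 1.0
    pts = rng.uniform(size=(n, 2)) * np.array([width, height])
    if n == 1:
        poly = None
        if Polygon is not None:
            poly = [Polygon([(0, 0), (width, 0), (width, height), (0, height)])]
        return pts, set(), poly
    mirrored = np.vstack(
        [
            pts,
            pts * [-1, 1],
            np.array([2 * width, 0]) + pts * [-1, 1],
            pts * [1, -1],
            np.array([0, 2 * height]) + pts * [1, -1],
        ]
    )
    vor = Voronoi(mirrored)
    edges: set[tuple[int, int]] = set()
    for a, b in vor.ridge_points:
        if a < n and b < n and a != b:
            edges.add((min(a, b), max(a, b)))
    polygons = None
    if Polygon is not None:
        polygons = []
        for i in range(n):
            region = vor.regions[vor.point_region[i]]
            polygons.append(Polygon(vor.vertices[region]).buffer(0))
    return pts, edges, polygons


def _grid_lattice(n: int, queen: bool = False):
    """Regular grid with rook (default) or queen contiguity."""
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    coords = np.array([(i % ncols, i // ncols) for i in range(n)], dtype=float)
    edges: set[tuple[int, int]] = set()
    steps = [(1, 0), (0, 1)] + ([(1, 1), (1, -1)] if queen else [])
    for i in range(n):
        x, y = int(coords[i, 0]), int(coords[i, 1])
        for dx, dy in steps:
            xx, yy = x + dx, y + dy
            j = yy * ncols + xx
            if 0 <= xx < ncols and 0 <= yy < nrows and j < n:
                edges.add((min(i, j), max(i, j)))
    polygons = None
    if Polygon is not None:
        polygons = [
            Polygon(
                [(x - 0.5, y - 0.5), (x + 0.5, y - 0.5), (x + 0.5, y + 0.5), (x - 0.5, y + 0.5)]
            )
            for x, y in coords
        ]
    return coords, edges, polygons


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_lattice(
    n_areas: int = 188,
    subarea_sizes: Sequence[int] = (53, 58, 77),
    seed: int = 0,
    nonrural_fraction: float = 28 / 188,
    n_urban: int = 2,
    geometry: str = "voronoi",
) -> AreaLattice:
    """Generate a connected areal lattice with contiguous subareas.

    The default emulates a province of 188 municipalities split into three
    subareas of 53/58/77 units where only 28 units are urban or peri-urban
    (two urban cores with peri-urban rings, the rest rural).

    Parameters
    ----------
    n_areas:
        Number of areal units; must equal ``sum(subarea_sizes)``.
    subarea_sizes:
        Target size of each contiguous subarea.
    nonrural_fraction:
        Fraction of areas labelled urban or peri-urban.
    geometry:
        ``"voronoi"`` (random seeded tessellation, irregular degrees) or
        ``"grid"`` (regular rook grid).
    """
    if sum(subarea_sizes) != n_areas:
        raise ValueError(
            f"sum(subarea_sizes)={sum(subarea_sizes)} does not equal n_areas={n_areas}"
        )
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    rng = default_rng(seed)
    if geometry == "voronoi":
        coords, edges, polygons = _voronoi_lattice(n_areas, rng)
    elif geometry == "grid":
        coords, edges, polygons = _grid_lattice(n_areas)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    if n_areas == 1:
        subarea = np.array([_subarea_labels(len(subarea_sizes))[0]])
    else:
        subarea = _grow_subareas(coords, edges, subarea_sizes, rng)

    # urban cores in the largest subareas, peri-urban rings around them
    degurba = np.array(["rural"] * n_areas, dtype=object)
    n_nonrural = int(round(nonrural_fraction * n_areas))
    n_urban_eff = min(n_urban, n_nonrural, n_areas)
    if n_urban_eff > 0 and n_areas > 1:
        order = np.argsort([-s for s in subarea_sizes], kind="stable")
        labels = np.array(_subarea_labels(len(subarea_sizes)))
        urban_nodes: list[int] = []
        for k in order[:n_urban_eff]:
            members = np.flatnonzero(subarea == labels[k])
            centroid = coords[members].mean(axis=0)
            d = np.linalg.norm(coords[members] - centroid, axis=1)
            urban_nodes.append(int(members[np.argmin(d)]))
        g = nx.Graph()
        g.add_nodes_from(range(n_areas))
        g.add_edges_from(edges)
        for u in urban_nodes:
            degurba[u] = "urban"
        frontier = list(urban_nodes)
        n_assigned = len(urban_nodes)
        while n_assigned < n_nonrural and frontier:
            nxt: list[int] = []
            for u in frontier:
                for v in sorted(g.neighbors(u)):
                    if degurba[v] == "rural" and n_assigned < n_nonrural:
                        degurba[v] = "peri-urban"
                        n_assigned += 1
                        nxt.append(v)
            frontier = nxt
    lattice = AreaLattice(
        n_areas=n_areas,
        subarea=subarea,
        degurba=degurba.astype(str),
        adjacency=edges,
        coords=coords,
        polygons=polygons,
    )
    lattice.validate()
    return lattice


def _age_profile() -> np.ndarray:
    """Ageing-skewed share of the population in 20 five-year age classes."""
    j = np.arange(1, N_AGE_CLASSES + 1)
    p = 0.75 * np.exp(-0.5 * ((j - 8.5) / 5.0) ** 2) + 0.25 * np.exp(
        -0.5 * ((j - 15.5) / 3.0) ** 2
    )
    return p / p.sum()


def _male_fraction_by_age(target_share: float, age_p: np.ndarray) -> np.ndarray:
    """Male fraction per age class, declining with age, matching the target share."""
    j = np.arange(N_AGE_CLASSES)
    m = 0.515 - 0.165 * j / (N_AGE_CLASSES - 1)
    delta = target_share - float(age_p @ m)
    return np.clip(m + delta, 0.01, 0.99)


def generate_population(
    lattice: AreaLattice,
    years: Sequence[int] = DEFAULT_YEARS,
    total: int = 535_666,
    male_share: float = 0.4828,
    seed: int = 0,
    dominant_share: tuple[float, float] = (0.118, 0.132),
    lognormal_sigma: float = 1.0,
    min_area_population: int = 100,
) -> pd.DataFrame:
    """Allocate a fixed reference population over areas, genders and age classes.

    Area sizes are heavy-tailed (log-normal) with one dominant area holding
    ~12–13% of the total, emulating a provincial capital.  The population is
    held constant across years (a fixed reference table); gender × age cells
    are obtained by deterministic largest-remainder rounding of the expected
    counts so that the realised male share matches ``male_share`` closely.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0.0 < male_share < 1.0):
        raise ValueError("male_share must be in (0, 1)")
    rng = default_rng(seed)
    n = lattice.n_areas

    weights = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n)
    if n > 1:
        urban = np.flatnonzero(lattice.degurba == "urban")
        dom = int(urban[0]) if len(urban) else int(np.argmax(weights))
        share = rng.uniform(*dominant_share)
        weights[dom] = 0.0
        weights = weights / weights.sum() * (1.0 - share)
        weights[dom] = share
    floor = min(min_area_population, total // max(n, 1))
    area_pop = largest_remainder(weights, total - floor * n) + floor

    age_p = _age_profile()
    male_frac = _male_fraction_by_age(male_share, age_p)
    cell_share = np.concatenate([age_p * male_frac, age_p * (1.0 - male_frac)])

    rows = []
    for a in range(n):
        cells = largest_remainder(cell_share, int(area_pop[a]))
        for gi, gender in enumerate(GENDERS):
            for age in range(N_AGE_CLASSES):
                rows.append((a, gender, age + 1, int(cells[gi * N_AGE_CLASSES + age])))
    one_year = pd.DataFrame(rows, columns=["area_id", "gender", "age_class", "count"])
    frames = []
    for year in years:
        f = one_year.copy()
        f.insert(1, "year", int(year))
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def generate_exposure_field(
    lattice: AreaLattice,
    years: Sequence[int] = DEFAULT_YEARS,
    mean_by_year: Mapping[int, float] | Sequence[float] | None = None,
    sd_by_year: Mapping[int, float] | Sequence[float] | None = None,
    spatial_range: float = 0.985,
    seed: int = 0,
    gradient_weight: float = 0.3,
    spectral_power: float = 5.0,
    year_noise: float = 0.1,
    floor: float = 0.5,
) -> pd.DataFrame:
    """Draw a spatially smooth annual-mean PM2.5 surface per year.

    The smooth component is a zero-mean Gaussian field synthesised in the
    Moran eigenvector basis of the contiguity graph (eigenvectors of the
    doubly centred adjacency matrix) with spectral weights λ^``spectral_power``,
    which concentrates variance on the largest-scale spatial patterns, plus a
    monotone north–south gradient.  ``spatial_range`` in [0, 1] is the
    variance share of that smooth component (0 → independent noise; at the
    default calibration a 188-area lattice yields sample Moran's I ≈ 0.95).
    Each year the field is rescaled exactly to the requested mean/SD and
    truncated below at ``floor`` µg/m³.
    """
    if not 0.0 <= spatial_range <= 1.0:
        raise ValueError("spatial_range must be in [0, 1]")
    n = lattice.n_areas
    years = [int(y) for y in years]
    if mean_by_year is None:
        try:
            mean_by_year = {y: DEFAULT_PM25_CALIBRATION[y][0] for y in years}
        except KeyError as exc:
            raise ValueError(f"no default PM2.5 calibration for year {exc}") from exc
    if sd_by_year is None:
        sd_by_year = {y: DEFAULT_PM25_CALIBRATION[y][1] for y in years}
    if not isinstance(mean_by_year, Mapping):
        mean_by_year = dict(zip(years, mean_by_year))
    if not isinstance(sd_by_year, Mapping):
        sd_by_year = dict(zip(years, sd_by_year))
    if any(mean_by_year[y] <= 0 for y in years):
        raise ValueError("yearly means must be positive")

    rng = default_rng(seed)
    if n > 1 and not nx.is_connected(lattice.graph()):
        raise ValueError("exposure GMRF requires a connected lattice")

    def standardize(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return (v - v.mean()) / s if s > 0 else v - v.mean()

    if n > 1 and spatial_range > 0:
        adj = lattice.adjacency_matrix().toarray()
        centre = np.eye(n) - np.ones((n, n)) / n
        vals, vecs = np.linalg.eigh(centre @ adj @ centre)
        keep = vals > 1e-8
        z = rng.standard_normal(n)
        smooth = vecs[:, keep] @ (z[: keep.sum()] * vals[keep] ** spectral_power)
        gradient = standardize(lattice.coords[:, 1]) if lattice.coords is not None else 0.0
        combo = standardize(standardize(smooth) + gradient_weight * gradient)
    else:
        rng.standard_normal(n)  # keep the stream aligned across spatial_range values
        combo = np.zeros(n)
    white = rng.standard_normal(n)
    latent = math.sqrt(1.0 - spatial_range) * white + math.sqrt(spatial_range) * combo

    rows = []
    for year in years:
        f = latent + year_noise * rng.standard_normal(n)
        f = standardize(f) if n > 1 else np.zeros(1)
        x = mean_by_year[year] + sd_by_year[year] * f
        x = np.maximum(x, floor)
        rows.append(
            pd.DataFrame({"area_id": np.arange(n), "year": year, "pm25": x})
        )
    return pd.concat(rows, ignore_index=True)


def baseline_stratum_risks(
    population: pd.DataFrame,
    crude_rate_per_1000: float = 4.5,
    age_log_slope: float = 0.45,
    male_excess: float = 1.3,
) -> pd.DataFrame:
    """Baseline death risk per gender × age stratum.

    Risk rises exponentially with age class and carries a male excess at a
    given age; the level is normalised so that the implied province-wide
    crude mortality rate equals ``crude_rate_per_1000``.
    """
    strata = population.groupby(["gender", "age_class"], as_index=False)["count"].sum()
    rel = np.exp(age_log_slope * (strata["age_class"].to_numpy() - 1.0))
    rel = rel * np.where(strata["gender"].to_numpy() == "M", male_excess, 1.0)
    total_pop = strata["count"].sum()
    scale = crude_rate_per_1000 / 1000.0 * total_pop / float(strata["count"] @ rel)
    risk = np.minimum(rel * scale, 0.95)
    return strata.assign(risk=risk)[["gender", "age_class", "risk"]]


def _sample_icar(lattice: AreaLattice, sd: float, rng: Generator) -> np.ndarray:
    """Draw a zero-mean intrinsic CAR field scaled to marginal SD ``sd``."""
    n = lattice.n_areas
    if n == 1:
        return np.zeros(1)
    adj = lattice.adjacency_matrix().toarray()
    lap = np.diag(adj.sum(axis=1)) - adj
    vals, vecs = np.linalg.eigh(lap)
    keep = vals > 1e-8
    z = rng.standard_normal(keep.sum())
    x = vecs[:, keep] @ (z / np.sqrt(vals[keep]))
    x = x - x.mean()
    s = x.std()
    return x / s * sd if s > 0 else x


def generate_outcomes(
    bundle: StudyBundle,
    beta0: float = 0.0,
    beta_pm: float = math.log(1.075),
    beta_rural: float = math.log(1.022),
    beta_year: float = 0.0,
    re_kind: str = "none",
    re_sd: float = 0.15,
    re_sd_icar: float = 0.15,
    seed: int = 0,
    crude_rate_per_1000: float = 4.5,
) -> StudyBundle:
    """Simulate death counts from the Poisson log-linear model.

    The linear predictor uses exactly the covariate coding of the risk
    models: PM2.5 centred at the bundle grand mean and scaled by 15 µg/m³, a
    rural indicator (urban and peri-urban merged), and the year measured from
    the first study year.  Deaths are drawn at the stratum level,
    ``Poisson(pop_aj · risk_j · exp(η_a,t))``, so that both the area-year
    totals and the province-wide stratum totals (needed for internal
    standardisation) are consistent realisations.
    """
    if re_kind not in {"none", "iid", "bym"}:
        raise ValueError("re_kind must be one of none/iid/bym")
    rng = default_rng(seed)
    lattice = bundle.lattice
    n = lattice.n_areas
    years = list(bundle.years)
    tot = bundle.population_totals()
    if (tot["population"] <= 0).any():
        raise ValueError("zero population in some area-year")

    risks = baseline_stratum_risks(bundle.population, crude_rate_per_1000)
    pop0 = bundle.population[bundle.population["year"] == years[0]]
    pop_risk = pop0.merge(risks, on=["gender", "age_class"])
    pop_risk["lam0"] = pop_risk["count"] * pop_risk["risk"]

    pm = bundle.exposure.set_index(["area_id", "year"])["pm25"]
    grand_mean = float(bundle.exposure["pm25"].mean())
    rural = (lattice.degurba == "rural").astype(float)

    u = rng.normal(scale=re_sd, size=n) if re_kind in {"iid", "bym"} else np.zeros(n)
    s = _sample_icar(lattice, re_sd_icar, rng) if re_kind == "bym" else np.zeros(n)

    death_rows = []
    strat_acc: dict[tuple[int, str, int], int] = {}
    rr_true = {}
    lam_by_area = pop_risk.groupby("area_id")["lam0"].sum()
    for year in years:
        year_c = year - years[0]
        for a in range(n):
            pm_c = (pm.loc[(a, year)] - grand_mean) / 15.0
            eta = beta0 + beta_pm * pm_c + beta_rural * rural[a] + beta_year * year_c
            eta += u[a] + s[a]
            rr_true[(a, year)] = math.exp(eta)
        # stratum-level draws, vectorised over strata within a year
        ar = pop_risk["area_id"].to_numpy()
        lam = pop_risk["lam0"].to_numpy() * np.array(
            [rr_true[(a, year)] for a in ar]
        )
        draws = rng.poisson(lam)
        draws = np.minimum(draws, pop_risk["count"].to_numpy())
        by_area = np.zeros(n, dtype=int)
        np.add.at(by_area, ar, draws)
        for a in range(n):
            death_rows.append((a, year, int(by_area[a])))
        g = pop_risk["gender"].to_numpy()
        ac = pop_risk["age_class"].to_numpy()
        for gi, age, d in zip(g, ac, draws):
            key = (year, gi, int(age))
            strat_acc[key] = strat_acc.get(key, 0) + int(d)

    deaths = pd.DataFrame(death_rows, columns=["area_id", "year", "deaths"])
    deaths_strata = pd.DataFrame(
        [(y, g, a, c) for (y, g, a), c in sorted(strat_acc.items())],
        columns=["year", "gender", "age_class", "deaths"],
    )
    truth = {
        "beta0": beta0,
        "beta_pm": beta_pm,
        "beta_rural": beta_rural,
        "beta_year": beta_year,
        "re_kind": re_kind,
        "re_sd": re_sd,
        "re_sd_icar": re_sd_icar,
        "pm_grand_mean": grand_mean,
        "u": u.tolist(),
        "s": s.tolist(),
        "expected_baseline": {
            str(int(a)): float(v) for a, v in lam_by_area.items()
        },
        "rr": {f"{a}:{y}": float(v) for (a, y), v in rr_true.items()},
        "crude_rate_per_1000": crude_rate_per_1000,
        "seed": seed,
    }
    out = replace(bundle, deaths=deaths, deaths_strata=deaths_strata, truth=truth)
    out.validate()
    return out


def make_bundle(
    n_areas: int = 188,
    subarea_sizes: Sequence[int] = (53, 58, 77),
    years: Sequence[int] = DEFAULT_YEARS,
    total_population: int = 535_666,
    male_share: float = 0.4828,
    seed: int = 0,
    spatial_range: float = 0.985,
    beta0: float = 0.0,
    beta_pm: float = math.log(1.075),
    beta_rural: float = math.log(1.022),
    beta_year: float = 0.0,
    re_kind: str = "iid",
    re_sd: float = 0.15,
    re_sd_icar: float = 0.15,
    geometry: str = "voronoi",
    mean_by_year=None,
    sd_by_year=None,
) -> StudyBundle:
    """Generate a complete study bundle (lattice → population → exposure → deaths).

    Sub-seeds for the four generators are spawned deterministically from
    ``seed`` so that two calls with identical arguments produce identical
    bundles.
    """
    ss = np.random.SeedSequence(seed)
    s_lat, s_pop, s_exp, s_out = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
    lattice = generate_lattice(n_areas, subarea_sizes, seed=s_lat, geometry=geometry)
    population = generate_population(
        lattice, years, total=total_population, male_share=male_share, seed=s_pop
    )
    exposure = generate_exposure_field(
        lattice,
        years,
        seed=s_exp,
        spatial_range=spatial_range,
        mean_by_year=mean_by_year,
        sd_by_year=sd_by_year,
    )
    bundle = StudyBundle(
        lattice=lattice, years=tuple(int(y) for y in years),
        population=population, exposure=exposure,
    )
    return generate_outcomes(
        bundle,
        beta0=beta0,
        beta_pm=beta_pm,
        beta_rural=beta_rural,
        beta_year=beta_year,
        re_kind=re_kind,
        re_sd=re_sd,
        re_sd_icar=re_sd_icar,
        seed=s_out,
    )


def exceedance_summary(exposure: pd.DataFrame, limit: float = PM25_ANNUAL_LIMIT) -> pd.DataFrame:
    """Count areas whose annual mean strictly exceeds ``limit``, per year.

    Percentages are of the total number of areas in the table.
    """
    if exposure.empty:
        raise ValueError("exposure table is empty")
    n_areas = exposure["area_id"].nunique()
    out = (
        exposure.assign(exceed=exposure["pm25"] > limit)
        .groupby("year", as_index=False)["exceed"]
        .sum()
        .rename(columns={"exceed": "n_exceeding"})
    )
    out["n_areas"] = n_areas
    out["pct"] = out["n_exceeding"] / n_areas * 100.0
    out["n_exceeding"] = out["n_exceeding"].astype(int)
    return out
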