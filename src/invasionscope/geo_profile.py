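"""Dragnet geographic profiling with bootstrap aggregation.

Geographic profiling (GP) scores every cell of a regular longitude/latitude
grid by aggregated distance-decay contributions from georeferenced occurrence
points, to prioritise the likely origin of a spatial point pattern (here, the
spread of an invasive sap beetle from its introduction site).  The Dragnet
family of GP algorithms uses a monotone negative-exponential decay with *no*
buffer zone: the score is maximal at zero distance from an occurrence, which
is appropriate for organisms whose spread is dominated by short-range
dispersal and human-mediated transport.

The model implemented here is

    score(c) = (1/N) * sum_i exp(-beta * d(c, i) / sigma)

where ``d`` is the great-circle (haversine) distance from cell centre ``c``
to occurrence ``i``, ``N`` the number of occurrences, ``beta`` a
dimensionless decay coefficient and ``sigma`` a distance normaliser (by
default the mean pairwise distance among the occurrences, making ``beta``
scale-free).  Robustness is obtained by bagging: the scorer is re-run on
random subsamples of the occurrence set (each drawing 25--75 % of the data),
each replicate surface is min--max rescaled to [0, 1], and the cell-wise
mean across replicates is the profile.  The final surface can be restricted
to an elevation band (e.g. 0--600 m a.s.l. when the organism is never found
higher) and summit regions of the surface are extracted as ranked candidate
source areas.

Two interfaces are provided: plain functions (:func:`dragnet_score`,
:func:`bootstrap_profile`, :func:`apply_elevation_mask`,
:func:`extract_source_areas`) and a model/results pair
(:class:`GeographicProfile` / :class:`GeographicProfileResults`) in the
style of statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "EARTH_RADIUS_KM",
    "SITE_TYPES",
    "OccurrenceRecord",
    "GridSpec",
    "DragnetParams",
    "BootstrapParams",
    "ScoreSurface",
    "ElevationGrid",
    "SourceArea",
    "haversine_distance",
    "mean_pairwise_distance",
    "dragnet_score",
    "bootstrap_profile",
    "apply_elevation_mask",
    "extract_source_areas",
    "GeographicProfile",
    "GeographicProfileResults",
]

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Recognised monitoring-site categories.
SITE_TYPES = frozenset({"warehouse", "orchard", "farm"})

#: Lowest land elevation on Earth (Dead Sea shore), m a.s.l.
_MIN_LAND_ELEVATION = -430.0


class ValidationError(ValueError):
    """Raised when an input record or parameter violates its contract."""


def _check_lonlat(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValidationError("coordinates must be finite")
    if np.any(lon < -180.0) or np.any(lon > 180.0):
        raise ValidationError("longitude out of range [-180, 180]")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValidationError("latitude out of range [-90, 90]")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced monitoring site (WGS84 decimal degrees)."""

    site_id: str
    longitude: float
    latitude: float
    elevation: float
    site_type: str = "orchard"
    year: int = 2019
    infested: bool = True

    def __post_init__(self):
        _check_lonlat(self.longitude, self.latitude)
        if not math.isfinite(self.elevation) or self.elevation < _MIN_LAND_ELEVATION:
            raise ValidationError(
                f"site {self.site_id!r}: elevation {self.elevation} m is below "
                f"the lowest land elevation ({_MIN_LAND_ELEVATION} m)"
            )
        if self.site_type not in SITE_TYPES:
            raise ValidationError(
                f"site {self.site_id!r}: site_type {self.site_type!r} not one of "
                f"{sorted(SITE_TYPES)}"
            )


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat raster; row 0 is the northernmost row.

    Cell centres define the evaluation points.  ``n_rows``/``n_cols`` are
    derived from the bounds and cell size (ceiling, so the grid covers the
    full bounding box).
    """

    min_lon: float
    max_lon: float
    min_lat: float
    max_lat: float
    cell_size: float

    def __post_init__(self):
        _check_lonlat([self.min_lon, self.max_lon], [self.min_lat, self.max_lat])
        if not self.max_lon > self.min_lon:
            raise ValidationError("max_lon must exceed min_lon")
        if not self.max_lat > self.min_lat:
            raise ValidationError("max_lat must exceed min_lat")
        if not self.cell_size > 0:
            raise ValidationError("cell_size must be positive")

    @property
    def n_cols(self) -> int:
        return max(1, int(math.ceil((self.max_lon - self.min_lon) / self.cell_size - 1e-9)))

    @property
    def n_rows(self) -> int:
        return max(1, int(math.ceil((self.max_lat - self.min_lat) / self.cell_size - 1e-9)))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lons of columns, lats of rows); lats descend (row 0 north)."""
        lons = self.min_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lats = self.max_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return lons, lats

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lons, lats = self.cell_centers()
        return float(lons[col]), float(lats[row])

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; clipped to the grid."""
        col = int((lon - self.min_lon) / self.cell_size)
        row = int((self.max_lat - lat) / self.cell_size)
        return (min(max(row, 0), self.n_rows - 1), min(max(col, 0), self.n_cols - 1))

    def contains(self, lon: float, lat: float) -> bool:
        return (self.min_lon <= lon <= self.max_lon) and (self.min_lat <= lat <= self.max_lat)

    @classmethod
    def from_points(
        cls, lons: Sequence[float], lats: Sequence[float], cell_size: float = 0.005,
        margin: float = 0.05,
    ) -> "GridSpec":
        """Bounding box of the points, expanded by ``margin`` degrees."""
        lons = np.asarray(lons, float)
        lats = np.asarray(lats, float)
        return cls(
            min_lon=float(lons.min() - margin), max_lon=float(lons.max() + margin),
            min_lat=float(lats.min() - margin), max_lat=float(lats.max() + margin),
            cell_size=cell_size,
        )

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.min_lon - other.min_lon) <= tol
            and abs(self.max_lon - other.max_lon) <= tol
            and abs(self.min_lat - other.min_lat) <= tol
            and abs(self.max_lat - other.max_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass(frozen=True)
class DragnetParams:
    """Decay kernel settings.  ``buffer`` is fixed at none by design."""

    decay_coefficient: float = 1.0
    normalize_by: str = "mean_pairwise_distance"  # or "none"

    def __post_init__(self):
        if not self.decay_coefficient > 0:
            raise ValidationError("decay_coefficient must be > 0")
        if self.normalize_by not in ("mean_pairwise_distance", "none"):
            raise ValidationError(
                f"normalize_by must be 'mean_pairwise_distance' or 'none', "
                f"got {self.normalize_by!r}"
            )


@dataclass(frozen=True)
class BootstrapParams:
    """Bagging scheme: subsample fractions drawn uniformly per replicate."""

    n_replicates: int = 30
    fraction_low: float = 0.25
    fraction_high: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not (0 < self.fraction_low <= self.fraction_high <= 1):
            raise ValidationError("need 0 < fraction_low <= fraction_high <= 1")


@dataclass
class ScoreSurface:
    """A grid of profile scores with a validity mask (True = valid cell)."""

    grid: GridSpec
    scores: np.ndarray
    mask: np.ndarray
    provenance: str = "single-run"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scores.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValidationError(
                f"scores/mask shape {self.scores.shape}/{self.mask.shape} does not "
                f"match grid shape {self.grid.shape}"
            )
        if np.any(~np.isfinite(self.scores[self.mask])) or np.any(self.scores[self.mask] < 0):
            raise ValidationError("valid scores must be finite and >= 0")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def rescaled(self) -> "ScoreSurface":
        """Min–max rescale valid scores to [0, 1] (constant surface -> 0)."""
        out = self.scores.copy()
        v = out[self.mask]
        if v.size:
            lo, hi = v.min(), v.max()
            out[self.mask] = (v - lo) / (hi - lo) if hi > lo else 0.0
        return ScoreSurface(self.grid, out, self.mask.copy(), self.provenance)

    def argmax_cell(self) -> tuple[int, int]:
        """(row, col) of the highest-scoring valid cell; ties break by (row, col)."""
        if not self.mask.any():
            raise ValidationError("surface has no valid cells")
        masked = np.where(self.mask, self.scores, -np.inf)
        idx = int(np.argmax(masked))  # C order => lexicographic (row, col) tie-break
        return np.unravel_index(idx, masked.shape)  # type: ignore[return-value]


@dataclass
class ElevationGrid:
    """A digital elevation model aligned to a :class:`GridSpec` (metres a.s.l.)."""

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray | None = None  # False where NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"DEM shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def elevation_at(self, lon: float, lat: float) -> float:
        r, c = self.grid.cell_of(lon, lat)
        return float(self.values[r, c])


@dataclass
class SourceArea:
    """A ranked candidate introduction area (cluster of top-scoring cells)."""

    rank: int
    peak_lon: float
    peak_lat: float
    peak_score: float
    member_cells: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.member_cells)


# ---------------------------------------------------------------------------
# distances

def haversine_distance(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def mean_pairwise_distance(lons: np.ndarray, lats: np.ndarray) -> float:
    """Mean haversine distance over all unordered pairs of points (km)."""
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    n = lons.size
    if n < 2:
        raise ValidationError("need at least 2 points for a pairwise distance")
    iu = np.triu_indices(n, k=1)
    d = haversine_distance(lons[iu[0]], lats[iu[0]], lons[iu[1]], lats[iu[1]])
    return float(np.mean(d))


# ---------------------------------------------------------------------------
# scoring

def _occurrence_arrays(occurrences: Sequence[OccurrenceRecord]) -> tuple[np.ndarray, np.ndarray]:
    lons = np.array([o.longitude for o in occurrences], float)
    lats = np.array([o.latitude for o in occurrences], float)
    return lons, lats


def dragnet_score(
    occurrences: Sequence[OccurrenceRecord],
    grid: GridSpec,
    params: DragnetParams | None = None,
) -> ScoreSurface:
    """Negative-exponential distance-decay score surface (no buffer zone).

    score(c) = (1/N) sum_i exp(-beta * d(c, i) / sigma), with sigma the mean
    pairwise occurrence distance (or 1 km when ``normalize_by='none'``).
    """
    params = params or DragnetParams()
    if len(occurrences) == 0:
        raise ValidationError("dragnet_score requires at least one occurrence")
    lons, lats = _occurrence_arrays(occurrences)
    # Canonical accumulation order: the surface is bitwise invariant to the
    # order occurrences are supplied in (float addition does not commute).
    order = np.lexsort((lats, lons))
    lons, lats = lons[order], lats[order]
    if params.normalize_by == "mean_pairwise_distance":
        if len(occurrences) < 2:
            raise ValidationError(
                "mean-pairwise-distance normalisation needs >= 2 occurrences"
            )
        sigma = mean_pairwise_distance(lons, lats)
        if sigma == 0.0:
            raise ValidationError(
                "degenerate configuration: all occurrences share one location, "
                "mean pairwise distance is zero"
            )
    else:
        sigma = 1.0

    glons, glats = grid.cell_centers()
    lon_grid = np.broadcast_to(glons[None, :], grid.shape)
    lat_grid = np.broadcast_to(glats[:, None], grid.shape)
    acc = np.zeros(grid.shape, float)
    beta = params.decay_coefficient
    for lo, la in zip(lons, lats):
        d = haversine_distance(lon_grid, lat_grid, lo, la)
        acc += np.exp(-beta * d / sigma)
    acc /= len(occurrences)
    return ScoreSurface(grid, acc, np.ones(grid.shape, bool), "single-run")


def bootstrap_profile(
    occurrences: Sequence[OccurrenceRecord],
    grid: GridSpec,
    params: DragnetParams | None = None,
    boot: BootstrapParams | None = None,
) -> ScoreSurface:
    """Bagged Dragnet profile: mean of rescaled subsample score surfaces.

    Each replicate draws a uniform fraction u in [fraction_low, fraction_high]
    of the data (at least 2 points, without replacement), scores it, min–max
    rescales the replicate surface to [0, 1], and the cell-wise mean across
    replicates is returned.  Replicate seeds are spawned deterministically
    from ``boot.seed``, so runs are reproducible and parallelisable.
    """
    params = params or DragnetParams()
    boot = boot or BootstrapParams()
    n = len(occurrences)
    if n < 3:
        raise ValidationError("bootstrap_profile requires at least 3 occurrences")
    children = np.random.SeedSequence(boot.seed).spawn(boot.n_replicates)
    reps = np.empty((boot.n_replicates,) + grid.shape, float)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        u = rng.uniform(boot.fraction_low, boot.fraction_high)
        m = min(n, max(2, int(np.rint(u * n))))
        idx = rng.choice(n, size=m, replace=False)
        sub = [occurrences[i] for i in idx]
        reps[r] = dragnet_score(sub, grid, params).rescaled().scores
    # Centered accumulation: exact when replicates coincide (e.g. fraction 1.0)
    # and better conditioned than a plain sum in general.
    base = reps[0]
    mean = base + (reps - base).sum(axis=0) / boot.n_replicates
    return ScoreSurface(grid, mean, np.ones(grid.shape, bool), "bootstrap-mean")


def apply_elevation_mask(
    surface: ScoreSurface,
    dem: ElevationGrid,
    max_elevation: float = 600.0,
) -> ScoreSurface:
    """Invalidate cells outside the elevation band [0, max_elevation] m a.s.l.

    The band is inclusive at both ends; NODATA DEM cells are also masked.
    Surviving scores are unchanged.
    """
    if not dem.grid.approx_equal(surface.grid):
        raise ValidationError("DEM grid does not match the surface grid (shape/georeference)")
    ok = dem.valid & (dem.values >= 0.0) & (dem.values <= max_elevation)
    return ScoreSurface(surface.grid, surface.scores.copy(), surface.mask & ok, "masked")


# ---------------------------------------------------------------------------
# hotspot extraction

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def extract_source_areas(
    surface: ScoreSurface,
    quantile_threshold: float = 0.95,
    merge_radius_km: float = 3.0,
) -> list[SourceArea]:
    """Cluster top-quantile cells into ranked candidate source areas.

    Cells with score >= the given quantile of valid scores are clustered by
    8-connectivity; clusters whose peak cells lie within ``merge_radius_km``
    of each other are merged.  Areas are ranked by descending peak score; the
    rank-1 area is the most likely area of origin.  Peak ties break by
    (row, col) lexicographic order.
    """
    if not (0 <= quantile_threshold <= 1):
        raise ValidationError("quantile_threshold must be in [0, 1]")
    if not surface.mask.any():
        return []
    valid_scores = surface.scores[surface.mask]
    thr = float(np.quantile(valid_scores, quantile_threshold))
    hot = surface.mask & (surface.scores >= thr)
    labels, n_lab = ndimage.label(hot, structure=_EIGHT_CONN)
    if n_lab == 0:
        return []

    clusters: list[dict] = []
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == lab)
        cells = list(zip(rows.tolist(), cols.tolist()))
        scores = surface.scores[rows, cols]
        best = max(range(len(cells)), key=lambda i: (scores[i], (-cells[i][0], -cells[i][1])))
        clusters.append({"cells": cells, "peak": cells[best], "peak_score": float(scores[best])})

    # merge clusters whose peaks are within merge_radius_km (transitively)
    k = len(clusters)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            pi, pj = clusters[i]["peak"], clusters[j]["peak"]
            loni, lati = surface.grid.cell_center(*pi)
            lonj, latj = surface.grid.cell_center(*pj)
            if haversine_distance(loni, lati, lonj, latj) <= merge_radius_km:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    merged: dict[int, dict] = {}
    for i, c in enumerate(clusters):
        root = find(i)
        if root not in merged:
            merged[root] = {"cells": [], "peak": c["peak"], "peak_score": c["peak_score"]}
        m = merged[root]
        m["cells"].extend(c["cells"])
        if (c["peak_score"], (-c["peak"][0], -c["peak"][1])) > (
            m["peak_score"], (-m["peak"][0], -m["peak"][1])
        ):
            m["peak"], m["peak_score"] = c["peak"], c["peak_score"]

    ordered = sorted(merged.values(), key=lambda m: (-m["peak_score"], m["peak"]))
    areas = []
    for rank, m in enumerate(ordered, start=1):
        lon, lat = surface.grid.cell_center(*m["peak"])
        areas.append(
            SourceArea(
                rank=rank, peak_lon=lon, peak_lat=lat,
                peak_score=m["peak_score"],
                member_cells=sorted(m["cells"]),
            )
        )
    return areas


# ---------------------------------------------------------------------------
# model / results

class GeographicProfile:
    """Dragnet geographic-profile model over a set of occurrence points.

    Parameters
    ----------
    occurrences
        Monitoring records; by default only infested sites enter the profile
        (the pattern whose origin is sought).
    grid
        Evaluation raster.  If omitted, a grid is built from the occurrence
        bounding box with ``cell_size`` and ``margin``.
    params
        Kernel settings (:class:`DragnetParams`).
    use_all_sites
        Score uninfested sites too (off by default).
    """

    def __init__(
        self,
        occurrences: Iterable[OccurrenceRecord],
        grid: GridSpec | None = None,
        params: DragnetParams | None = None,
        cell_size: float = 0.005,
        margin: float = 0.05,
        use_all_sites: bool = False,
    ):
        occurrences = list(occurrences)
        if not use_all_sites:
            occurrences = [o for o in occurrences if o.infested]
        if not occurrences:
            raise ValidationError("no (infested) occurrences to profile")
        ids = [o.site_id for o in occurrences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate site_id(s): {dupes}")
        self.occurrences = occurrences
        self.params = params or DragnetParams()
        if grid is None:
            lons, lats = _occurrence_arrays(occurrences)
            grid = GridSpec.from_points(lons, lats, cell_size=cell_size, margin=margin)
        self.grid = grid

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "GeographicProfile":
        """Build from a DataFrame with columns site_id, longitude, latitude,
        elevation_m, site_type, year, infested."""
        records = [
            OccurrenceRecord(
                site_id=str(row["site_id"]),
                longitude=float(row["longitude"]),
                latitude=float(row["latitude"]),
                elevation=float(row.get("elevation_m", row.get("elevation", 0.0))),
                site_type=str(row.get("site_type", "orchard")),
                year=int(row.get("year", 2019)),
                infested=bool(row.get("infested", True)),
            )
            for _, row in df.iterrows()
        ]
        return cls(records, **kwargs)

    def fit(
        self,
        bootstrap: BootstrapParams | bool | None = True,
        seed: int | None = None,
    ) -> "GeographicProfileResults":
        """Compute the profile surface.

        ``bootstrap=True`` (default) uses the default 30-replicate 25–75 %
        bagging scheme; pass a :class:`BootstrapParams` to customise, or
        ``False``/``None`` for a single deterministic run.
        """
        if bootstrap is True:
            boot = BootstrapParams(seed=0 if seed is None else seed)
        elif isinstance(bootstrap, BootstrapParams):
            boot = bootstrap if seed is None else replace(bootstrap, seed=seed)
        else:
            boot = None
        if boot is None:
            surface = dragnet_score(self.occurrences, self.grid, self.params).rescaled()
        else:
            surface = bootstrap_profile(self.occurrences, self.grid, self.params, boot)
        return GeographicProfileResults(self, surface, boot)


class GeographicProfileResults:
    """Fitted geographic profile: score surface plus extraction helpers."""

    def __init__(
        self,
        model: GeographicProfile,
        surface: ScoreSurface,
        bootstrap: BootstrapParams | None,
    ):
        self.model = model
        self.surface = surface
        self.bootstrap = bootstrap

    def apply_elevation_mask(
        self, dem: ElevationGrid, max_elevation: float = 600.0
    ) -> "GeographicProfileResults":
        masked = apply_elevation_mask(self.surface, dem, max_elevation)
        return GeographicProfileResults(self.model, masked, self.bootstrap)

    def source_areas(
        self, quantile_threshold: float = 0.95, merge_radius_km: float = 3.0
    ) -> list[SourceArea]:
        return extract_source_areas(self.surface, quantile_threshold, merge_radius_km)

    def peak(self) -> tuple[float, float]:
        """(lon, lat) of the highest-scoring valid cell."""
        r, c = self.surface.argmax_cell()
        return self.model.grid.cell_center(r, c)

    def summary(self, quantile_threshold: float = 0.95) -> str:
        m = self.model
        s = self.surface
        lines = [
            "Dragnet geographic profile",
            "=" * 44,
            f"occurrences:        {len(m.occurrences)}",
            f"grid:               {m.grid.n_rows} x {m.grid.n_cols} cells, "
            f"{m.grid.cell_size:g} deg",
            f"decay coefficient:  {m.params.decay_coefficient:g} "
            f"(normalised by {m.params.normalize_by})",
            f"provenance:         {s.provenance}",
            f"valid cells:        {s.n_valid} / {s.scores.size}",
        ]
        if self.bootstrap is not None:
            b = self.bootstrap
            lines.append(
                f"bootstrap:          {b.n_replicates} replicates, "
                f"fractions [{b.fraction_low:g}, {b.fraction_high:g}], seed {b.seed}"
            )
        areas = self.source_areas(quantile_threshold)
        lines.append(f"candidate source areas (q={quantile_threshold:g}): {len(areas)}")
        for a in areas:
            lines.append(
                f"  rank {a.rank}: peak ({a.peak_lon:.4f}, {a.peak_lat:.4f}) "
                f"score {a.peak_score:.4f}, {a.n_cells} cells"
            )
        return "\n".join(lines)

    def plot(self, ax=None, cmap: str = "viridis"):
        """Render the score surface (masked cells blank); returns the Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.model.grid
        data = np.ma.masked_where(~self.surface.mask, self.surface.scores)
        im = ax.imshow(
            data,
            extent=(g.min_lon, g.max_lon, g.min_lat, g.max_lat),
            origin="upper",
            cmap=cmap,
            aspect="auto",
        )
        ax.scatter(
            [o.longitude for o in self.model.occurrences],
            [o.latitude for o in self.model.occurrences],
            s=12, c="red", marker="o", edgecolors="white", linewidths=0.4,
        )
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        ax.figure.colorbar(im, ax=ax, label="profile score")
        return ax
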