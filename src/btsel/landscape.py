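"""Synthetic raster landscapes and the distance surfaces behind the risk traits.

The landscape is a pair of co-registered categorical grids — landcover
(forest / open) and roads (none / primary / secondary) — plus a set of
hunter access points.  The three risk-taking traits are measured against
Euclidean distance surfaces computed from these grids: distance to open
landcover, distance to edge landcover (forest cells adjacent to open or
road cells), and distance to the nearest hunter access point.

Grid convention follows ESRI ASCII rasters: row 0 is the northern edge,
``origin`` is the planar coordinate of the lower-left corner, and cells
are square with side ``resolution`` metres.  Points are assigned to cells
by half-open intervals ``[x, x + resolution)``.  All distances are planar
centre-to-centre metres; no geodesic correction is applied (study-area
scale makes the planar error negligible).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

FOREST = 0
OPEN = 1

ROAD_NONE = 0
ROAD_PRIMARY = 1
ROAD_SECONDARY = 2

_NODATA = -9999


class ConfigurationError(ValueError):
    """Raised when a landscape specification cannot be realised."""


@dataclass
class Landscape:
    """Co-registered cover/roads grids plus hunter access points.

    Parameters
    ----------
    cover : ndarray of int
        ``FOREST`` (0) or ``OPEN`` (1), shape (nrows, ncols).
    roads : ndarray of int
        ``ROAD_NONE`` (0), ``ROAD_PRIMARY`` (1) or ``ROAD_SECONDARY`` (2),
        same shape as ``cover``.
    access_points : ndarray, shape (k, 2)
        Planar (x, y) coordinates in metres of hunter access points.
    origin : (float, float)
        Planar coordinate of the lower-left grid corner.
    resolution : float
        Metres per cell side (default 30 m, the cropland-data-layer grain).
    """

    cover: np.ndarray
    roads: np.ndarray
    access_points: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    resolution: float = 30.0

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover, dtype=np.int8)
        self.roads = np.asarray(self.roads, dtype=np.int8)
        self.access_points = np.asarray(self.access_points, dtype=float).reshape(-1, 2)
        if self.cover.shape != self.roads.shape:
            raise ValueError("cover and roads grids must share shape")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        x0, y0 = self.origin
        xmax = x0 + self.ncols * self.resolution
        ymax = y0 + self.nrows * self.resolution
        for x, y in self.access_points:
            if not (x0 <= x < xmax and y0 <= y < ymax):
                raise ValueError(f"access point ({x}, {y}) outside grid bounding box")

    @property
    def nrows(self) -> int:
        return self.cover.shape[0]

    @property
    def ncols(self) -> int:
        return self.cover.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cover.shape

    def cell_centre(self, row, col):
        """Planar (x, y) of cell centres; accepts arrays."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.resolution
        y = y0 + (self.nrows - np.asarray(row) - 0.5) * self.resolution
        return x, y

    def centre_grids(self):
        """(X, Y) arrays of all cell-centre coordinates, shape (nrows, ncols)."""
        rows, cols = np.meshgrid(
            np.arange(self.nrows), np.arange(self.ncols), indexing="ij"
        )
        return self.cell_centre(rows, cols)

    def point_to_cell(self, x, y):
        """Map planar points to (row, col); raises if any point falls outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.resolution).astype(int)
        row = self.nrows - 1 - np.floor((y - y0) / self.resolution).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            i = int(np.argmax(np.atleast_1d(bad)))
            bx = float(np.atleast_1d(x)[i])
            by = float(np.atleast_1d(y)[i])
            raise ValueError(f"point index {i} at ({bx:.1f}, {by:.1f}) outside raster extent")
        return row, col


@dataclass
class DistanceSurfaces:
    """Per-cell distances (metres) to open cover, edge cover and access points."""

    dist_open: np.ndarray
    dist_edge: np.ndarray
    dist_access: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "dist_open": self.dist_open,
            "dist_edge": self.dist_edge,
            "dist_access": self.dist_access,
        }


@dataclass
class LandscapeSpec:
    """Recipe for :func:`generate_landscape`.

    ``patch_area_ha_median``/``patch_area_ha_sigma`` parameterise a
    lognormal open-patch size distribution (hectares); openings are grown
    as random ellipses until ``open_fraction`` of cells (within +-20%) is
    open.  Primary roads are full-length transects, secondary roads
    shorter segments; access points sit on primary-road cells.
    """

    shape: tuple[int, int] = (120, 120)
    open_fraction: float = 0.12
    patch_area_ha_median: float = 2.0
    patch_area_ha_sigma: float = 1.0
    n_primary_roads: int = 2
    n_secondary_roads: int = 4
    n_access_points: int = 6
    resolution: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    seed: int = 0


def georgia_landscape_spec(seed: int = 0) -> LandscapeSpec:
    """Georgia-style site: more open area, large fields (>10 ha) present."""
    return LandscapeSpec(
        open_fraction=0.15,
        patch_area_ha_median=4.0,
        patch_area_ha_sigma=1.2,
        seed=seed,
    )


def south_carolina_landscape_spec(seed: int = 0) -> LandscapeSpec:
    """South-Carolina-style site: scarce openings, small (<2 ha) food plots."""
    return LandscapeSpec(
        open_fraction=0.05,
        patch_area_ha_median=0.8,
        patch_area_ha_sigma=0.5,
        seed=seed,
    )


def _ellipse_mask(shape, centre, n_cells, rng):
    """Boolean mask of a randomly oriented ellipse of ~n_cells cells."""
    nrows, ncols = shape
    aspect = rng.uniform(0.5, 1.0)
    # pi * a * b = n_cells with b = aspect * a
    a = max(np.sqrt(n_cells / (np.pi * aspect)), 0.5)
    b = max(aspect * a, 0.5)
    theta = rng.uniform(0, np.pi)
    r0, c0 = centre
    rr, cc = np.meshgrid(np.arange(nrows) - r0, np.arange(ncols) - c0, indexing="ij")
    u = rr * np.cos(theta) + cc * np.sin(theta)
    v = -rr * np.sin(theta) + cc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Generate a synthetic landscape; deterministic for a fixed seed.

    Raises
    ------
    ConfigurationError
        If ``open_fraction`` is not in [0, 1], the grid is too small, or
        the requested road/access layout cannot be placed.
    """
    nrows, ncols = spec.shape
    if nrows < 10 or ncols < 10:
        raise ConfigurationError("grid must be at least 10x10")
    if not 0.0 <= spec.open_fraction <= 1.0:
        raise ConfigurationError("open_fraction must be in [0, 1]")
    if spec.n_primary_roads > nrows + ncols:
        raise ConfigurationError("more primary roads requested than grid transects")
    if spec.n_access_points > 0 and spec.n_primary_roads == 0:
        raise ConfigurationError("access points require at least one primary road")

    rng = np.random.default_rng(spec.seed)
    cover = np.full(spec.shape, FOREST, dtype=np.int8)
    n_cells = nrows * ncols
    target = spec.open_fraction * n_cells
    cells_per_ha = 10_000.0 / spec.resolution**2

    attempts = 0
    while cover.sum() < target and attempts < 10_000:
        attempts += 1
        area_ha = spec.patch_area_ha_median * np.exp(
            spec.patch_area_ha_sigma * rng.standard_normal()
        )
        patch_cells = max(1.0, area_ha * cells_per_ha)
        # cap the patch so we never overshoot the +20% band
        open_now = int((cover == OPEN).sum())
        cap = max(1.0, np.floor(1.2 * target) - open_now)
        patch_cells = min(patch_cells, cap)
        centre = (rng.integers(0, nrows), rng.integers(0, ncols))
        mask = _ellipse_mask(spec.shape, centre, patch_cells, rng)
        new = mask & (cover == FOREST)
        if new.sum() > cap:
            # trim surplus cells from this patch deterministically
            idx = np.flatnonzero(new.ravel())
            drop = rng.choice(idx, size=int(new.sum() - cap), replace=False)
            new.ravel()[drop] = False
        cover[new] = OPEN

    roads = np.full(spec.shape, ROAD_NONE, dtype=np.int8)
    transects = [("row", r) for r in range(nrows)] + [("col", c) for c in range(ncols)]
    order = rng.permutation(len(transects))
    for k in range(spec.n_primary_roads):
        kind, i = transects[order[k]]
        if kind == "row":
            roads[i, :] = ROAD_PRIMARY
        else:
            roads[:, i] = ROAD_PRIMARY
    for _ in range(spec.n_secondary_roads):
        if rng.random() < 0.5:
            r = int(rng.integers(0, nrows))
            length = int(rng.uniform(0.2, 0.4) * ncols)
            c0 = int(rng.integers(0, max(1, ncols - length)))
            sel = roads[r, c0 : c0 + length]
            sel[sel == ROAD_NONE] = ROAD_SECONDARY
        else:
            c = int(rng.integers(0, ncols))
            length = int(rng.uniform(0.2, 0.4) * nrows)
            r0 = int(rng.integers(0, max(1, nrows - length)))
            sel = roads[r0 : r0 + length, c]
            sel[sel == ROAD_NONE] = ROAD_SECONDARY

    primary_cells = np.argwhere(roads == ROAD_PRIMARY)
    access = np.empty((0, 2))
    if spec.n_access_points > 0:
        if len(primary_cells) == 0:
            raise ConfigurationError("no primary-road cells available for access points")
        pick = rng.choice(
            len(primary_cells),
            size=min(spec.n_access_points, len(primary_cells)),
            replace=False,
        )
        land_tmp = Landscape(cover, roads, np.empty((0, 2)), spec.origin, spec.resolution)
        xs, ys = land_tmp.cell_centre(primary_cells[pick, 0], primary_cells[pick, 1])
        access = np.column_stack([xs, ys])

    return Landscape(cover, roads, access, spec.origin, spec.resolution)


def derive_edge(
    land: Landscape, neighbourhood: int = 8, roads_as_open: bool = True
) -> np.ndarray:
    """Boolean grid of edge cells.

    A cell is edge iff it is forest (and not itself a road corridor) and
    at least one neighbour is open landcover or — by default — a road cell
    of either class.  ``neighbourhood`` is 8 (diagonals count, default) or 4.
    """
    if neighbourhood not in (4, 8):
        raise ValueError("neighbourhood must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if neighbourhood == 8 else 1)
    openlike = land.cover == OPEN
    if roads_as_open:
        openlike = openlike | (land.roads != ROAD_NONE)
    forest = (land.cover == FOREST) & ~openlike
    has_openlike_neighbour = ndimage.binary_dilation(openlike, structure=structure)
    return forest & has_openlike_neighbour


def distance_surface(feature_cells: np.ndarray, land: Landscape) -> np.ndarray:
    """Euclidean distance (m) from every cell centre to the nearest feature-cell centre."""
    feature_cells = np.asarray(feature_cells, dtype=bool)
    if feature_cells.shape != land.shape:
        raise ValueError("feature grid shape mismatch")
    if not feature_cells.any():
        raise ValueError("empty feature set: distance surface undefined")
    return ndimage.distance_transform_edt(~feature_cells, sampling=land.resolution)


def distance_to_points(points: np.ndarray, land: Landscape) -> np.ndarray:
    """Per-cell Euclidean distance (m) to the nearest of ``points`` (x, y)."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise ValueError("empty point list: distance surface undefined")
    X, Y = land.centre_grids()
    tree = cKDTree(points)
    d, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
    return d.reshape(land.shape)


def compute_surfaces(land: Landscape, neighbourhood: int = 8) -> DistanceSurfaces:
    """Derive the three distance surfaces used by the risk traits."""
    return DistanceSurfaces(
        dist_open=distance_surface(land.cover == OPEN, land),
        dist_edge=distance_surface(derive_edge(land, neighbourhood), land),
        dist_access=distance_to_points(land.access_points, land),
    )


def sample_surface(surface: np.ndarray, land: Landscape, x, y) -> np.ndarray:
    """Value of a precomputed surface at planar points by nearest-cell lookup."""
    row, col = land.point_to_cell(x, y)
    return np.asarray(surface)[row, col]


def mean_open_patch_area_ha(land: Landscape) -> float:
    """Mean area (ha) of connected open patches (8-connectivity)."""
    labels, n = ndimage.label(land.cover == OPEN, structure=np.ones((3, 3)))
    if n == 0:
        return 0.0
    sizes = ndimage.sum_labels(np.ones(land.shape), labels, index=np.arange(1, n + 1))
    return float(np.mean(sizes) * land.resolution**2 / 10_000.0)


# ---------------------------------------------------------------------------
# ESRI ASCII grid and access-point CSV round trips


def write_ascii_grid(path, grid, origin=(0.0, 0.0), resolution=30.0) -> None:
    grid = np.asarray(grid)
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {origin[0]:.6f}\n"
        f"yllcorner {origin[1]:.6f}\n"
        f"cellsize {resolution:.6f}\n"
        f"NODATA_value {_NODATA}\n"
    )
    fmt = "%d" if np.issubdtype(grid.dtype, np.integer) else "%.6f"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (grid, origin, resolution)."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    origin = (header["xllcorner"], header["yllcorner"])
    return grid, origin, header["cellsize"]


def write_access_csv(path, access_points) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "class"])
        for i, (x, y) in enumerate(np.asarray(access_points).reshape(-1, 2)):
            writer.writerow([i, f"{x:.3f}", f"{y:.3f}", "access"])


def read_access_csv(path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return np.array([[float(r["x"]), float(r["y"])] for r in rows]).reshape(-1, 2)


def save_landscape(land: Landscape, outdir) -> list[Path]:
    """Persist cover/roads as ESRI ASCII and access points as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in [("cover", land.cover), ("roads", land.roads)]:
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, grid, land.origin, land.resolution)
        paths.append(p)
    p = outdir / "access_points.csv"
    write_access_csv(p, land.access_points)
    paths.append(p)
    return paths


def load_landscape(indir) -> Landscape:
    indir = Path(indir)
    cover, origin, res = read_ascii_grid(indir / "cover.asc")
    roads, _, _ = read_ascii_grid(indir / "roads.asc")
    access = read_access_csv(indir / "access_points.csv")
    return Landscape(cover.astype(np.int8), roads.astype(np.int8), access, origin, res)
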