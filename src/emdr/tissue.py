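"""Tissue geometry: lattice grids, masks, point patterns and peristromal niches.

The simulation substrate is a square lattice in which each site is one average
tumor-cell diameter (15 um) across and carries exactly one state code: empty,
tumor cell, stroma (active or inactivated), or excluded (micronecrotic areas
that take part in neither growth nor statistics).  Histology arrives either as
an integer-coded label image (pre-segmented mask) or as a point table of cell
centers and stroma-pixel centers; both map onto :class:`TissueGrid` /
:class:`PointPattern`.

Coordinate convention: 0-based lattice indices ``state[row, col]``; the
physical center of site ``(row, col)`` is ``((col + 0.5) * cell_size,
(row + 0.5) * cell_size)`` in um, on the half-open window ``[0, side)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

# Lattice state codes.  The on-disk palette is {0 empty, 1 tumor, 2 stroma,
# 3 excluded}; STROMA_INACTIVE (4) marks stroma whose paracrine protection has
# been switched off in silico -- it still occupies space.
EMPTY = 0
TUMOR = 1
STROMA = 2
EXCLUDED = 3
STROMA_INACTIVE = 4

_VALID_CODES = frozenset({EMPTY, TUMOR, STROMA, EXCLUDED, STROMA_INACTIVE})
DEFAULT_CELL_SIZE = 15.0  # um, average tumor cell diameter


@dataclass
class TissueGrid:
    """Integer lattice of tissue states with a physical scale.

    Parameters
    ----------
    state
        2-D ``int8`` array, ``state[row, col]``, codes in
        ``{EMPTY, TUMOR, STROMA, EXCLUDED, STROMA_INACTIVE}``.
    cell_size
        Physical side of one lattice site in um (default 15, one tumor cell
        diameter).
    meta
        Free-form provenance (e.g. generator parameters, achieved metrics).
    """

    state: np.ndarray
    cell_size: float = DEFAULT_CELL_SIZE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state)
        if self.state.ndim != 2 or self.state.size == 0:
            raise ValueError("state must be a non-empty 2-D array")
        codes = np.unique(self.state)
        unknown = set(codes.tolist()) - _VALID_CODES
        if unknown:
            raise ValueError(f"unknown state codes: {sorted(unknown)}")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.state = self.state.astype(np.int8, copy=False)

    # -- basic geometry -------------------------------------------------
    @property
    def height(self) -> int:
        return self.state.shape[0]

    @property
    def width(self) -> int:
        return self.state.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.state.shape

    @property
    def side_um(self) -> tuple[float, float]:
        """Physical extent (width_um, height_um) of the window."""
        return (self.width * self.cell_size, self.height * self.cell_size)

    # -- masks ----------------------------------------------------------
    def stroma_mask(self, active_only: bool = False) -> np.ndarray:
        m = self.state == STROMA
        if not active_only:
            m |= self.state == STROMA_INACTIVE
        return m

    def free_mask(self) -> np.ndarray:
        """Sites that can host a tumor cell (currently empty)."""
        return self.state == EMPTY

    def tumor_capable_mask(self) -> np.ndarray:
        """Sites that may ever host a tumor cell (empty or tumor)."""
        return (self.state == EMPTY) | (self.state == TUMOR)

    def site_centers(self, mask: np.ndarray) -> np.ndarray:
        """Physical (x_um, y_um) centers of sites selected by a boolean mask."""
        rows, cols = np.nonzero(mask)
        return np.column_stack(((cols + 0.5) * self.cell_size,
                                (rows + 0.5) * self.cell_size))

    def stroma_points(self, active_only: bool = False) -> np.ndarray:
        """Stroma pixel centers in um, for spatial statistics."""
        return self.site_centers(self.stroma_mask(active_only=active_only))

    def copy(self) -> "TissueGrid":
        return TissueGrid(self.state.copy(), self.cell_size, dict(self.meta))


@dataclass
class PointPattern:
    """Marked point set: stroma pixel centers plus tumor cells with a binary marker.

    ``marker`` is boolean, True = marker-positive (e.g. BrdU+).  All
    coordinates are um inside the half-open rectangular ``window``
    ``(width_um, height_um)``.
    """

    window: tuple[float, float]
    stroma: np.ndarray      # (S, 2) float
    cells: np.ndarray       # (C, 2) float
    marker: np.ndarray      # (C,) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stroma = np.atleast_2d(np.asarray(self.stroma, dtype=float))
        if self.stroma.size == 0:
            self.stroma = np.empty((0, 2))
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=float))
        if self.cells.size == 0:
            self.cells = np.empty((0, 2))
        self.marker = np.asarray(self.marker, dtype=bool).ravel()
        if len(self.marker) != len(self.cells):
            raise ValueError("marker length must match number of cells")
        w, h = self.window
        for pts, name in ((self.stroma, "stroma"), (self.cells, "cells")):
            if len(pts) and (
                (pts[:, 0] < 0).any() or (pts[:, 0] >= w).any()
                or (pts[:, 1] < 0).any() or (pts[:, 1] >= h).any()
            ):
                raise ValueError(f"{name} coordinates fall outside the window")

    @property
    def n_positive(self) -> int:
        return int(self.marker.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.marker).sum())

    # -- CSV round trip (header: x_um,y_um,type,marker) ------------------
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["x_um", "y_um", "type", "marker"])
            for x, y in self.stroma:
                wr.writerow([f"{x:.6g}", f"{y:.6g}", "stroma", "NA"])
            for (x, y), m in zip(self.cells, self.marker):
                wr.writerow([f"{x:.6g}", f"{y:.6g}", "cell",
                             "pos" if m else "neg"])

    @classmethod
    def from_csv(cls, path: str | Path,
                 window: tuple[float, float] | None = None) -> "PointPattern":
        stroma, cells, marker = [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                x, y = float(row["x_um"]), float(row["y_um"])
                kind = row["type"].strip().lower()
                if kind == "stroma":
                    stroma.append((x, y))
                elif kind == "cell":
                    m = row["marker"].strip().lower()
                    if m not in ("pos", "neg"):
                        raise ValueError(f"cell marker must be pos/neg, got {m!r}")
                    cells.append((x, y))
                    marker.append(m == "pos")
                else:
                    raise ValueError(f"unknown point type {kind!r}")
        pts = np.array(stroma + cells) if (stroma or cells) else np.empty((0, 2))
        if window is None:
            hi = pts.max(axis=0) if len(pts) else np.array([0.0, 0.0])
            window = (float(hi[0]) + 1.0, float(hi[1]) + 1.0)
        return cls(window, np.array(stroma), np.array(cells),
                   np.array(marker, dtype=bool))


@dataclass
class NicheMap:
    """Boolean peristromal-niche membership per lattice site.

    A site is in the niche when it is non-stroma and lies within
    ``distance_cells`` lattice cells (Chebyshev by default) of at least one
    *active* stroma site.  Inactivated stroma generates no niche.
    """

    inside: np.ndarray
    distance_cells: int
    metric: str = "chebyshev"

    @property
    def n_sites(self) -> int:
        return int(self.inside.sum())


# ---------------------------------------------------------------------------
# Mask IO
# ---------------------------------------------------------------------------

_IO_PALETTE = frozenset({EMPTY, TUMOR, STROMA, EXCLUDED, STROMA_INACTIVE})


def load_mask(path: str | Path, cell_size: float = DEFAULT_CELL_SIZE) -> TissueGrid:
    """Load a label image (PNG/TIFF) or point-table CSV as a :class:`TissueGrid`.

    Label palette: 0 empty, 1 tumor, 2 stroma, 3 excluded (4 = inactivated
    stroma is accepted when written by this package).  CSV point tables
    (``x_um,y_um,type,marker``) are rasterized: each point occupies the
    lattice site containing it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _grid_from_point_table(path, cell_size)
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"expected single-channel label image, got shape {arr.shape}")
    unknown = set(np.unique(arr).tolist()) - _IO_PALETTE
    if unknown:
        raise ValueError(f"unknown label codes in {path.name}: {sorted(unknown)}")
    return TissueGrid(arr.astype(np.int8), cell_size)


def write_mask(grid: TissueGrid, path: str | Path) -> None:
    """Write a grid as a single-channel label image (PNG or TIFF)."""
    path = Path(path)
    arr = grid.state.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr, mode="L").save(path)


def _grid_from_point_table(path: Path, cell_size: float) -> TissueGrid:
    pattern = PointPattern.from_csv(path)
    w_um, h_um = pattern.window
    width = max(1, int(np.ceil(w_um / cell_size)))
    height = max(1, int(np.ceil(h_um / cell_size)))
    state = np.zeros((height, width), dtype=np.int8)
    for x, y in pattern.stroma:
        state[int(y // cell_size), int(x // cell_size)] = STROMA
    for x, y in pattern.cells:
        r, c = int(y // cell_size), int(x // cell_size)
        if state[r, c] == EMPTY:
            state[r, c] = TUMOR
    return TissueGrid(state, cell_size)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pixelate_stroma(mask: np.ndarray, pixel_size: float,
                    tile: float = DEFAULT_CELL_SIZE,
                    threshold: float = 0.5) -> np.ndarray:
    """Tile a binary stroma raster into ``tile`` um squares; return centers.

    A tile becomes a stroma pixel when the fraction of raster pixels whose
    centers fall inside it that are stroma is at least ``threshold``.  Only
    tiles fully inside the raster window are considered.  Returns an (N, 2)
    array of tile-center coordinates in um.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2-D array")
    if tile <= 0 or pixel_size <= 0:
        raise ValueError("tile and pixel_size must be positive")
    h_um = mask.shape[0] * pixel_size
    w_um = mask.shape[1] * pixel_size
    n_ty = int(np.floor(h_um / tile + 1e-9))
    n_tx = int(np.floor(w_um / tile + 1e-9))
    if n_ty == 0 or n_tx == 0:
        raise ValueError("tile larger than the raster window")
    # raster pixel centers in um
    px_x = (np.arange(mask.shape[1]) + 0.5) * pixel_size
    px_y = (np.arange(mask.shape[0]) + 0.5) * pixel_size
    tile_ix = np.floor(px_x / tile).astype(int)
    tile_iy = np.floor(px_y / tile).astype(int)
    centers = []
    for ty in range(n_ty):
        rows = np.nonzero(tile_iy == ty)[0]
        if rows.size == 0:
            continue
        sub = mask[rows]
        for tx in range(n_tx):
            cols = np.nonzero(tile_ix == tx)[0]
            if cols.size == 0:
                continue
            cov = sub[:, cols].mean()
            if cov >= threshold:
                centers.append(((tx + 0.5) * tile, (ty + 0.5) * tile))
    return np.array(centers) if centers else np.empty((0, 2))


def compute_niche_map(grid: TissueGrid, distance_cells: int = 3,
                      metric: str = "chebyshev") -> NicheMap:
    """Mark non-stroma sites within ``distance_cells`` of active stroma.

    ``metric`` is the lattice distance: "chebyshev" (a (2d+1)^2 block around
    each stroma site) or "euclidean".  Inactivated stroma confers no niche;
    ``distance_cells == 0`` yields an empty niche.
    """
    if distance_cells < 0:
        raise ValueError("distance_cells must be non-negative")
    if metric not in ("chebyshev", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    active = grid.state == STROMA
    inside = np.zeros(grid.shape, dtype=bool)
    if distance_cells == 0 or not active.any():
        return NicheMap(inside, distance_cells, metric)
    if metric == "chebyshev":
        dist = ndimage.distance_transform_cdt(~active, metric="chessboard")
    else:
        dist = ndimage.distance_transform_edt(~active)
    inside = (dist <= distance_cells) & ~grid.stroma_mask()
    return NicheMap(inside, distance_cells, metric)


def extract_quadrant(grid: TissueGrid, origin: tuple[float, float],
                     side: float = 1500.0) -> TissueGrid:
    """Extract a square quadrant (default 1500 um, i.e. 100 x 100 sites).

    ``origin`` is the (x_um, y_um) lower corner; it must align to the lattice
    and the quadrant must lie fully inside the source grid.
    """
    cs = grid.cell_size
    c0, r0 = origin[0] / cs, origin[1] / cs
    n = side / cs
    for v, name in ((c0, "origin x"), (r0, "origin y"), (n, "side")):
        if abs(v - round(v)) > 1e-9:
            raise ValueError(f"{name} must be a multiple of cell_size")
    c0, r0, n = int(round(c0)), int(round(r0)), int(round(n))
    if n <= 0:
        raise ValueError("side must be positive")
    if r0 < 0 or c0 < 0 or r0 + n > grid.height or c0 + n > grid.width:
        raise ValueError("quadrant extends outside the source grid")
    return TissueGrid(grid.state[r0:r0 + n, c0:c0 + n].copy(), cs)


def stroma_metrics(grid: TissueGrid) -> tuple[float, float]:
    """Return (abundance, dispersal) of the stroma in a grid.

    Abundance is the stroma fraction of non-excluded sites.  Dispersal is the
    boundary fraction of stroma: the fraction of stroma sites with at least
    one non-stroma neighbor in their 8-neighborhood (out-of-grid neighbors do
    not count as non-stroma).  A grid with no stroma returns (0, 0).
    """
    stroma = grid.stroma_mask()
    n_stroma = int(stroma.sum())
    n_valid = int((grid.state != EXCLUDED).sum())
    abundance = n_stroma / n_valid if n_valid else 0.0
    if n_stroma == 0:
        return (abundance, 0.0)
    interior = ndimage.binary_erosion(
        stroma, structure=np.ones((3, 3), dtype=bool), border_value=1)
    dispersal = 1.0 - int(interior.sum()) / n_stroma
    return (abundance, dispersal)
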