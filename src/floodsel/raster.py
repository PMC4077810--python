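"""Categorical habitat rasters on a planar metre grid.

The landscape is a regular lattice of square pixels (default 50 m) carrying
one of six habitat class codes.  Pixel ``[i, j]`` covers the half-open square
``[origin_x + j*s, origin_x + (j+1)*s) x [origin_y + i*s, origin_y + (i+1)*s)``
with row 0 at the southern (origin) edge.  All coordinates are planar metres;
no geodesy is attempted.

I/O is the ESRI ASCII grid format (plain text), with the optional boundary
polyline stored as a GeoJSON LineString alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString

#: Habitat class codes, ordered roughly by typical distance to permanent water.
HABITAT_CODES = {
    1: "secondary_floodplain",
    2: "tertiary_floodplain",
    3: "grassland",
    4: "riparian_woodland",
    5: "mopane_woodland",
    6: "mixed_acacia_woodland",
}
HABITAT_NAMES = {v: k for k, v in HABITAT_CODES.items()}

#: Classes whose herbaceous layer is governed by the flood pulse.
SEASONALLY_FLOODED = (1, 2)

NODATA = -9999


@dataclass
class HabitatRaster:
    """Categorical habitat grid with optional water-distance and boundary layers.

    Parameters
    ----------
    classes
        Integer array of shape ``(n_rows, n_cols)`` holding habitat codes
        (1..6) or ``NODATA``.
    origin_x, origin_y
        South-west corner of the grid in metres.
    pixel_size
        Side length of a square pixel in metres.
    dist_water
        Optional per-cell distance (m) to the permanent water channel.
    boundary
        Optional polyline (``(n, 2)`` vertex array, metres) marking a hard
        edge such as a veterinary fence.
    inundated
        Optional boolean mask of currently flooded cells.
    """

    classes: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 50.0
    dist_water: np.ndarray | None = None
    boundary: np.ndarray | None = None
    inundated: np.ndarray | None = None
    nodata: int = NODATA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.classes.ndim != 2:
            raise ValueError("classes must be a 2-D array")
        valid = np.isin(self.classes, list(HABITAT_CODES) + [self.nodata])
        if not valid.all():
            bad = np.unique(self.classes[~valid])
            raise ValueError(f"invalid class codes present: {bad}")

    @property
    def n_rows(self) -> int:
        return self.classes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.classes.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in metres."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y + self.n_rows * self.pixel_size,
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-centre coordinates, shape (n_rows, n_cols)."""
        s = self.pixel_size
        x = self.origin_x + (np.arange(self.n_cols) + 0.5) * s
        y = self.origin_y + (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(x, y)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing points (x, y)."""
        j = np.floor((np.asarray(x) - self.origin_x) / self.pixel_size).astype(int)
        i = np.floor((np.asarray(y) - self.origin_y) / self.pixel_size).astype(int)
        return i, j

    def class_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Habitat code under each point; ``nodata`` outside the grid."""
        i, j = self.cell_of(x, y)
        i = np.atleast_1d(i)
        j = np.atleast_1d(j)
        out = np.full(i.shape, self.nodata, dtype=int)
        ok = (i >= 0) & (i < self.n_rows) & (j >= 0) & (j < self.n_cols)
        out[ok] = self.classes[i[ok], j[ok]]
        return out if out.size > 1 else out[0]

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x < xmax and ymin <= y < ymax

    def class_proportions(self, mask: np.ndarray | None = None) -> dict[int, float]:
        """Proportion of (optionally masked) valid cells in each habitat class."""
        cls = self.classes if mask is None else self.classes[mask]
        cls = cls[cls != self.nodata]
        if cls.size == 0:
            raise ValueError("no valid cells in selection")
        codes, counts = np.unique(cls, return_counts=True)
        return {int(c): n / cls.size for c, n in zip(codes, counts)}

    def boundary_line(self) -> LineString | None:
        if self.boundary is None:
            return None
        return LineString(self.boundary)

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, path: str | Path) -> None:
        """Write the class grid as an ESRI ASCII grid (row 0 printed last)."""
        path = Path(path)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin_x}\n"
            f"yllcorner {self.origin_y}\n"
            f"cellsize {self.pixel_size}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            for row in self.classes[::-1]:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
        if self.boundary is not None:
            geo = {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(x), float(y)] for x, y in self.boundary],
                },
                "properties": {"role": "boundary"},
            }
            path.with_suffix(".boundary.geojson").write_text(json.dumps(geo))

    @classmethod
    def read_ascii(cls, path: str | Path) -> "HabitatRaster":
        path = Path(path)
        with path.open() as fh:
            hdr = {}
            pos = fh.tell()
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            grid = np.loadtxt(fh, dtype=int)
        grid = np.atleast_2d(grid)[::-1].copy()
        boundary = None
        bpath = path.with_suffix(".boundary.geojson")
        if bpath.exists():
            geo = json.loads(bpath.read_text())
            boundary = np.asarray(geo["geometry"]["coordinates"], dtype=float)
        return cls(
            classes=grid,
            origin_x=hdr.get("xllcorner", 0.0),
            origin_y=hdr.get("yllcorner", 0.0),
            pixel_size=hdr.get("cellsize", 50.0),
            nodata=int(hdr.get("nodata_value", NODATA)),
            boundary=boundary,
        )
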