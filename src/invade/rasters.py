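"""Aligned environmental raster stacks and ESRI ASCII grid I/O.

The stack is the common currency between the driver regression, the
maximum-entropy SDM and the suitability classifier: a set of named 2-D
layers (bio1..bio19, elev, landcover) sharing one grid, one origin, one
cell size and one nodata mask.  Coordinates are planar map units (km by
convention throughout this package); row 0 is the top of the grid, as in
the ESRI ASCII format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnvStack", "read_ascii_grid", "write_ascii_grid"]

NODATA_DEFAULT = -9999.0


def read_ascii_grid(path: str) -> tuple[np.ndarray, float, float, float, float]:
    """Read an ESRI ASCII grid.

    Returns ``(array, xll, yll, cellsize, nodata)`` with nodata cells set
    to NaN.  Both ``xllcorner`` and ``xllcenter`` headers are accepted
    (center coordinates are shifted back to the corner).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2
    else:
        raise ValueError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2
    else:
        raise ValueError(f"{path}: missing yllcorner/yllcenter")

    body = " ".join(lines[i:])
    values = np.array(body.split(), dtype=float)
    if values.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} values, found {values.size}"
        )
    arr = values.reshape(nrows, ncols)
    arr[arr == nodata] = np.nan
    return arr, xll, yll, cellsize, nodata


def write_ascii_grid(
    path: str,
    arr: np.ndarray,
    xll: float,
    yll: float,
    cellsize: float,
    nodata: float = NODATA_DEFAULT,
) -> None:
    """Write a 2-D array (NaN = nodata) as an ESRI ASCII grid."""
    arr = np.asarray(arr, dtype=float)
    out = np.where(np.isnan(arr), nodata, arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {xll:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


@dataclass
class EnvStack:
    """Named raster layers on one shared grid.

    Parameters
    ----------
    layers
        Mapping layer name -> 2-D float array (NaN marks nodata).
    cell_size
        Cell edge length in map units (km by package convention).
    origin
        ``(xll, yll)`` of the lower-left grid corner in map units.
    categorical
        Names of layers holding class codes rather than continuous values
        (by default ``landcover`` if present).
    """

    layers: dict[str, np.ndarray]
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    categorical: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack requires at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers disagree on shape: {sorted(shapes)}")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}
        if not self.categorical and "landcover" in self.layers:
            self.categorical = {"landcover"}
        # nodata must be congruent across layers: union the masks
        mask = np.zeros(self.shape, dtype=bool)
        for arr in self.layers.values():
            mask |= np.isnan(arr)
        for arr in self.layers.values():
            arr[mask] = np.nan

    # ---- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where any layer is nodata."""
        return np.isnan(next(iter(self.layers.values())))

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.mask

    def cell_area(self) -> float:
        return self.cell_size**2

    def xy_to_rowcol(self, x, y):
        """Map coordinates to (row, col); vectorized, no bounds clipping."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = (self.n_rows - 1) - np.floor(
            (y - self.origin[1]) / self.cell_size
        ).astype(int)
        return row, col

    def rowcol_to_xy(self, row, col):
        """Cell-center coordinates of (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - 1 - row + 0.5) * self.cell_size
        return x, y

    def in_extent(self, x, y) -> np.ndarray:
        row, col = self.xy_to_rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    # ---- sampling -----------------------------------------------------
    def sample(self, x, y, names: list[str] | None = None) -> np.ndarray:
        """Layer values at map coordinates.

        Returns an ``(n_points, n_layers)`` array; points outside the
        extent or on nodata cells yield NaN rows.
        """
        names = names or self.names
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.xy_to_rowcol(x, y)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.full((x.size, len(names)), np.nan)
        for j, name in enumerate(names):
            out[ok, j] = self.layers[name][row[ok], col[ok]]
        return out

    def values_at_cells(self, rows, cols, names: list[str] | None = None) -> np.ndarray:
        names = names or self.names
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    # ---- persistence --------------------------------------------------
    def to_directory(self, directory: str) -> None:
        """Write one ``<layer>.asc`` file per layer."""
        os.makedirs(directory, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(
                os.path.join(directory, f"{name}.asc"),
                arr,
                self.origin[0],
                self.origin[1],
                self.cell_size,
            )

    @classmethod
    def from_directory(cls, directory: str, categorical: set[str] | None = None) -> "EnvStack":
        """Load every ``.asc`` file in a directory as one aligned stack."""
        files = sorted(f for f in os.listdir(directory) if f.endswith(".asc"))
        if not files:
            raise FileNotFoundError(f"no .asc layers in {directory}")
        layers = {}
        geom = None
        for fname in files:
            arr, xll, yll, cs, _ = read_ascii_grid(os.path.join(directory, fname))
            this = (arr.shape, round(xll, 6), round(yll, 6), round(cs, 6))
            if geom is None:
                geom = this
            elif this != geom:
                raise ValueError(f"{fname} is not aligned with the other layers")
            layers[fname[:-4]] = arr
        return cls(
            layers,
            cell_size=geom[3],
            origin=(geom[1], geom[2]),
            categorical=categorical or set(),
        )
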