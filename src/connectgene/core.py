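"""Core spatial containers: rasters, labelled point sets and distance matrices.

The raster model is deliberately minimal: a 2-D float array on a regular
grid with square cells, an origin at the lower-left corner, and NaN as the
in-memory nodata value.  Row 0 is the northernmost row, matching the ESRI
ASCII grid convention used for on-disk exchange.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Raster",
    "PointSet",
    "DistanceMatrix",
    "derive_rng",
    "derive_seed",
]


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed (< 2**31) from a master seed.

    The scheme is a documented, stable function of the master seed and the
    stage name, so a single pipeline seed determines every stochastic step.
    """
    h = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def derive_rng(master_seed: int, stage: str) -> np.random.Generator:
    """A numpy Generator seeded deterministically per (master seed, stage)."""
    return np.random.default_rng(derive_seed(master_seed, stage))


@dataclass
class Raster:
    """A georeferenced regular grid.

    Parameters
    ----------
    values
        2-D float array, row 0 = north.  NaN marks nodata cells.
    cell_size
        Side length of a (square) cell, in CRS units (metres by default).
    xll, yll
        Coordinates of the lower-left corner of the grid.
    """

    values: np.ndarray
    cell_size: float = 1.0
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def cell_center(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (row, col) indices to (x, y) cell-center coordinates."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.xll + (cols + 0.5) * self.cell_size
        y = self.yll + (self.nrows - rows - 0.5) * self.cell_size
        return x, y

    def index_of(self, x: np.ndarray, y: np.ndarray, clip: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices of the containing cells."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.floor((x - self.xll) / self.cell_size).astype(int)
        rows = (self.nrows - 1 - np.floor((y - self.yll) / self.cell_size)).astype(int)
        if clip:
            rows = np.clip(rows, 0, self.nrows - 1)
            cols = np.clip(cols, 0, self.ncols - 1)
        else:
            bad = (rows < 0) | (rows >= self.nrows) | (cols < 0) | (cols >= self.ncols)
            if np.any(bad):
                raise ValueError("coordinates fall outside the raster extent")
        return rows, cols

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Extract cell values at point coordinates (nearest cell)."""
        rows, cols = self.index_of(x, y)
        return self.values[rows, cols]

    def is_aligned(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
        )

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.cell_size, self.xll, self.yll)

    def like(self, values: np.ndarray) -> "Raster":
        """A new raster on this grid with the given values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("values shape does not match raster grid")
        return Raster(values, self.cell_size, self.xll, self.yll)

    # -- I/O (ESRI ASCII grid) -------------------------------------------
    NODATA = -9999.0

    def to_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plain text, row 0 = north)."""
        out = np.where(np.isfinite(self.values), self.values, self.NODATA)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xll!r}\n"
            f"yllcorner {self.yll!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.NODATA!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "Raster":
        with open(path) as fh:
            hdr: dict[str, float] = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        nodata = hdr.get("nodata_value", cls.NODATA)
        values[values == nodata] = np.nan
        r = cls(values, hdr["cellsize"], hdr.get("xllcorner", 0.0), hdr.get("yllcorner", 0.0))
        if r.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
            raise ValueError("ASCII grid body does not match header dimensions")
        return r


@dataclass
class PointSet:
    """Labelled x/y points (occurrences, background, population sites)."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    label: np.ndarray | None = None  # presence 1 / background 0 where used

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise ValueError("ids, x and y must have equal length")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=int)
            if len(self.label) != len(self.x):
                raise ValueError("label length mismatch")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, idx: np.ndarray) -> "PointSet":
        lab = None if self.label is None else self.label[idx]
        return PointSet(self.ids[idx], self.x[idx], self.y[idx], lab)

    @staticmethod
    def concat(parts: Sequence["PointSet"]) -> "PointSet":
        ids = np.concatenate([np.asarray(p.ids, dtype=object) for p in parts])
        x = np.concatenate([p.x for p in parts])
        y = np.concatenate([p.y for p in parts])
        labels = [p.label for p in parts]
        lab = None if any(l is None for l in labels) else np.concatenate(labels)
        return PointSet(ids, x, y, lab)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"id": self.ids, "x": self.x, "y": self.y})
        if self.label is not None:
            df["label"] = self.label
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointSet":
        df = pd.read_csv(path)
        lab = df["label"].to_numpy() if "label" in df.columns else None
        return cls(df["id"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(), lab)


@dataclass
class DistanceMatrix:
    """A labelled symmetric non-negative matrix with zero diagonal.

    ``kind`` records what the distances are: least-cost distance (LCD),
    resistance distance (IBR), straight-line distance (EUCLIDEAN) or
    genetic differentiation (FST).  Disconnected pairs are stored as
    ``numpy.inf`` sentinels.
    """

    labels: np.ndarray
    values: np.ndarray
    kind: str = "LCD"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T], self.values.T[finite & finite.T], rtol=1e-10, atol=1e-10
        ):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values[finite] < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def has_infinite(self) -> bool:
        return bool(np.any(~np.isfinite(self.upper_triangle())))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "FST") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(), df.to_numpy(dtype=float), kind)
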