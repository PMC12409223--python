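"""2D scalar fields on the isocenter-plane U/T grid.

Grids live in the lateral measurement plane at isocenter: U is the
horizontal scanning axis, T the vertical one (beam's-eye view, U increasing
rightward).  ``values[i, j]`` is the sample at the *center* of voxel
``(i, j)``, at position ``(origin[0] + i * spacing, origin[1] + j * spacing)``
in mm — axis 0 is U, axis 1 is T.  Spacing is uniform and identical on both
axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "DoseGrid", "DoseRateGrid", "write_grid_csv", "read_grid_csv"]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a uniform 2D voxel-center grid (mm)."""

    origin: tuple[float, float]  # (U, T) of the center of voxel [0, 0]
    spacing: float               # mm, both axes
    shape: tuple[int, int]       # (nU, nT)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError("grid shape must be at least 1x1")

    @property
    def u_coords(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.shape[0])

    @property
    def t_coords(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.shape[1])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.u_coords, self.t_coords, indexing="ij")

    def index_of(self, u: float, t: float) -> tuple[int, int]:
        """Index of the voxel whose center is nearest to (u, t)."""
        i = int(round((u - self.origin[0]) / self.spacing))
        j = int(round((t - self.origin[1]) / self.spacing))
        if not (0 <= i < self.shape[0] and 0 <= j < self.shape[1]):
            raise IndexError(f"position ({u}, {t}) mm outside grid")
        return i, j

    @staticmethod
    def covering(u_range: tuple[float, float], t_range: tuple[float, float],
                 spacing: float, margin: float = 0.0) -> "GridGeometry":
        """Smallest grid covering the given U/T ranges plus a margin (mm)."""
        u0 = u_range[0] - margin
        t0 = t_range[0] - margin
        nu = int(np.ceil((u_range[1] + margin - u0) / spacing)) + 1
        nt = int(np.ceil((t_range[1] + margin - t0) / spacing)) + 1
        return GridGeometry(origin=(u0, t0), spacing=spacing, shape=(nu, nt))


@dataclass
class DoseGrid:
    """Dose (Gy) at isocenter-plane voxel centers."""

    geometry: GridGeometry
    values: np.ndarray  # Gy, shape == geometry.shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape does not match grid geometry")

    def value_at(self, u: float, t: float) -> float:
        """Dose of the voxel nearest to (u, t) mm."""
        return float(self.values[self.geometry.index_of(u, t)])

    def max(self) -> float:
        return float(np.max(self.values))

    def isodose_mask(self, level: float) -> np.ndarray:
        """Boolean mask of voxels with dose >= level * max."""
        return self.values >= level * self.max()


@dataclass
class DoseRateGrid:
    """PBS-average (or dose-averaged) dose rate (Gy/s) with validity mask.

    Voxels outside ``valid_mask`` carry NaN; ``invalid_reason`` holds a short
    code per voxel ("" where valid): "dose-floor" for voxels under the dose
    floor, "degenerate" where the 5%–95% window collapsed to zero width.
    """

    geometry: GridGeometry
    values: np.ndarray       # Gy/s, NaN where invalid
    valid_mask: np.ndarray   # bool
    invalid_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.invalid_reason is None:
            reason = np.full(self.geometry.shape, "", dtype=object)
            reason[~self.valid_mask] = "invalid"
            self.invalid_reason = reason

    def value_at(self, u: float, t: float) -> float:
        idx = self.geometry.index_of(u, t)
        if not self.valid_mask[idx]:
            raise ValueError(f"voxel at ({u}, {t}) mm is invalid: {self.invalid_reason[idx]}")
        return float(self.values[idx])


def write_grid_csv(grid: DoseGrid | DoseRateGrid, path: str | Path,
                   extra_meta: dict | None = None) -> None:
    """Write a grid as a CSV matrix plus a JSON geometry sidecar (<path>.json).

    Rows are U indices, columns T indices, matching ``values[i, j]``.
    """
    path = Path(path)
    np.savetxt(path, grid.values, delimiter=",", fmt="%.10g")
    meta = {
        "origin_u_mm": grid.geometry.origin[0],
        "origin_t_mm": grid.geometry.origin[1],
        "spacing_mm": grid.geometry.spacing,
        "shape": list(grid.geometry.shape),
        "axes": ["U", "T"],
        "kind": "dose_rate" if isinstance(grid, DoseRateGrid) else "dose",
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_grid_csv(path: str | Path) -> DoseGrid | DoseRateGrid:
    """Read a grid written by :func:`write_grid_csv`."""
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    geom = GridGeometry(origin=(meta["origin_u_mm"], meta["origin_t_mm"]),
                        spacing=meta["spacing_mm"], shape=tuple(meta["shape"]))
    if meta.get("kind") == "dose_rate":
        return DoseRateGrid(geom, values, valid_mask=np.isfinite(values))
    return DoseGrid(geom, values)
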