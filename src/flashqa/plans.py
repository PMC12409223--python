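"""Simplified treatment-plan description: a rectangular, equally weighted spot grid.

Transmission (250 MeV) FLASH fields are laterally shaped with equally
weighted spots; the simplified planning-side model places them evenly on a
rectangular grid with one mean beam width per gantry angle, a constant beam
intensity (MU/s) and constant spot-changing dead times (4 ms for a U step,
11 ms for a T row change).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["SimplePlan", "read_plan", "write_plan"]


@dataclass
class SimplePlan:
    field_id: str
    gantry_angle: float = 0.0
    couch_angle: float = 0.0
    # rectangular spot grid (mm)
    u_start: float = 0.0
    t_start: float = 0.0
    du: float = 2.5
    dt: float = 2.5
    nu: int = 1
    nt: int = 1
    mu_per_spot: float = 100.0       # MU, single value: equally weighted spots
    mean_sigma: tuple[float, float] = (3.0, 3.0)  # (σU, σT) mm for this angle
    dose_cal: float = 0.7            # Gy·mm² per MU
    intensity: float = 1.0e4         # MU/s
    dead_time_u: float = 4.0         # ms between spots within a row
    dead_time_t: float = 11.0        # ms between rows
    fractions: int = 3
    fraction_dose: float = 11.0      # Gy

    def __post_init__(self) -> None:
        if self.nu < 1 or self.nt < 1:
            raise ValueError("spot grid must be at least 1x1")
        if self.du <= 0 or self.dt <= 0:
            raise ValueError("spot spacing must be positive")
        if self.intensity <= 0:
            raise ValueError("beam intensity must be positive")
        if self.mu_per_spot <= 0:
            raise ValueError("MU per spot must be positive")
        if self.dead_time_u < 0 or self.dead_time_t < 0:
            raise ValueError("dead times must be non-negative")
        if self.mean_sigma[0] <= 0 or self.mean_sigma[1] <= 0:
            raise ValueError("mean sigma must be positive")

    @property
    def n_spots(self) -> int:
        return self.nu * self.nt

    @property
    def total_mu(self) -> float:
        return self.n_spots * self.mu_per_spot

    def spot_positions(self) -> np.ndarray:
        """(n, 2) array of (U, T) mm in delivery order.

        Raster scan with U as the fast axis; row traversal alternates
        direction (boustrophedon) to minimize magnet ramp distance.
        """
        out = np.empty((self.n_spots, 2))
        k = 0
        for j in range(self.nt):
            cols = range(self.nu) if j % 2 == 0 else range(self.nu - 1, -1, -1)
            for i in cols:
                out[k] = (self.u_start + i * self.du, self.t_start + j * self.dt)
                k += 1
        return out

    def field_center(self) -> tuple[float, float]:
        """(U, T) mm of the spot-grid centroid."""
        return (self.u_start + 0.5 * (self.nu - 1) * self.du,
                self.t_start + 0.5 * (self.nt - 1) * self.dt)


def write_plan(plan: SimplePlan, path: str | Path) -> None:
    obj = asdict(plan)
    obj["mean_sigma"] = list(plan.mean_sigma)
    Path(path).write_text(json.dumps(obj, indent=1))


def read_plan(path: str | Path) -> SimplePlan:
    obj = json.loads(Path(path).read_text())
    obj["mean_sigma"] = tuple(obj["mean_sigma"])
    return SimplePlan(**obj)
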