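"""Simplified planning-system-side field model.

The planning side works with a deliberately simplified beam model: spots
evenly placed on a rectangular grid, equal weight everywhere, one mean beam
width per gantry angle, constant beam intensity (MU/s), constant spot-change
dead times (4 ms for a U step, 11 ms for a T row change), and a tail cutoff
on each Gaussian spot.  The cumulative dose per voxel is piecewise linear:
dose accrues uniformly while a spot's beam is on and is flat during dead
times, which makes the resulting dose-rate maps smooth across neighboring
voxels (no sample-crossing artifact).
"""

from __future__ import annotations

import numpy as np

from ._dosecore import DOSE_FLOOR_FRAC, gaussian_spot_maps, pbs_rate_from_curves
from .grids import DoseGrid, DoseRateGrid, GridGeometry
from .plans import SimplePlan

__all__ = [
    "tps_delivery_timeline",
    "tps_dose_map",
    "tps_pbs_dose_rate_map",
    "dose_averaged_dose_rate_map",
    "plan_total_dose",
    "DEFAULT_CUTOFF_FACTOR",
]

#: elliptical Gaussian tail cutoff radius, in units of sigma
DEFAULT_CUTOFF_FACTOR = 4.0


def tps_delivery_timeline(plan: SimplePlan) -> np.ndarray:
    """Per-spot (t_start, t_end) beam-on intervals in ms, delivery order.

    Beam-on per spot is ``mu_per_spot / intensity``; ``dead_time_u`` separates
    spots within a row and ``dead_time_t`` separates rows (boustrophedon
    raster with U as fast axis, matching ``SimplePlan.spot_positions``).
    """
    beam_on_ms = plan.mu_per_spot / plan.intensity * 1000.0
    out = np.empty((plan.n_spots, 2))
    t = 0.0
    k = 0
    for j in range(plan.nt):
        for i in range(plan.nu):
            if k > 0:
                t += plan.dead_time_t if i == 0 else plan.dead_time_u
            out[k] = (t, t + beam_on_ms)
            t += beam_on_ms
            k += 1
    return out


def _tps_spot_maps(plan: SimplePlan, geometry: GridGeometry,
                   cutoff_factor: float | None) -> np.ndarray:
    pos = plan.spot_positions()
    n = plan.n_spots
    sigma = np.tile(np.asarray(plan.mean_sigma, dtype=float), (n, 1))
    dose_area = np.full(n, plan.mu_per_spot * plan.dose_cal)
    return gaussian_spot_maps(geometry, pos, sigma, dose_area, cutoff_factor)


def tps_dose_map(plan: SimplePlan, geometry: GridGeometry,
                 cutoff_factor: float | None = DEFAULT_CUTOFF_FACTOR) -> DoseGrid:
    """Planned 2D dose map: equal-weight Gaussian sum with constant σ.

    The Gaussian tails are truncated at ``cutoff_factor``·σ (elliptical
    radius); at the default 4σ the integral deficit per spot is exp(−8),
    about 0.034%.
    """
    maps = _tps_spot_maps(plan, geometry, cutoff_factor)
    return DoseGrid(geometry, maps.sum(axis=0))


def tps_pbs_dose_rate_map(plan: SimplePlan, geometry: GridGeometry,
                          lower_frac: float = 0.05, upper_frac: float = 0.95,
                          cutoff_factor: float | None = DEFAULT_CUTOFF_FACTOR,
                          dose_floor_frac: float = DOSE_FLOOR_FRAC) -> DoseRateGrid:
    """PBS-average (5%–95%) dose-rate map of the simplified delivery model.

    Cumulative dose per voxel is piecewise linear (uniform accrual during
    each spot's beam-on, flat during dead times); threshold crossing times
    are found by exact linear interpolation on that curve.
    """
    timeline = tps_delivery_timeline(plan)
    events = np.unique(timeline.ravel())
    # delivered fraction of each spot at each event time
    span = timeline[:, 1] - timeline[:, 0]
    frac = np.clip((events[:, None] - timeline[None, :, 0]) / span[None, :], 0.0, 1.0)
    maps = _tps_spot_maps(plan, geometry, cutoff_factor)
    return pbs_rate_from_curves(events, frac, maps, geometry, lower_frac,
                                upper_frac, interpolate=True,
                                dose_floor_frac=dose_floor_frac)


def dose_averaged_dose_rate_map(plan: SimplePlan, geometry: GridGeometry,
                                cutoff_factor: float | None = DEFAULT_CUTOFF_FACTOR,
                                dose_floor_frac: float = DOSE_FLOOR_FRAC) -> DoseRateGrid:
    """Dose-averaged dose-rate map.

    Per voxel v: ``DADR_v = Σ_i d_iv·r_i / Σ_i d_iv`` with ``d_iv`` spot i's
    dose to the voxel and ``r_i = d_iv / τ_i`` its instantaneous rate over
    its beam-on duration τ_i.  Unlike the PBS-average metric this depends
    only on beam-on durations, so pauses and dead times leave it unchanged.
    """
    maps = _tps_spot_maps(plan, geometry, cutoff_factor)
    timeline = tps_delivery_timeline(plan)
    tau_s = (timeline[:, 1] - timeline[:, 0]) / 1000.0
    total = maps.sum(axis=0)
    num = (maps ** 2 / tau_s[:, None, None]).sum(axis=0)
    floor = dose_floor_frac * total.max()
    valid = total >= floor
    values = np.full(geometry.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        values[valid] = num[valid] / total[valid]
    return DoseRateGrid(geometry, values, valid)


def plan_total_dose(plan: SimplePlan) -> float:
    """Total physical prescription dose in Gy (fractions × dose/fraction)."""
    if plan.fractions < 1:
        raise ValueError("plan must have at least one fraction")
    if plan.fraction_dose <= 0:
        raise ValueError("fraction dose must be positive")
    return plan.fractions * plan.fraction_dose
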