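"""Shared numerics: Gaussian spot-map evaluation and the PBS-average dose-rate core.

Both the log-file reconstruction and the simplified TPS model express a field
as a sum of 2D Gaussian spots with a per-spot cumulative-delivery fraction
curve over time; the dose-rate metric (5%–95% window per voxel) operates on
that shared representation.
"""

from __future__ import annotations

import numpy as np

from .grids import DoseRateGrid, GridGeometry

#: voxels with total dose below this fraction of the map maximum get no rate
DOSE_FLOOR_FRAC = 0.01


def gaussian_spot_maps(geometry: GridGeometry,
                       mu: np.ndarray,       # (n, 2) mm
                       sigma: np.ndarray,    # (n, 2) mm
                       dose_area: np.ndarray,  # (n,) Gy·mm²
                       cutoff_factor: float | None = None) -> np.ndarray:
    """Per-spot dose maps (n, nU, nT) in Gy at voxel centers.

    Each spot contributes ``dose_area · N(x; µ, diag(σU², σT²))`` with N the
    unit-integral bivariate normal density.  ``cutoff_factor`` truncates the
    tails at the elliptical radius ``cutoff_factor`` (in units of σ), as a
    planning-system-style computational shortcut; ``None`` means no cutoff.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    dose_area = np.atleast_1d(np.asarray(dose_area, dtype=float))
    n = len(mu)
    u = geometry.u_coords
    t = geometry.t_coords
    out = np.empty((n, len(u), len(t)))
    for i in range(n):
        zu = (u - mu[i, 0]) / sigma[i, 0]
        zt = (t - mu[i, 1]) / sigma[i, 1]
        norm = dose_area[i] / (2.0 * np.pi * sigma[i, 0] * sigma[i, 1])
        m = norm * np.outer(np.exp(-0.5 * zu ** 2), np.exp(-0.5 * zt ** 2))
        if cutoff_factor is not None:
            r2 = zu[:, None] ** 2 + zt[None, :] ** 2
            m = np.where(r2 <= cutoff_factor ** 2, m, 0.0)
        out[i] = m
    return out


def crossing_times(event_times: np.ndarray,   # (ne,) ms, increasing
                   cum: np.ndarray,           # (ne, nv) non-decreasing per column
                   targets: np.ndarray,       # (nv,) target dose per voxel
                   interpolate: bool) -> np.ndarray:
    """Per-voxel first time the cumulative curve reaches its target (ms).

    ``interpolate=False`` returns the first event/sample time at or beyond
    the target (the behavior that produces sharp voxel-to-voxel variation at
    field edges, where a threshold can land just before or after a beam-off
    plateau); ``interpolate=True`` linearly interpolates within the rising
    segment containing the crossing.
    """
    ne, nv = cum.shape
    idx = (cum < targets[None, :]).sum(axis=0)  # first index with cum >= target
    idx = np.minimum(idx, ne - 1)
    t_at = event_times[idx]
    if not interpolate:
        return t_at
    cols = np.arange(nv)
    prev = np.maximum(idx - 1, 0)
    c0 = cum[prev, cols]
    c1 = cum[idx, cols]
    t0 = event_times[prev]
    t1 = t_at
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(c1 > c0, (targets - c0) / (c1 - c0), 1.0)
    out = t0 + frac * (t1 - t0)
    out[idx == 0] = event_times[0]
    return out


def pbs_rate_from_curves(event_times_ms: np.ndarray,   # (ne,)
                         frac: np.ndarray,             # (ne, ns) per-spot delivered fraction
                         spot_maps: np.ndarray,        # (ns, nU, nT) Gy
                         geometry: GridGeometry,
                         lower_frac: float = 0.05,
                         upper_frac: float = 0.95,
                         interpolate: bool = False,
                         dose_floor_frac: float = DOSE_FLOOR_FRAC,
                         chunk: int = 2048) -> DoseRateGrid:
    """PBS-average dose-rate map from per-spot fraction curves.

    Per valid voxel v with total dose D_v, with t_lo/t_hi the first times the
    cumulative dose reaches ``lower_frac·D_v`` / ``upper_frac·D_v``::

        DR_v = (upper_frac − lower_frac) · D_v / (t_hi − t_lo)

    Voxels under the dose floor, or whose window collapses to zero width
    (a single instantaneous accrual), are marked invalid rather than given an
    infinite rate.
    """
    ns = spot_maps.shape[0]
    nu, nt = geometry.shape
    flat = spot_maps.reshape(ns, -1)
    total = flat.sum(axis=0)
    floor = dose_floor_frac * total.max() if total.size else 0.0
    valid = total >= floor
    rate = np.full(nu * nt, np.nan)
    reason = np.full(nu * nt, "", dtype=object)
    reason[~valid] = "dose-floor"
    vidx = np.nonzero(valid)[0]
    for start in range(0, len(vidx), chunk):
        sel = vidx[start:start + chunk]
        cum = frac @ flat[:, sel]            # (ne, |sel|)
        d = total[sel]
        t_lo = crossing_times(event_times_ms, cum, lower_frac * d, interpolate)
        t_hi = crossing_times(event_times_ms, cum, upper_frac * d, interpolate)
        dt_ms = t_hi - t_lo
        ok = dt_ms > 0
        rate[sel[ok]] = (upper_frac - lower_frac) * d[ok] / (dt_ms[ok] / 1000.0)
        reason[sel[~ok]] = "degenerate"
        valid[sel[~ok]] = False
    return DoseRateGrid(geometry, rate.reshape(nu, nt), valid.reshape(nu, nt),
                        reason.reshape(nu, nt))
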