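"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package internals: the gamma
oracle does an exhaustive per-voxel search over a finely interpolated test
map, and the dose-rate oracle scans each voxel's full cumulative time series
directly.
"""

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from flashqa import DoseGrid
from flashqa.reconstruction import CumulativeDose


def gamma_oracle(reference: DoseGrid, test: DoseGrid, dose_crit_pct=3.0,
                 dta_mm=3.0, mask_level=0.9, search_factor=3.0, subdiv=10):
    """Exhaustive gamma: per masked voxel, loop over every fine test sample
    within the search radius. Returns the gamma map (NaN outside the mask)."""
    geom = reference.geometry
    denom = dose_crit_pct / 100.0 * reference.values.max()
    mask = reference.values >= mask_level * reference.values.max()
    interp = RegularGridInterpolator((geom.u_coords, geom.t_coords),
                                     test.values, method="linear",
                                     bounds_error=False, fill_value=np.nan)
    step = geom.spacing / subdiv
    radius = search_factor * dta_mm
    offs = np.arange(-np.floor(radius / step), np.floor(radius / step) + 1) * step
    ou, ot = np.meshgrid(offs, offs, indexing="ij")
    keep = ou ** 2 + ot ** 2 <= radius ** 2
    ou, ot = ou[keep], ot[keep]
    dist2 = (ou ** 2 + ot ** 2) / dta_mm ** 2

    gamma = np.full(geom.shape, np.nan)
    for i, j in zip(*np.nonzero(mask)):
        u0, t0 = geom.u_coords[i], geom.t_coords[j]
        tv = interp(np.column_stack([u0 + ou, t0 + ot]))
        g2 = dist2 + ((tv - reference.values[i, j]) / denom) ** 2
        gamma[i, j] = np.sqrt(np.nanmin(g2))
    return gamma, mask


def pbs_rate_oracle(cum: CumulativeDose, lower=0.05, upper=0.95,
                    interpolate=False, dose_floor_frac=0.01):
    """Per-voxel scan of the full cumulative time series (no chunking, no
    vectorized searchsorted); returns the rate map in Gy/s (NaN invalid)."""
    nu, nt = cum.geometry.shape
    final = cum.spot_maps.sum(axis=0)
    floor = dose_floor_frac * final.max()
    out = np.full((nu, nt), np.nan)
    for i in range(nu):
        for j in range(nt):
            d = final[i, j]
            if d < floor:
                continue
            times, curve = cum.voxel_curve(i, j)

            def first_reach(target):
                for k in range(len(times)):
                    if curve[k] >= target:
                        if not interpolate or k == 0 or curve[k] == curve[k - 1]:
                            return times[k]
                        f = (target - curve[k - 1]) / (curve[k] - curve[k - 1])
                        return times[k - 1] + f * (times[k] - times[k - 1])
                return times[-1]

            t_lo = first_reach(lower * d)
            t_hi = first_reach(upper * d)
            if t_hi > t_lo:
                out[i, j] = (upper - lower) * d / ((t_hi - t_lo) / 1000.0)
    return out
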