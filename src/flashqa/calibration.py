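"""Beam-line calibration data and conversions.

The scanning-magnet Hall probes do not read position directly: a calibrated
curve maps the raw Hall reading to magnet current, and commissioning data map
magnet current to lateral spot position at the isocenter plane.  Both maps are
kept as separate piecewise-linear, strictly monotone curves and composed on
demand.  The same module holds the commissioning beam widths per gantry angle,
the spot dose-area calibration (Gy·mm² per monitor unit at 2 cm measurement
depth), and the daily UHDR monitor recombination factor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CalibrationCurve",
    "SigmaVariation",
    "BeamModel",
    "hall_to_position",
    "position_to_hall",
    "counts_to_dose",
    "fit_recombination_factor",
    "sigma_lookup",
    "RecombinationWarning",
    "default_beam_model",
    "read_beam_model",
    "write_beam_model",
]

#: relative monitor-vs-reference dose ratio beyond which a recombination fit
#: is flagged as outside the empirically observed regime (~20% charge loss)
RECOMBINATION_WARN_LEVEL = 1.25


class RecombinationWarning(UserWarning):
    """Fitted recombination factor outside the expected regime."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear, invertible calibration curve.

    ``x`` must be strictly increasing and ``y`` strictly monotone, so the
    curve can be evaluated in either direction.  No extrapolation: inputs
    outside the calibrated domain are data errors.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.x.size < 2 or self.y.shape != self.x.shape:
            raise ValueError("calibration curve needs >= 2 matching breakpoints")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("calibration curve inputs must be strictly increasing")
        dy = np.diff(self.y)
        if not (np.all(dy > 0) or np.all(dy < 0)):
            raise ValueError("calibration curve outputs must be strictly monotone")

    def __call__(self, value: float | np.ndarray) -> float | np.ndarray:
        v = np.asarray(value, dtype=float)
        if np.any(v < self.x[0]) or np.any(v > self.x[-1]):
            raise ValueError(
                f"value outside calibrated domain [{self.x[0]}, {self.x[-1]}]")
        out = np.interp(v, self.x, self.y)
        return float(out) if np.isscalar(value) else out

    def inverse(self) -> "CalibrationCurve":
        """Curve with input and output swapped."""
        if self.y[-1] > self.y[0]:
            return CalibrationCurve(self.y, self.x)
        return CalibrationCurve(self.y[::-1], self.x[::-1])


@dataclass(frozen=True)
class SigmaVariation:
    """Bounded multiplicative beam-size variation across the spot map.

    Models the measured behavior that the actual beam size varies across the
    field (up to ~10%) while the planning system assumes one σ per angle.
    The factor grows linearly with distance from isocenter, reaching
    ``max_frac`` at ``radius_mm``, and is clipped to ±10%.
    """

    max_frac: float = 0.1
    radius_mm: float = 100.0

    def factor(self, u: float, t: float) -> float:
        r = float(np.hypot(u, t))
        f = 1.0 + self.max_frac * min(r / self.radius_mm, 1.0)
        return float(np.clip(f, 0.9, 1.1))


@dataclass
class BeamModel:
    """Calibration bundle for one beam line.

    sigma_table maps gantry angle (deg) to the commissioning mean beam widths
    (σU, σT) in mm; dose_cal is Gy·mm² per MU so a spot's point dose is
    MU · dose_cal · N(x; µ, diag(σU², σT²)) with N the unit-integral bivariate
    normal density; recomb_factor (≥ 1) multiplies UHDR monitor doses.
    """

    hall_to_current_u: CalibrationCurve
    hall_to_current_t: CalibrationCurve
    current_to_pos_u: CalibrationCurve
    current_to_pos_t: CalibrationCurve
    sigma_table: dict[float, tuple[float, float]]
    dose_cal: float
    recomb_factor: float = 1.0
    sigma_variation: SigmaVariation | None = None

    def __post_init__(self) -> None:
        for ang, (su, st) in self.sigma_table.items():
            if su <= 0 or st <= 0:
                raise ValueError(f"sigma_table entry at {ang} deg must be positive")
        if self.dose_cal <= 0:
            raise ValueError("dose_cal must be positive")
        if self.recomb_factor < 1.0:
            raise ValueError("recomb_factor must be >= 1")

    # -- conversions -------------------------------------------------------

    def position_sd_per_hall_unit(self, axis: str) -> float:
        """Local mm-per-sensor-unit slope at the center of the Hall domain.

        Used to express Hall noise in mm-equivalent terms.
        """
        curve = self.hall_to_current_u if axis == "U" else self.hall_to_current_t
        mid = 0.5 * (curve.x[0] + curve.x[-1])
        eps = 1e-6 * (curve.x[-1] - curve.x[0])
        return abs(hall_to_position(mid + eps, axis, self)
                   - hall_to_position(mid - eps, axis, self)) / (2 * eps)


def hall_to_position(raw: float | np.ndarray, axis: str, model: BeamModel) -> float | np.ndarray:
    """Lateral spot position (mm at isocenter) from a raw Hall reading."""
    if axis == "U":
        return model.current_to_pos_u(model.hall_to_current_u(raw))
    if axis == "T":
        return model.current_to_pos_t(model.hall_to_current_t(raw))
    raise ValueError(f"axis must be 'U' or 'T', got {axis!r}")


def position_to_hall(pos: float | np.ndarray, axis: str, model: BeamModel) -> float | np.ndarray:
    """Inverse of :func:`hall_to_position` (used by the delivery simulator)."""
    if axis == "U":
        return model.hall_to_current_u.inverse()(model.current_to_pos_u.inverse()(pos))
    if axis == "T":
        return model.hall_to_current_t.inverse()(model.current_to_pos_t.inverse()(pos))
    raise ValueError(f"axis must be 'U' or 'T', got {axis!r}")


def counts_to_dose(delta_counts: float, model: BeamModel, arm: str) -> float:
    """Spot dose-area (Gy·mm²) from a monitor-count increment (MU).

    UHDR deliveries additionally apply the daily monitor recombination
    factor; CONV deliveries do not.  Divide by a reference-geometry factor
    (mm²) for a point dose.
    """
    if delta_counts < 0:
        raise ValueError("monitor count increment must be non-negative")
    if arm not in ("CONV", "UHDR"):
        raise ValueError(f"arm must be CONV or UHDR, got {arm!r}")
    dose = delta_counts * model.dose_cal
    if arm == "UHDR":
        dose *= model.recomb_factor
    return dose


def recomb_multiplier(model: BeamModel, arm: str) -> float:
    """1.0 for CONV, the monitor recombination factor for UHDR."""
    if arm not in ("CONV", "UHDR"):
        raise ValueError(f"arm must be CONV or UHDR, got {arm!r}")
    return model.recomb_factor if arm == "UHDR" else 1.0


def fit_recombination_factor(monitor_dose: float, reference_dose: float) -> float:
    """Daily monitor recombination factor from a recombination-free reference.

    The dose-control monitor under-responds at ultra-high dose rates because
    of ion recombination in its chamber; the factor is the ratio of the dose
    seen by a recombination-free reference detector to the monitor-derived
    dose.  Factors beyond ~1.25 are outside the empirically observed regime
    and raise a :class:`RecombinationWarning`.
    """
    if monitor_dose <= 0 or reference_dose <= 0:
        raise ValueError("doses must be positive")
    factor = reference_dose / monitor_dose
    if factor > RECOMBINATION_WARN_LEVEL:
        warnings.warn(
            f"recombination factor {factor:.4f} exceeds the expected regime "
            f"(> {RECOMBINATION_WARN_LEVEL})", RecombinationWarning, stacklevel=2)
    return factor


def sigma_lookup(gantry_angle: float, model: BeamModel,
                 position: tuple[float, float] | None = None,
                 max_angle_gap: float = 5.0) -> tuple[float, float]:
    """Commissioning beam widths (σU, σT) mm for a gantry angle.

    The nearest table entry within ``max_angle_gap`` degrees is used.  If the
    model carries a per-position variation field and a position is given, the
    widths are scaled by its bounded factor.
    """
    if not model.sigma_table:
        raise ValueError("beam model has an empty sigma table")
    angles = np.array(sorted(model.sigma_table))
    nearest = angles[np.argmin(np.abs(angles - gantry_angle))]
    if abs(nearest - gantry_angle) > max_angle_gap:
        raise ValueError(
            f"no sigma table entry within {max_angle_gap} deg of {gantry_angle} deg")
    su, st = model.sigma_table[float(nearest)]
    if position is not None and model.sigma_variation is not None:
        f = model.sigma_variation.factor(*position)
        su, st = su * f, st * f
    return su, st


# -- serialization ---------------------------------------------------------

def _curve_to_json(c: CalibrationCurve) -> dict:
    return {"x": c.x.tolist(), "y": c.y.tolist()}


def write_beam_model(model: BeamModel, path: str | Path) -> None:
    obj = {
        "hall_to_current_U": _curve_to_json(model.hall_to_current_u),
        "hall_to_current_T": _curve_to_json(model.hall_to_current_t),
        "current_to_pos_U": _curve_to_json(model.current_to_pos_u),
        "current_to_pos_T": _curve_to_json(model.current_to_pos_t),
        "sigma_table": {str(a): list(s) for a, s in model.sigma_table.items()},
        "dose_cal_gy_mm2_per_mu": model.dose_cal,
        "recomb_factor": model.recomb_factor,
    }
    if model.sigma_variation is not None:
        obj["sigma_variation"] = {"max_frac": model.sigma_variation.max_frac,
                                  "radius_mm": model.sigma_variation.radius_mm}
    Path(path).write_text(json.dumps(obj, indent=1))


def read_beam_model(path: str | Path) -> BeamModel:
    obj = json.loads(Path(path).read_text())
    var = None
    if "sigma_variation" in obj:
        var = SigmaVariation(**obj["sigma_variation"])
    return BeamModel(
        hall_to_current_u=CalibrationCurve(**obj["hall_to_current_U"]),
        hall_to_current_t=CalibrationCurve(**obj["hall_to_current_T"]),
        current_to_pos_u=CalibrationCurve(**obj["current_to_pos_U"]),
        current_to_pos_t=CalibrationCurve(**obj["current_to_pos_T"]),
        sigma_table={float(a): tuple(s) for a, s in obj["sigma_table"].items()},
        dose_cal=obj["dose_cal_gy_mm2_per_mu"],
        recomb_factor=obj.get("recomb_factor", 1.0),
        sigma_variation=var,
    )


def default_beam_model(sigma: tuple[float, float] = (3.0, 3.0),
                       dose_cal: float = 0.7,
                       recomb_factor: float = 1.0,
                       sigma_variation: SigmaVariation | None = None) -> BeamModel:
    """A linear demonstration beam model.

    Hall domain [-1, 1] sensor units maps through [-50, 50] A to
    [-200, 200] mm at isocenter (200 mm per sensor unit); one σ entry per
    cardinal gantry angle.
    """
    h2c = CalibrationCurve([-1.0, 1.0], [-50.0, 50.0])
    c2p = CalibrationCurve([-50.0, 50.0], [-200.0, 200.0])
    table = {a: sigma for a in (0.0, 90.0, 180.0, 270.0)}
    return BeamModel(h2c, h2c, c2p, c2p, table, dose_cal, recomb_factor,
                     sigma_variation)
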