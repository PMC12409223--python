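"""Synthetic PBS field deliveries with the machine's time structure.

Stands in for machine data: produces 1 kHz delivery logs (cumulative
monitor counts, Hall readings, timestamps) plus the ground truth they encode.
The timing model matches the simplified delivery model used on the planning
side — constant beam intensity while a spot is on, constant spot-change dead
times (4 ms U step, 11 ms T row change), boustrophedon raster with U fast —
with optional Gaussian sensor noise and beam-pause injection on top.

During a dead time the scanning magnets ramp linearly to the next spot's
field strength; the ramp starts at the first sample tick at or after beam-off
and settles exactly at the next beam-on, so every sample carrying dose also
carries the exact spot position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import BeamModel, position_to_hall, sigma_lookup
from .deliverylog import DeliveryLog
from .plans import SimplePlan
from .tps import tps_delivery_timeline

__all__ = ["TrueSpot", "GroundTruth", "NoiseSettings", "simulate_delivery",
           "inject_pause"]


@dataclass(frozen=True)
class TrueSpot:
    mu_u: float      # mm
    mu_t: float      # mm
    sigma_u: float   # mm
    sigma_t: float   # mm
    mu: float        # monitor units delivered
    t_start: float   # ms, beam-on start
    t_end: float     # ms, beam-on end


@dataclass
class GroundTruth:
    """What the simulator actually delivered (the oracle for reconstruction)."""

    spots: list[TrueSpot]
    pauses: list[tuple[float, float, str]] = field(default_factory=list)  # (start ms, duration ms, cause)
    total_mu: float = 0.0
    intensity: float = 0.0  # MU/s

    def __post_init__(self) -> None:
        for a, b in zip(self.spots, self.spots[1:]):
            if b.t_start < a.t_end:
                raise ValueError("ground-truth spot intervals overlap or are unordered")
        if self.spots and not np.isclose(self.total_mu, sum(s.mu for s in self.spots)):
            raise ValueError("total_mu does not equal the sum of spot MU")


@dataclass(frozen=True)
class NoiseSettings:
    """Per-sample sensor noise for the simulator.

    hall_sd is in raw sensor units (use
    ``BeamModel.position_sd_per_hall_unit`` to convert an mm-equivalent);
    monitor_sd is in MU per sample, applied to the increments and truncated
    so the cumulative channels stay monotone; hall_quant, if positive, rounds
    Hall readings to that sensor-unit step (ADC quantization).
    """

    hall_sd: float = 0.0
    monitor_sd: float = 0.0
    hall_quant: float = 0.0


def _hall_trace(sample_t: np.ndarray, timeline: np.ndarray, values: np.ndarray,
                period: float) -> np.ndarray:
    """Piecewise-linear Hall channel: flat on each spot, linear ramps between."""
    bt: list[float] = []
    bv: list[float] = []
    n = len(timeline)
    for i in range(n):
        start, end = timeline[i]
        ramp_start = np.ceil(end / period - 1e-9) * period
        if i + 1 < n:
            ramp_start = min(ramp_start, timeline[i + 1, 0])
        bt += [start, ramp_start]
        bv += [values[i], values[i]]
    return np.interp(sample_t, bt, bv)


def simulate_delivery(plan: SimplePlan, model: BeamModel,
                      noise: NoiseSettings | None = None, seed: int = 0,
                      arm: str = "UHDR", sample_period_ms: float = 1.0,
                      tail_ms: float = 10.0) -> tuple[DeliveryLog, GroundTruth]:
    """Simulate one field delivery; returns the 1 kHz log and its ground truth.

    The log spans field load (t = 0) to the last spot's beam-off plus
    ``tail_ms``.  With zero noise the final cumulative monitor count equals
    the plan's total MU to float precision, and the same seed reproduces the
    log exactly.
    """
    if plan.n_spots < 1:
        raise ValueError("plan must contain at least one spot")
    if plan.intensity <= 0:
        raise ValueError("beam intensity must be positive")
    if min(plan.dead_time_u, plan.dead_time_t) < sample_period_ms:
        raise ValueError("dead times must be at least one sample period")
    noise = noise or NoiseSettings()
    rng = np.random.default_rng(seed)

    timeline = tps_delivery_timeline(plan)
    pos = plan.spot_positions()
    n_samp = int(np.ceil((timeline[-1, 1] + tail_ms) / sample_period_ms)) + 1
    t = np.round(np.arange(n_samp) * sample_period_ms, 1)

    # cumulative true MU at each sample time (analytic overlap -> exact totals)
    rate_per_ms = plan.intensity / 1000.0
    dur = timeline[:, 1] - timeline[:, 0]
    overlap = np.clip(t[:, None] - timeline[None, :, 0], 0.0, dur[None, :])
    cum = rate_per_ms * overlap.sum(axis=1)

    def monitor_channel() -> np.ndarray:
        if noise.monitor_sd <= 0:
            return cum.copy()
        inc = np.diff(cum, prepend=0.0)
        inc = np.clip(inc + rng.normal(0.0, noise.monitor_sd, n_samp), 0.0, None)
        return np.cumsum(inc)

    mon1 = monitor_channel()
    mon2 = monitor_channel()

    hall = {}
    for axis, col in (("U", 0), ("T", 1)):
        raw = np.asarray(position_to_hall(pos[:, col], axis, model), dtype=float)
        ch = _hall_trace(t, timeline, raw, sample_period_ms)
        if noise.hall_sd > 0:
            ch = ch + rng.normal(0.0, noise.hall_sd, n_samp)
        if noise.hall_quant > 0:
            ch = np.round(ch / noise.hall_quant) * noise.hall_quant
        hall[axis] = ch

    log = DeliveryLog(field_id=plan.field_id, gantry_angle=plan.gantry_angle,
                      couch_angle=plan.couch_angle, arm=arm,
                      sample_period_ms=sample_period_ms,
                      t_ms=t, mon1=mon1, mon2=mon2,
                      hallU=hall["U"], hallT=hall["T"])

    spots = []
    for i in range(plan.n_spots):
        su, st = sigma_lookup(plan.gantry_angle, model, position=tuple(pos[i]))
        spots.append(TrueSpot(mu_u=pos[i, 0], mu_t=pos[i, 1], sigma_u=su,
                              sigma_t=st, mu=plan.mu_per_spot,
                              t_start=timeline[i, 0], t_end=timeline[i, 1]))
    truth = GroundTruth(spots=spots, total_mu=plan.total_mu,
                        intensity=plan.intensity)
    return log, truth


def inject_pause(log: DeliveryLog, truth: GroundTruth, at: float,
                 duration: float, cause: str = "interlock") -> tuple[DeliveryLog, GroundTruth]:
    """Insert a beam pause at ``at`` ms (must fall inside a beam-on interval).

    Monitor channels stay flat for the pause; all later samples shift by the
    pause duration (rounded to the sample grid), so the total MU is
    unchanged.  Returns a new log and ground truth; inputs are not modified.
    """
    spot_idx = next((i for i, s in enumerate(truth.spots)
                     if s.t_start <= at < s.t_end), None)
    if spot_idx is None:
        raise ValueError(f"pause time {at} ms is not within any beam-on interval")
    period = log.sample_period_ms
    n_ins = max(1, int(round(duration / period)))
    actual = n_ins * period

    # pause begins at the sample tick at or before `at`, keeping the grid exact
    k = int(np.searchsorted(log.t_ms, at, side="right")) - 1

    def splice(ch: np.ndarray) -> np.ndarray:
        return np.concatenate([ch[:k + 1], np.full(n_ins, ch[k]), ch[k + 1:]])

    t_new = np.round(np.concatenate([
        log.t_ms[:k + 1],
        log.t_ms[k] + period * np.arange(1, n_ins + 1),
        log.t_ms[k + 1:] + actual,
    ]), 1)
    new_log = DeliveryLog(field_id=log.field_id, gantry_angle=log.gantry_angle,
                          couch_angle=log.couch_angle, arm=log.arm,
                          sample_period_ms=period, t_ms=t_new,
                          mon1=splice(log.mon1), mon2=splice(log.mon2),
                          hallU=splice(log.hallU), hallT=splice(log.hallT),
                          annotations=log.annotations
                          + [f"pause {actual} ms at {at} ms ({cause})"])

    new_spots = []
    for i, s in enumerate(truth.spots):
        if i == spot_idx:
            new_spots.append(replace(s, t_end=s.t_end + actual))
        elif s.t_start >= at:
            new_spots.append(replace(s, t_start=s.t_start + actual,
                                     t_end=s.t_end + actual))
        else:
            new_spots.append(s)
    new_pauses = [(p0 + actual, d, c) if p0 >= at else (p0, d, c)
                  for (p0, d, c) in truth.pauses]
    new_pauses.append((float(log.t_ms[k]), float(actual), cause))
    new_pauses.sort()
    new_truth = GroundTruth(spots=new_spots, pauses=new_pauses,
                            total_mu=truth.total_mu, intensity=truth.intensity)
    return new_log, new_truth
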