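"""PSQA/DQA computations and decision logic.

Patient-specific QA (PSQA) checks each field against the plan recalculated
in water: (1) laser/isocenter alignment (a physical measurement, recorded
here), (2) a five-spot pattern for spot position (±2 mm) and size (±10%,
from a 2D Gaussian fit), (3) the central field dose (±5%, else the field is
scaled), and (4) the full 2D field delivery, judged by the mean dose
deviation in the 90% isodose area (>3% triggers a boosting factor) and a
3%/3 mm gamma analysis (pass: >90% of masked voxels at γ ≤ 1).  Daily QA
(DQA) runs the identical pipeline against the PSQA-day measurement, with a
daily recombination correction for UHDR deliveries.  UHDR fields must also
keep the measured local dose rate above 40 Gy/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .calibration import BeamModel, fit_recombination_factor
from .deliverylog import DeliveryLog
from .grids import DoseGrid, GridGeometry
from .plans import SimplePlan
from .reconstruction import detect_pauses
from .tps import tps_dose_map

__all__ = [
    "SpotFit", "FiveSpotResult", "GammaResult", "CentralDoseResult",
    "BoostingResult", "DoseRateCheckResult", "QADecision",
    "fit_spot_2d_gaussian", "analyze_five_spot", "gamma_index_map",
    "central_dose_check", "boosting_check", "uhdr_dose_rate_check",
    "run_psqa", "run_dqa",
    "POSITION_TOL_MM", "SIZE_TOL_FRAC", "CENTRAL_DOSE_TOL",
    "MEAN_DEV_THRESHOLD_PCT", "GAMMA_PASS_PCT", "UHDR_RATE_FLOOR",
]

POSITION_TOL_MM = 2.0        # five-spot position tolerance
SIZE_TOL_FRAC = 0.10         # five-spot beam-size tolerance
CENTRAL_DOSE_TOL = 0.05      # measured/planned central dose ratio tolerance
MEAN_DEV_THRESHOLD_PCT = 3.0  # mean 90%-isodose deviation triggering boosting
GAMMA_PASS_PCT = 90.0        # required gamma pass fraction
UHDR_RATE_FLOOR = 40.0       # Gy/s, local dose rate must be strictly above


# --------------------------------------------------------------------------
# 2D Gaussian spot fitting

@dataclass(frozen=True)
class SpotFit:
    center: tuple[float, float]   # (U, T) mm
    sigma: tuple[float, float]    # (σU, σT) mm
    amplitude: float
    background: float
    residual_rms: float


def fit_spot_2d_gaussian(image: DoseGrid,
                         initial_guess: dict | None = None) -> SpotFit:
    """Least-squares fit of an axis-aligned elliptical Gaussian + background.

    The image must contain one dominant interior peak; a flat image or a
    peak on the image border is an error.
    """
    v = image.values
    if v.max() - v.min() <= 1e-12 * max(abs(v.max()), 1.0):
        raise ValueError("flat image: no peak to fit")
    pk = np.unravel_index(np.argmax(v), v.shape)
    if pk[0] in (0, v.shape[0] - 1) or pk[1] in (0, v.shape[1] - 1):
        raise ValueError("peak lies on the image border")
    uu, tt = image.geometry.meshgrid()

    b0 = float(v.min())
    a0 = float(v.max() - b0)
    w = np.clip(v - b0, 0, None)
    wsum = w.sum()
    u0 = float((w * uu).sum() / wsum)
    t0 = float((w * tt).sum() / wsum)
    su0 = max(np.sqrt((w * (uu - u0) ** 2).sum() / wsum), image.geometry.spacing)
    st0 = max(np.sqrt((w * (tt - t0) ** 2).sum() / wsum), image.geometry.spacing)
    p0 = [a0, u0, t0, su0, st0, b0]
    if initial_guess:
        for k, i in (("amplitude", 0), ("u", 1), ("t", 2),
                     ("sigma_u", 3), ("sigma_t", 4), ("background", 5)):
            if k in initial_guess:
                p0[i] = initial_guess[k]

    def resid(p):
        a, cu, ct, su, st, b = p
        m = a * np.exp(-0.5 * (((uu - cu) / su) ** 2 + ((tt - ct) / st) ** 2)) + b
        return (m - v).ravel()

    eps = image.geometry.spacing
    res = optimize.least_squares(
        resid, p0, max_nfev=200,
        bounds=([0, u0 - 50 * eps, t0 - 50 * eps, 0.1 * eps, 0.1 * eps, -np.inf],
                [np.inf, u0 + 50 * eps, t0 + 50 * eps, np.inf, np.inf, np.inf]))
    if not res.success:
        raise RuntimeError("2D Gaussian fit did not converge")
    a, cu, ct, su, st, b = res.x
    return SpotFit(center=(float(cu), float(ct)), sigma=(float(su), float(st)),
                   amplitude=float(a), background=float(b),
                   residual_rms=float(np.sqrt(np.mean(res.fun ** 2))))


# --------------------------------------------------------------------------
# Five-spot check

#: default five-spot nominal pattern: field center plus four cardinal points
DEFAULT_FIVE_SPOT_PATTERN = ((0.0, 0.0), (40.0, 0.0), (-40.0, 0.0),
                             (0.0, 40.0), (0.0, -40.0))


@dataclass
class FiveSpotResult:
    fits: list[SpotFit]
    nominal: np.ndarray                  # (5, 2) mm
    offsets: np.ndarray                  # (5, 2) mm, fitted − nominal
    size_deviations: np.ndarray          # (5, 2) fractional, fitted/ref − 1
    suggested_correction: tuple[float, float]  # mm, −mean(offsets)
    position_pass: bool
    size_pass: bool

    @property
    def passed(self) -> bool:
        return self.position_pass and self.size_pass


def analyze_five_spot(image: DoseGrid, nominal=DEFAULT_FIVE_SPOT_PATTERN,
                      reference_sizes: tuple[float, float] = (3.0, 3.0),
                      pos_tol: float = POSITION_TOL_MM,
                      size_tol: float = SIZE_TOL_FRAC,
                      window_mm: float | None = None) -> FiveSpotResult:
    """Fit each of the five delivered spots and compare with commissioning.

    Each peak is fit independently inside a crop window around its nominal
    position (default: 45% of the smallest nominal pair distance).  The
    suggested global offset correction is the negated mean per-spot offset —
    applying it as a rigid translation removes a systematic positional shift.
    """
    nominal = np.asarray(nominal, dtype=float)
    if window_mm is None:
        d = np.linalg.norm(nominal[:, None] - nominal[None, :], axis=2)
        window_mm = 0.45 * d[d > 0].min()
    geom = image.geometry
    fits = []
    for (nu, nt) in nominal:
        iu = np.nonzero(np.abs(geom.u_coords - nu) <= window_mm)[0]
        it = np.nonzero(np.abs(geom.t_coords - nt) <= window_mm)[0]
        if iu.size < 3 or it.size < 3:
            raise ValueError(f"nominal spot at ({nu}, {nt}) mm not inside the image")
        sub = DoseGrid(GridGeometry(origin=(geom.u_coords[iu[0]], geom.t_coords[it[0]]),
                                    spacing=geom.spacing,
                                    shape=(iu.size, it.size)),
                       image.values[np.ix_(iu, it)])
        try:
            fits.append(fit_spot_2d_gaussian(sub))
        except ValueError as exc:
            raise ValueError(f"unresolvable spot near ({nu}, {nt}) mm: {exc}") from exc
    centers = np.array([f.center for f in fits])
    sigmas = np.array([f.sigma for f in fits])
    offsets = centers - nominal
    size_dev = sigmas / np.asarray(reference_sizes, dtype=float) - 1.0
    corr = -offsets.mean(axis=0)
    return FiveSpotResult(
        fits=fits, nominal=nominal, offsets=offsets, size_deviations=size_dev,
        suggested_correction=(float(corr[0]), float(corr[1])),
        position_pass=bool(np.all(np.abs(offsets) <= pos_tol)),
        size_pass=bool(np.all(np.abs(size_dev) <= size_tol)))


# --------------------------------------------------------------------------
# Gamma analysis

@dataclass
class GammaResult:
    gamma: np.ndarray            # γ on the reference grid, NaN outside mask
    mask: np.ndarray             # 90%-isodose analysis mask
    pass_fraction: float         # % of masked voxels with γ <= 1
    mean_signed_deviation: float  # % mean (test − ref)/ref within mask
    dose_difference: np.ndarray  # test − ref, Gy


def gamma_index_map(reference: DoseGrid, test: DoseGrid,
                    dose_crit_pct: float = 3.0, dta_mm: float = 3.0,
                    mask_level: float = 0.9, search_factor: float = 3.0,
                    subdivisions: int = 10) -> GammaResult:
    """Global 2D gamma index between two dose maps on the same grid.

    For each reference voxel r inside the analysis mask (reference dose ≥
    ``mask_level`` of the reference maximum)::

        γ(r) = min_{r'} sqrt( |r − r'|²/dta² + (D_test(r') − D_ref(r))²/Δ² )

    with Δ = ``dose_crit_pct``% of the reference maximum (global
    normalization), the search capped at ``search_factor``·dta, and the test
    map linearly interpolated at 1/``subdivisions`` voxel resolution.
    """
    if reference.geometry != test.geometry:
        raise ValueError("reference and test must share grid geometry")
    geom = reference.geometry
    denom = dose_crit_pct / 100.0 * reference.max()
    mask = reference.isodose_mask(mask_level)
    if not mask.any():
        raise ValueError("empty analysis mask")

    step = geom.spacing / subdivisions
    fine = _upsample_linear(test.values, subdivisions)
    max_off = int(np.floor(search_factor * dta_mm / step))
    pad = np.full((fine.shape[0] + 2 * max_off, fine.shape[1] + 2 * max_off), np.nan)
    pad[max_off:max_off + fine.shape[0], max_off:max_off + fine.shape[1]] = fine

    mi, mj = np.nonzero(mask)
    base_i = mi * subdivisions + max_off
    base_j = mj * subdivisions + max_off
    ref_vals = reference.values[mask]

    oi, oj = np.meshgrid(np.arange(-max_off, max_off + 1),
                         np.arange(-max_off, max_off + 1), indexing="ij")
    d2 = (oi.ravel() ** 2 + oj.ravel() ** 2) * step ** 2
    keep = d2 <= (search_factor * dta_mm) ** 2
    order = np.argsort(d2[keep])
    offs = np.column_stack([oi.ravel()[keep], oj.ravel()[keep]])[order]
    d2 = d2[keep][order]

    gamma2 = np.full(ref_vals.shape, np.inf)
    active = np.arange(ref_vals.size)
    for (doi, doj), dist2 in zip(offs, d2):
        geom2 = dist2 / dta_mm ** 2
        still = gamma2[active] > geom2
        active = active[still]
        if active.size == 0:
            break
        tv = pad[base_i[active] + doi, base_j[active] + doj]
        cand = geom2 + ((tv - ref_vals[active]) / denom) ** 2
        gamma2[active] = np.fmin(gamma2[active], cand)

    gamma_map = np.full(geom.shape, np.nan)
    gamma_map[mask] = np.sqrt(gamma2)
    diff = test.values - reference.values
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = float(np.mean(diff[mask] / reference.values[mask]) * 100.0)
    return GammaResult(
        gamma=gamma_map, mask=mask,
        pass_fraction=float(np.mean(gamma2[np.isfinite(gamma2)] <= 1.0) * 100.0)
        if np.isfinite(gamma2).any() else 0.0,
        mean_signed_deviation=dev, dose_difference=diff)


def _upsample_linear(values: np.ndarray, subdiv: int) -> np.ndarray:
    """Bilinear upsampling keeping original samples on the fine lattice."""
    nu, nt = values.shape
    fi = np.arange((nu - 1) * subdiv + 1) / subdiv
    fj = np.arange((nt - 1) * subdiv + 1) / subdiv
    tmp = np.empty((fi.size, nt))
    for j in range(nt):
        tmp[:, j] = np.interp(fi, np.arange(nu), values[:, j])
    out = np.empty((fi.size, fj.size))
    for i in range(fi.size):
        out[i] = np.interp(fj, np.arange(nt), tmp[i])
    return out


# --------------------------------------------------------------------------
# Scalar checks

@dataclass(frozen=True)
class CentralDoseResult:
    ratio: float                  # measured / planned
    scaling_factor: float | None  # 1/ratio when out of tolerance, else None


def central_dose_check(measured_dose: float, planned_dose: float,
                       tol: float = CENTRAL_DOSE_TOL) -> CentralDoseResult:
    """Field-center dose ratio; out of tolerance → dose scaling factor."""
    if planned_dose <= 0:
        raise ValueError("planned dose must be positive")
    ratio = measured_dose / planned_dose
    scaling = 1.0 / ratio if abs(ratio - 1.0) > tol else None
    return CentralDoseResult(ratio=ratio, scaling_factor=scaling)


@dataclass(frozen=True)
class BoostingResult:
    mean_deviation_pct: float     # signed mean (test − ref)/ref, %
    boosting_factor: float | None


def boosting_check(reference: DoseGrid, test: DoseGrid,
                   mask_level: float = 0.9,
                   threshold_pct: float = MEAN_DEV_THRESHOLD_PCT) -> BoostingResult:
    """Mean dose deviation in the 90% isodose area; >3% → boosting factor."""
    if reference.geometry != test.geometry:
        raise ValueError("reference and test must share grid geometry")
    mask = reference.isodose_mask(mask_level)
    if not mask.any():
        raise ValueError("empty analysis mask")
    dev = float(np.mean((test.values[mask] - reference.values[mask])
                        / reference.values[mask]) * 100.0)
    boost = 1.0 / (1.0 + dev / 100.0) if abs(dev) > threshold_pct else None
    return BoostingResult(mean_deviation_pct=dev, boosting_factor=boost)


@dataclass(frozen=True)
class DoseRateCheckResult:
    rates: tuple[float, ...]
    failing_positions: tuple[int, ...]

    @property
    def passed(self) -> bool:
        return not self.failing_positions


def uhdr_dose_rate_check(rates, floor: float = UHDR_RATE_FLOOR) -> DoseRateCheckResult:
    """UHDR local dose rates must be strictly above the floor (40 Gy/s)."""
    rates = tuple(float(r) for r in rates)
    if not rates:
        raise ValueError("at least one dose-rate sample is required")
    failing = tuple(i for i, r in enumerate(rates) if r <= floor)
    return DoseRateCheckResult(rates=rates, failing_positions=failing)


# --------------------------------------------------------------------------
# PSQA / DQA pipelines

@dataclass
class QADecision:
    kind: str                                  # "PSQA" or "DQA"
    status: str                                # pass | pass-with-correction | fail | clinical-review
    laser_ok: bool = True
    five_spot: FiveSpotResult | None = None
    offset_correction: tuple[float, float] = (0.0, 0.0)  # mm, applied
    scaling_factor: float | None = None
    boosting: BoostingResult | None = None
    central_dose: CentralDoseResult | None = None
    gamma: GammaResult | None = None
    dose_rate_check: DoseRateCheckResult | None = None
    recombination_factor: float | None = None
    notes: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        """JSON-serializable summary of the decision."""
        out = {
            "kind": self.kind,
            "status": self.status,
            "laser_ok": self.laser_ok,
            "offset_correction_mm": list(self.offset_correction),
            "scaling_factor": self.scaling_factor,
            "notes": list(self.notes),
        }
        if self.central_dose is not None:
            out["central_dose_ratio"] = self.central_dose.ratio
        if self.five_spot is not None:
            out["five_spot_pass"] = self.five_spot.passed
            out["five_spot_max_offset_mm"] = float(np.abs(self.five_spot.offsets).max())
        if self.gamma is not None:
            out["gamma_pass_fraction_pct"] = self.gamma.pass_fraction
            out["mean_deviation_pct"] = self.gamma.mean_signed_deviation
        if self.boosting is not None:
            out["boosting_factor"] = self.boosting.boosting_factor
        if self.dose_rate_check is not None:
            out["dose_rate_check_pass"] = self.dose_rate_check.passed
            out["dose_rate_samples_gy_s"] = list(self.dose_rate_check.rates)
        if self.recombination_factor is not None:
            out["recombination_factor"] = self.recombination_factor
        return out


def _translate(grid: DoseGrid, shift_mm: tuple[float, float]) -> DoseGrid:
    """Rigid translation of a map by (dU, dT) mm, linear interpolation."""
    if shift_mm == (0.0, 0.0):
        return grid
    s = (shift_mm[0] / grid.geometry.spacing, shift_mm[1] / grid.geometry.spacing)
    return DoseGrid(grid.geometry,
                    ndimage.shift(grid.values, s, order=1, mode="constant", cval=0.0))


def _qa_pipeline(kind: str, reference: DoseGrid, measured: DoseGrid,
                 center: tuple[float, float],
                 five_spot_image: DoseGrid | None,
                 five_spot_nominal, reference_sizes,
                 dose_rate_samples, arm: str, laser_ok: bool,
                 apply_offset_above_mm: float = 0.2) -> QADecision:
    decision = QADecision(kind=kind, status="pass", laser_ok=laser_ok)
    if not laser_ok:
        decision.notes.append("laser/isocenter alignment out of tolerance")

    corrected = measured
    if five_spot_image is not None:
        fs = analyze_five_spot(five_spot_image, nominal=five_spot_nominal,
                               reference_sizes=reference_sizes)
        decision.five_spot = fs
        if not fs.passed:
            decision.notes.append("five-spot position/size check failed")
        corr = fs.suggested_correction
        if max(abs(corr[0]), abs(corr[1])) > apply_offset_above_mm:
            decision.offset_correction = corr
            corrected = _translate(corrected, corr)
            decision.notes.append(
                f"applied offset correction ({corr[0]:.2f}, {corr[1]:.2f}) mm")

    cd = central_dose_check(corrected.value_at(*center), reference.value_at(*center))
    decision.central_dose = cd
    if cd.scaling_factor is not None:
        decision.scaling_factor = cd.scaling_factor
        corrected = DoseGrid(corrected.geometry, corrected.values * cd.scaling_factor)
        decision.notes.append(f"applied dose scaling {cd.scaling_factor:.4f}")

    decision.boosting = boosting_check(reference, corrected)
    if decision.boosting.boosting_factor is not None:
        # the delivery is repeated with the boosting factor applied; evaluate
        # the spatial agreement of that corrected delivery
        corrected = DoseGrid(corrected.geometry,
                             corrected.values * decision.boosting.boosting_factor)
        decision.notes.append(
            f"mean deviation {decision.boosting.mean_deviation_pct:.2f}% > "
            f"{MEAN_DEV_THRESHOLD_PCT}%: boosting factor "
            f"{decision.boosting.boosting_factor:.4f}, repeat delivery")
    decision.gamma = gamma_index_map(reference, corrected)

    if dose_rate_samples is not None and arm == "UHDR":
        decision.dose_rate_check = uhdr_dose_rate_check(dose_rate_samples)
        if not decision.dose_rate_check.passed:
            decision.notes.append(
                f"local dose rate not above {UHDR_RATE_FLOOR} Gy/s at positions "
                f"{list(decision.dose_rate_check.failing_positions)}")

    hard_fail = (not laser_ok
                 or (decision.five_spot is not None and not decision.five_spot.passed)
                 or (decision.dose_rate_check is not None
                     and not decision.dose_rate_check.passed))
    corrected_any = (decision.offset_correction != (0.0, 0.0)
                     or decision.scaling_factor is not None
                     or decision.boosting.boosting_factor is not None)
    if hard_fail:
        decision.status = "fail"
    elif decision.gamma.pass_fraction <= GAMMA_PASS_PCT:
        decision.status = "clinical-review"
        decision.notes.append(
            f"gamma pass fraction {decision.gamma.pass_fraction:.1f}% <= "
            f"{GAMMA_PASS_PCT}%: clinical decision based on the location of "
            "the largest deviation")
    elif corrected_any:
        decision.status = "pass-with-correction"
    return decision


def run_psqa(plan: SimplePlan, measured: DoseGrid, model: BeamModel | None = None,
             five_spot_image: DoseGrid | None = None,
             five_spot_nominal=DEFAULT_FIVE_SPOT_PATTERN,
             dose_rate_samples=None, arm: str = "UHDR",
             laser_ok: bool = True) -> QADecision:
    """Patient-specific QA: measured field vs the plan recalculated in water.

    The reference is the simplified planning-side dose map on the measured
    grid.  Corrections found by the earlier steps (offset, scaling) are
    applied to the measured map before the gamma and boosting evaluation.
    """
    reference = tps_dose_map(plan, measured.geometry)
    return _qa_pipeline("PSQA", reference, measured, plan.field_center(),
                        five_spot_image, five_spot_nominal, plan.mean_sigma,
                        dose_rate_samples, arm, laser_ok)


def run_dqa(psqa_reference: DoseGrid, daily: DoseGrid,
            center: tuple[float, float] | None = None,
            five_spot_image: DoseGrid | None = None,
            five_spot_nominal=DEFAULT_FIVE_SPOT_PATTERN,
            reference_sizes: tuple[float, float] = (3.0, 3.0),
            dose_rate_samples=None, arm: str = "UHDR", laser_ok: bool = True,
            recomb_monitor_dose: float | None = None,
            recomb_reference_dose: float | None = None,
            daily_log: DeliveryLog | None = None) -> QADecision:
    """Daily QA: same pipeline and tolerances as PSQA, but the reference is
    the dose delivered on the PSQA day.

    For UHDR deliveries a daily recombination factor (from the
    recombination-free reference detector) is applied to the daily map first.
    If the daily delivery log is supplied it is scanned for interruptions;
    an interrupted UHDR delivery carries an exclusion recommendation.
    """
    decision_notes: list[str] = []
    recomb = None
    if arm == "UHDR" and recomb_monitor_dose is not None and recomb_reference_dose is not None:
        recomb = fit_recombination_factor(recomb_monitor_dose, recomb_reference_dose)
        daily = DoseGrid(daily.geometry, daily.values * recomb)
        decision_notes.append(f"applied daily recombination factor {recomb:.4f}")
    if center is None:
        idx = np.unravel_index(np.argmax(psqa_reference.values),
                               psqa_reference.geometry.shape)
        center = (float(psqa_reference.geometry.u_coords[idx[0]]),
                  float(psqa_reference.geometry.t_coords[idx[1]]))
    decision = _qa_pipeline("DQA", psqa_reference, daily, center,
                            five_spot_image, five_spot_nominal, reference_sizes,
                            dose_rate_samples, arm, laser_ok)
    decision.recombination_factor = recomb
    decision.notes = decision_notes + decision.notes
    if daily_log is not None:
        pauses = detect_pauses(daily_log)
        if pauses.exclusion_recommended:
            decision.notes.append(
                "interlock interruption during UHDR delivery: exclusion from "
                "the UHDR arm recommended")
    return decision
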