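"""Blinding-aware delivery reports.

The trial is blinded on the delivery arm: only the beam current differs
between the conventional and ultra-high-dose-rate arms, so anything that
reveals dose rate, beam current, or the arm label must stay out of the
shareable report until unblinding.  A report therefore has three parts:

* part 1 (shareable): field metadata, setup, 2D dose metrics, prescription
  check, and sanitized QA outcomes;
* part 2 (restricted): dose-rate maps and statistics, irradiation times,
  measured point dose rates, the arm label, log references;
* part 3 (restricted): raw PSQA/DQA results.

A blinded report *omits* the restricted parts at construction — they are not
merely hidden — and its part 1 carries no dose-rate values, beam-current
values, or arm labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .deliverylog import DeliveryLog
from .grids import DoseGrid, DoseRateGrid
from .plans import SimplePlan
from .qa import QADecision
from .reconstruction import _beam_on
from .tps import plan_total_dose

__all__ = ["TreatmentReport", "build_report", "irradiation_time_ms"]

#: decision-summary keys that reveal dose rate (stripped when blinded)
_RESTRICTED_DECISION_KEYS = ("dose_rate_check_pass", "dose_rate_samples_gy_s",
                             "recombination_factor")


def irradiation_time_ms(log: DeliveryLog) -> float:
    """Irradiation time of one field: last beam-on sample − first (ms)."""
    _, on = _beam_on(log, None)
    idx = np.nonzero(on)[0]
    if idx.size == 0:
        return 0.0
    return float(log.t_ms[idx[-1]] - log.t_ms[idx[0]])


@dataclass
class TreatmentReport:
    part1: dict
    part2: dict | None
    part3: dict | None
    blinded: bool

    def to_json(self, indent: int = 1) -> str:
        obj = {"blinded": self.blinded, "part1": self.part1}
        if not self.blinded:
            obj["part2"] = self.part2
            obj["part3"] = self.part3
        return json.dumps(obj, indent=indent)

    def to_markdown(self) -> str:
        lines = [f"# Delivery report — field {self.part1['field']['field_id']}",
                 f"*Blinded:* {self.blinded}", "",
                 "## Part 1 — plan and dose evaluation (shareable)"]
        lines += _dict_to_md(self.part1)
        if not self.blinded:
            lines += ["", "## Part 2 — dose rate and delivery time (restricted)"]
            lines += _dict_to_md(self.part2 or {})
            lines += ["", "## Part 3 — QA raw results (restricted)"]
            lines += _dict_to_md(self.part3 or {})
        return "\n".join(lines) + "\n"


def _dict_to_md(d: dict, indent: int = 0) -> list[str]:
    lines = []
    for k, v in d.items():
        pad = "  " * indent
        if isinstance(v, dict):
            lines.append(f"{pad}- **{k}**:")
            lines += _dict_to_md(v, indent + 1)
        else:
            lines.append(f"{pad}- **{k}**: {v}")
    return lines


def _rate_stats(grid: DoseRateGrid) -> dict:
    vals = grid.values[grid.valid_mask]
    if vals.size == 0:
        return {"valid_voxels": 0}
    return {"valid_voxels": int(vals.size),
            "min_gy_s": float(vals.min()),
            "mean_gy_s": float(vals.mean()),
            "max_gy_s": float(vals.max())}


def _sanitize_decision(summary: dict) -> dict:
    """Strip dose-rate content from a QA decision summary."""
    out = {k: v for k, v in summary.items() if k not in _RESTRICTED_DECISION_KEYS}
    out["notes"] = [n for n in out.get("notes", [])
                    if "Gy/s" not in n and "dose rate" not in n.lower()
                    and "recombination" not in n.lower() and "UHDR" not in n]
    return out


def build_report(plan: SimplePlan, decisions: list[QADecision] | None = None,
                 dose_map: DoseGrid | None = None,
                 dose_rate_maps: dict[str, DoseRateGrid] | None = None,
                 logs: list[DeliveryLog] | None = None,
                 point_dose_rates: list[float] | None = None,
                 arm: str | None = None,
                 setup_metadata: dict | None = None,
                 blinded: bool = False) -> TreatmentReport:
    """Assemble a treatment delivery report.

    3D plan metrics (DVH, V95, D98, D5–D95) require patient CT data and are
    reported as "not computed"; the 2D field metrics within the 90% isodose
    area stand in for them.  Setup/physiology metadata are pass-through
    strings, never computed.
    """
    if dose_map is None:
        raise ValueError("a report needs at least the 2D dose map")
    decisions = decisions or []

    mask = dose_map.isodose_mask(0.9)
    in_mask = dose_map.values[mask]
    center = dose_map.geometry.index_of(
        float(np.mean(dose_map.geometry.u_coords)),
        float(np.mean(dose_map.geometry.t_coords)))
    part1 = {
        "field": {
            "field_id": plan.field_id,
            "gantry_angle_deg": plan.gantry_angle,
            "couch_angle_deg": plan.couch_angle,
            "spots": plan.n_spots,
        },
        "setup": setup_metadata or {},
        "prescription": {
            "fractions": plan.fractions,
            "fraction_dose_gy": plan.fraction_dose,
            "total_dose_gy": plan_total_dose(plan),
        },
        "dose_2d": {
            "min_gy_90pct_isodose": float(in_mask.min()),
            "mean_gy_90pct_isodose": float(in_mask.mean()),
            "max_gy_90pct_isodose": float(in_mask.max()),
            "reference_point_dose_gy": float(dose_map.values[center]),
            "dvh_metrics": "not computed (require 3D patient data)",
        },
        "qa_decisions": [
            (_sanitize_decision(d.summary()) if blinded else d.summary())
            for d in decisions
        ],
    }

    if blinded:
        return TreatmentReport(part1=part1, part2=None, part3=None, blinded=True)

    part2 = {
        "arm": arm or "",
        "dose_rate_maps": {name: _rate_stats(g)
                           for name, g in (dose_rate_maps or {}).items()},
        "irradiation_time_ms": [irradiation_time_ms(lg) for lg in (logs or [])],
        "point_dose_rates_gy_s": list(point_dose_rates or []),
        "log_files": [lg.field_id for lg in (logs or [])],
    }
    part3 = {"qa_raw": [d.summary() for d in decisions]}
    return TreatmentReport(part1=part1, part2=part2, part3=part3, blinded=False)
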