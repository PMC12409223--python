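"""Time-resolved machine delivery log: data model, validation, file format.

One log records a single field delivery at 1 kHz: two cumulative dose-monitor
channels (MU), two raw Hall-probe readings (one per scanning magnet), and
timestamps quantized to 0.1 ms.  Sampling starts when the field is loaded,
before any beam is on, so leading samples typically carry zero dose.

File dialect (UTF-8 text)::

    #FLASHQA-LOG v1
    {"field_id": ..., "gantry_angle": ..., ...}
    t_ms,mon1,mon2,hallU,hallT
    0.0,0,0,-0.25,-0.25
    ...

The header JSON is a single line; t_ms is printed with exactly one decimal
digit; monitor and Hall values are printed at full float precision so a
write/read cycle is lossless.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, TextIO

import numpy as np

__all__ = ["LogSample", "DeliveryLog", "LogParseError", "LogValidationError",
           "read_log", "write_log", "validate_log", "monitor_consistency"]

MAGIC = "#FLASHQA-LOG v1"
COLUMNS = "t_ms,mon1,mon2,hallU,hallT"

#: allowed deviation of inter-sample spacing from the nominal period (ms)
SPACING_TOL_MS = 0.05
#: timestamp quantization (ms)
TIME_QUANTUM_MS = 0.1
#: relative |mon1 - mon2| above which monitor consistency is questionable
MONITOR_WARN_REL = 0.01


class LogParseError(ValueError):
    """Malformed log file (names the offending line)."""


class LogValidationError(ValueError):
    """A DeliveryLog invariant is violated."""


class LogSample(NamedTuple):
    t: float      # ms since field load, multiple of 0.1 ms
    mon1: float   # cumulative MU, monitor 1
    mon2: float   # cumulative MU, monitor 2
    hallU: float  # raw Hall reading, U magnet (sensor units)
    hallT: float  # raw Hall reading, T magnet (sensor units)


@dataclass
class DeliveryLog:
    """One field delivery's machine record.

    Sample channels are stored as parallel numpy arrays; the ``samples``
    property iterates row records.  Monitor channels are cumulative and must
    be non-decreasing; sample times start at field load and are strictly
    increasing with the nominal period.
    """

    field_id: str
    gantry_angle: float
    couch_angle: float
    arm: str                       # "CONV" or "UHDR"
    sample_period_ms: float = 1.0
    t_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    mon1: np.ndarray = field(default_factory=lambda: np.empty(0))
    mon2: np.ndarray = field(default_factory=lambda: np.empty(0))
    hallU: np.ndarray = field(default_factory=lambda: np.empty(0))
    hallT: np.ndarray = field(default_factory=lambda: np.empty(0))
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("t_ms", "mon1", "mon2", "hallU", "hallT"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_ms)
        if any(len(getattr(self, name)) != n for name in ("mon1", "mon2", "hallU", "hallT")):
            raise ValueError("log channels must have equal length")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def samples(self) -> Iterator[LogSample]:
        for row in zip(self.t_ms, self.mon1, self.mon2, self.hallU, self.hallT):
            yield LogSample(*row)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DeliveryLog):
            return NotImplemented
        return (self.field_id == other.field_id
                and self.gantry_angle == other.gantry_angle
                and self.couch_angle == other.couch_angle
                and self.arm == other.arm
                and self.sample_period_ms == other.sample_period_ms
                and self.annotations == other.annotations
                and all(np.array_equal(getattr(self, n), getattr(other, n))
                        for n in ("t_ms", "mon1", "mon2", "hallU", "hallT")))


def validate_log(log: DeliveryLog) -> list[str]:
    """Check all DeliveryLog invariants; return violations (empty iff valid).

    Reported, not raised, so callers can collect every problem at once.
    """
    violations: list[str] = []
    if log.arm not in ("CONV", "UHDR"):
        violations.append(f"arm must be CONV or UHDR, got {log.arm!r}")
    if log.sample_period_ms <= 0:
        violations.append("sample_period_ms must be positive")
    t = log.t_ms
    if len(t) and t[0] < 0:
        violations.append("sample times must be non-negative")
    # 0.1 ms quantization
    offgrid = np.nonzero(np.abs(t / TIME_QUANTUM_MS - np.round(t / TIME_QUANTUM_MS)) > 1e-6)[0]
    if offgrid.size:
        violations.append(
            f"timestamp not a multiple of {TIME_QUANTUM_MS} ms at sample {offgrid[0]}")
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.nonzero(np.abs(dt - log.sample_period_ms) > SPACING_TOL_MS)[0]
        if np.any(dt <= 0):
            violations.append(
                f"sample times not strictly increasing at sample {int(np.nonzero(dt <= 0)[0][0]) + 1}")
        elif bad.size:
            violations.append(
                f"sample spacing {dt[bad[0]]:.3g} ms deviates from nominal "
                f"{log.sample_period_ms} ms at sample {int(bad[0]) + 1}")
    for name in ("mon1", "mon2"):
        ch = getattr(log, name)
        if np.any(ch < 0):
            violations.append(f"monitor channel {name} has negative counts")
        dec = np.nonzero(np.diff(ch) < 0)[0]
        if dec.size:
            violations.append(
                f"monitor channel {name} not monotone at sample {int(dec[0]) + 1}")
    return violations


def monitor_consistency(log: DeliveryLog) -> float:
    """Relative |mon1 − mon2| difference of the final cumulative counts.

    The two monitors are independent; a relative difference above
    ``MONITOR_WARN_REL`` (1%) should be treated as a warning.
    """
    if len(log) == 0 or log.mon1[-1] == 0:
        return 0.0
    return abs(log.mon1[-1] - log.mon2[-1]) / log.mon1[-1]


def _format_float(x: float) -> str:
    return repr(float(x))


def write_log(log: DeliveryLog, path: str | Path | TextIO) -> None:
    """Write a log in the v1 text dialect (lossless round trip)."""
    if validate_log(log):
        raise LogValidationError("; ".join(validate_log(log)))
    header = {
        "field_id": log.field_id,
        "gantry_angle": log.gantry_angle,
        "couch_angle": log.couch_angle,
        "arm": log.arm,
        "sample_period_ms": log.sample_period_ms,
        "annotations": log.annotations,
    }
    own = isinstance(path, (str, Path))
    fh: TextIO = open(path, "w", encoding="utf-8") if own else path  # type: ignore[arg-type]
    try:
        fh.write(MAGIC + "\n")
        fh.write(json.dumps(header) + "\n")
        fh.write(COLUMNS + "\n")
        for s in log.samples:
            fh.write(f"{s.t:.1f},{_format_float(s.mon1)},{_format_float(s.mon2)},"
                     f"{_format_float(s.hallU)},{_format_float(s.hallT)}\n")
    finally:
        if own:
            fh.close()


def read_log(path: str | Path | TextIO) -> DeliveryLog:
    """Read and validate a v1 log file.

    Raises :class:`LogParseError` on malformed content (naming the line) and
    :class:`LogValidationError` if any invariant fails.
    """
    own = isinstance(path, (str, Path))
    fh: TextIO = open(path, "r", encoding="utf-8") if own else path  # type: ignore[arg-type]
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    if not lines or lines[0].strip() != MAGIC:
        raise LogParseError(f"line 1: expected magic '{MAGIC}'")
    if len(lines) < 3:
        raise LogParseError("line 2-3: missing header JSON or column line")
    try:
        header = json.loads(lines[1])
    except json.JSONDecodeError as exc:
        raise LogParseError(f"line 2: invalid header JSON ({exc})") from exc
    if lines[2].strip() != COLUMNS:
        raise LogParseError(f"line 3: expected column header '{COLUMNS}'")
    rows = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 5:
            raise LogParseError(f"line {lineno}: expected 5 fields, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise LogParseError(f"line {lineno}: non-numeric field ({exc})") from exc
    data = np.array(rows, dtype=float).reshape(-1, 5)
    try:
        log = DeliveryLog(
            field_id=str(header["field_id"]),
            gantry_angle=float(header["gantry_angle"]),
            couch_angle=float(header["couch_angle"]),
            arm=str(header["arm"]),
            sample_period_ms=float(header.get("sample_period_ms", 1.0)),
            t_ms=data[:, 0], mon1=data[:, 1], mon2=data[:, 2],
            hallU=data[:, 3], hallT=data[:, 4],
            annotations=list(header.get("annotations", [])),
        )
    except KeyError as exc:
        raise LogParseError(f"line 2: header missing key {exc}") from exc
    violations = validate_log(log)
    if violations:
        raise LogValidationError("; ".join(violations))
    return log
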