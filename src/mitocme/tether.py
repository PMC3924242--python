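"""Tether-force analysis for optical-trap membrane-tension measurements.

A polystyrene bead held in an optical trap is attached to the plasma
membrane and the cell is moved away to pull a thin membrane tether.  The
displacement of the bead from the trap centre (``dx``, nm) times the
calibrated trap stiffness (``k``, pN/nm) is the tether force (pN), which is
proportional to the apparent plasma-membrane tension.  A zero-force
reference is obtained by moving the cell back toward the bead, which
relaxes the tether.

This module converts annotated displacement traces into per-cell tether
forces with the quality-control rules used for live-cell work:

* the force is the 1-s average immediately before the stage manipulation,
  minus the zero-reference average;
* measurements taken more than 30 s after tether formation are flagged
  (actin polymerises into old tethers and corrupts the reading);
* occasional double tethers give a twofold force from the same cell and
  are flagged and excluded;
* forces are optionally expressed relative to the mean interphase force
  of the same experiment, so that experiments can be pooled.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "EVENT_TETHER_FORMED",
    "EVENT_TOWARD",
    "EVENT_AWAY",
    "TetherTrace",
    "TetherMeasurement",
    "RelativeForce",
    "DegenerateSegmentError",
    "calibrate_stiffness",
    "force_trace",
    "locate_zero_reference",
    "measure_tether_force",
    "flag_double_tethers",
    "relative_forces",
    "save_trace",
    "load_trace",
]

#: Boltzmann constant in pN nm / K (1e-21 J = 1 pN nm).
BOLTZMANN_PN_NM_PER_K = 1.380649e-2

EVENT_TETHER_FORMED = "tether_formed"
EVENT_TOWARD = "stage_toward_cell_contact"
EVENT_AWAY = "stage_away"

FLAG_STALE = "stale_tether"
FLAG_DOUBLE = "double_tether"
FLAG_NO_ZERO = "no_zero_reference"


class DegenerateSegmentError(ValueError):
    """Raised when a calibration segment has zero positional variance."""


@dataclass
class TetherTrace:
    """A timestamped bead-displacement record with stage-event annotations.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing.
    displacement : array of float
        Bead displacement from the trap centre in nm.
    events : sequence of (float, str)
        Stage/tether events, ``(time_s, label)``.
    stiffness : float
        Calibrated trap stiffness in pN/nm (> 0).
    """

    time: np.ndarray
    displacement: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)
    stiffness: float = float("nan")
    cell_id: str = ""
    experiment_id: str = ""
    phase: str = "interphase"
    tether_formed_at: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.displacement.shape:
            raise ValueError("time and displacement must be 1-D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not math.isnan(self.stiffness) and self.stiffness <= 0:
            raise ValueError("stiffness must be positive")
        t0, t1 = self.span
        for t, label in self.events:
            if not (t0 <= t <= t1):
                raise ValueError(f"event {label!r} at {t} s lies outside trace span")
        if self.tether_formed_at is None:
            for t, label in self.events:
                if label == EVENT_TETHER_FORMED:
                    self.tether_formed_at = t
                    break

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def events_with_label(self, label: str) -> list[float]:
        return [t for t, lab in self.events if lab == label]


@dataclass
class TetherMeasurement:
    """One cell's tether force with QC flags.

    ``force`` is plateau mean minus baseline mean, in pN.  Measurements
    with any QC flag are excluded from group summaries.
    """

    force: float
    baseline: float
    plateau_window: tuple[float, float]
    baseline_window: tuple[float, float]
    qc_flags: set[str] = field(default_factory=set)
    cell_id: str = ""
    experiment_id: str = ""
    phase: str = "interphase"

    @property
    def ok(self) -> bool:
        return not self.qc_flags


@dataclass
class RelativeForce:
    """Tether force relative to the mean interphase force of its experiment."""

    value: float
    cell_id: str = ""
    experiment_id: str = ""
    phase: str = "interphase"


def calibrate_stiffness(no_load_segment: Sequence[float], temperature: float = 298.0) -> float:
    """Equipartition trap-stiffness calibration from a tether-free segment.

    The trapped bead is a harmonic oscillator, so each quadratic degree of
    freedom carries ``kB*T/2`` of thermal energy: ``k = kB*T / var(x)``.

    Parameters
    ----------
    no_load_segment : array of float
        Bead displacement (nm) with no tether attached; >= 1000 samples.
    temperature : float
        Absolute temperature in kelvin.

    Returns
    -------
    float
        Trap stiffness in pN/nm.
    """
    x = np.asarray(no_load_segment, dtype=float)
    if x.size < 1000:
        raise ValueError(f"need >= 1000 samples for calibration, got {x.size}")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    var = float(np.var(x, ddof=1))
    if var <= 0:
        raise DegenerateSegmentError("calibration segment has zero variance")
    return BOLTZMANN_PN_NM_PER_K * temperature / var


def force_trace(trace: TetherTrace) -> np.ndarray:
    """Pointwise force (pN): stiffness times displacement."""
    if math.isnan(trace.stiffness):
        raise ValueError("trace has no stiffness set")
    return trace.stiffness * trace.displacement


def locate_zero_reference(
    trace: TetherTrace,
    settling_margin: float = 0.2,
    averaging_span: float = 1.0,
) -> tuple[tuple[float, float], set[str]]:
    """Find the zero-force reference window of a trace.

    The window runs from the toward-cell stage event plus a settling
    margin (stage-motion transients) to the subsequent away event.  When
    the events are absent a changepoint fallback proposes the window with
    the lowest rolling mean, and the ``no_zero_reference`` flag is
    attached.

    Returns
    -------
    (t_start, t_end), flags
    """
    toward = trace.events_with_label(EVENT_TOWARD)
    away = trace.events_with_label(EVENT_AWAY)
    flags: set[str] = set()
    if toward:
        t_on = toward[0]
        later = [t for t in away if t > t_on]
        t_off = later[0] if later else trace.span[1]
        window = (t_on + settling_margin, t_off)
    else:
        flags.add(FLAG_NO_ZERO)
        window = _lowest_mean_window(trace, averaging_span)
    if window[1] - window[0] < averaging_span:
        raise ValueError(
            f"zero-reference window {window} shorter than averaging span {averaging_span} s"
        )
    return window, flags


def _lowest_mean_window(trace: TetherTrace, span: float) -> tuple[float, float]:
    """Changepoint fallback: the span-long window with the lowest mean."""
    dt = float(np.median(np.diff(trace.time))) if trace.time.size > 1 else span
    w = max(1, int(round(span / dt)))
    if w >= trace.time.size:
        return trace.span
    csum = np.cumsum(np.insert(trace.displacement, 0, 0.0))
    means = (csum[w:] - csum[:-w]) / w
    i = int(np.argmin(means))
    return float(trace.time[i]), float(trace.time[min(i + w, trace.time.size - 1)])


def _window_mean(trace: TetherTrace, values: np.ndarray, window: tuple[float, float]) -> float:
    lo, hi = window
    sel = (trace.time >= lo) & (trace.time < hi)
    if not sel.any():
        raise ValueError(f"window {window} contains no samples")
    return float(values[sel].mean())


def measure_tether_force(
    trace: TetherTrace,
    averaging_span: float = 1.0,
    max_tether_age: float = 30.0,
    settling_margin: float = 0.2,
) -> TetherMeasurement:
    """Measure one tether force from an annotated trace.

    The plateau window is the ``averaging_span`` seconds immediately
    preceding the first stage manipulation after tether formation; the
    force is its mean minus the zero-reference mean.  The ``stale_tether``
    flag is set when the plateau window ends more than ``max_tether_age``
    seconds after tether formation.
    """
    f = force_trace(trace)
    t_formed = trace.tether_formed_at
    stage_times = sorted(
        t for t, lab in trace.events
        if lab in (EVENT_TOWARD, EVENT_AWAY) and (t_formed is None or t > t_formed)
    )
    if not stage_times:
        raise ValueError("no stage-manipulation event to anchor the plateau window")
    t_anchor = stage_times[0]
    plateau = (t_anchor - averaging_span, t_anchor)
    if plateau[0] < trace.span[0]:
        raise ValueError("plateau window extends before trace start")

    baseline_window, flags = locate_zero_reference(trace, settling_margin, averaging_span)
    plateau_mean = _window_mean(trace, f, plateau)
    baseline_mean = _window_mean(trace, f, baseline_window)

    if t_formed is not None and plateau[1] - t_formed > max_tether_age:
        flags.add(FLAG_STALE)

    return TetherMeasurement(
        force=plateau_mean - baseline_mean,
        baseline=baseline_mean,
        plateau_window=plateau,
        baseline_window=baseline_window,
        qc_flags=flags,
        cell_id=trace.cell_id,
        experiment_id=trace.experiment_id,
        phase=trace.phase,
    )


def flag_double_tethers(
    measurements: Iterable[TetherMeasurement],
    tolerance: float = 0.15,
) -> list[TetherMeasurement]:
    """Flag measurements consistent with a double tether.

    Double tethers pulled by a single bead give a twofold force from the
    same cell.  A measurement is flagged when its force lies within
    ``tolerance`` (fractional) of twice the median of the cell's other
    unflagged measurements.  Externally annotated double tethers (flag
    already present) are honoured regardless of ratio.  Candidates are
    examined largest-first so a genuine double does not inflate the
    median it is compared against.
    """
    measurements = list(measurements)
    by_cell: dict[str, list[TetherMeasurement]] = {}
    for m in measurements:
        by_cell.setdefault(m.cell_id, []).append(m)
    for cell_ms in by_cell.values():
        for m in sorted(cell_ms, key=lambda m: -m.force):
            if FLAG_DOUBLE in m.qc_flags:
                continue
            others = [x.force for x in cell_ms if x is not m and FLAG_DOUBLE not in x.qc_flags]
            if not others:
                continue
            ref = 2.0 * float(np.median(others))
            if ref > 0 and abs(m.force - ref) <= tolerance * ref:
                m.qc_flags.add(FLAG_DOUBLE)
    return measurements


def relative_forces(measurements: Iterable[TetherMeasurement]) -> list[RelativeForce]:
    """Express each unflagged force relative to the mean unflagged
    interphase force of the same experiment.

    By construction the interphase values of one experiment average to
    exactly 1.
    """
    measurements = [m for m in measurements if m.ok]
    by_exp: dict[str, list[TetherMeasurement]] = {}
    for m in measurements:
        by_exp.setdefault(m.experiment_id, []).append(m)
    out: list[RelativeForce] = []
    for exp, group in by_exp.items():
        inter = [m.force for m in group if m.phase == "interphase"]
        if not inter:
            raise ValueError(f"experiment {exp!r} has no unflagged interphase measurement")
        ref = float(np.mean(inter))
        for m in group:
            out.append(RelativeForce(m.force / ref, m.cell_id, m.experiment_id, m.phase))
    return out


# ---------------------------------------------------------------------------
# Trace CSV dialect: <name>.csv with header time_s,displacement_nm and a
# sidecar <name>.events.csv with header time_s,event.

def save_trace(trace: TetherTrace, path: str | Path) -> tuple[Path, Path]:
    path = Path(path)
    events_path = path.with_suffix(".events.csv")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "displacement_nm"])
        for t, x in zip(trace.time, trace.displacement):
            w.writerow([f"{t:.6f}", f"{x:.6f}"])
    with open(events_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "event"])
        for t, label in trace.events:
            w.writerow([f"{t:.6f}", label])
    return path, events_path


def load_trace(
    path: str | Path,
    events_path: str | Path | None = None,
    stiffness: float = float("nan"),
    cell_id: str = "",
    experiment_id: str = "",
    phase: str = "interphase",
) -> TetherTrace:
    path = Path(path)
    if events_path is None:
        events_path = path.with_suffix(".events.csv")
    data = np.genfromtxt(path, delimiter=",", names=True)
    events: list[tuple[float, str]] = []
    events_path = Path(events_path)
    if events_path.exists():
        with open(events_path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader, None)
            for row in reader:
                if row:
                    events.append((float(row[0]), row[1]))
    return TetherTrace(
        time=data["time_s"],
        displacement=data["displacement_nm"],
        events=events,
        stiffness=stiffness,
        cell_id=cell_id,
        experiment_id=experiment_id,
        phase=phase,
    )
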