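"""Eye-position processing: resampling, blink repair, saccade/fixation
segmentation, drift-correction mode finding, and saccade-goal labels.

Conventions: time in ms, position in degrees of visual angle from the
screen centre (x rightward, y upward), directions in degrees polar
angle.  Saccades are detected on a 200 Hz trace as maximal spans above
a 50 deg/s velocity criterion with at least 1 deg amplitude; the
intervals between them are fixations, analysed only when they last at
least 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GazeTrace",
    "SaccadeEvent",
    "FixationEvent",
    "GoalLabel",
    "resample_gaze",
    "interpolate_blinks",
    "detect_saccades",
    "extract_fixations",
    "mean_shift_mode",
    "label_saccade_goal",
    "angdiff",
]


@dataclass
class GazeTrace:
    """Uniformly sampled eye-position trace."""

    t: np.ndarray  # ms, strictly increasing, uniform
    x: np.ndarray  # deg
    y: np.ndarray  # deg
    valid: np.ndarray | None = None  # False during blinks/track loss

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t.shape == self.x.shape == self.y.shape == self.valid.shape):
            raise ValueError("t, x, y, valid must share one shape")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if self.t.size > 1 else float("nan")

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.dt

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.t, "x_deg": self.x,
                             "y_deg": self.y, "valid": self.valid.astype(int)})

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "GazeTrace":
        return GazeTrace(df["time_ms"].to_numpy(float), df["x_deg"].to_numpy(float),
                         df["y_deg"].to_numpy(float),
                         df["valid"].to_numpy(int).astype(bool) if "valid" in df else None)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read(path: str | Path) -> "GazeTrace":
        return GazeTrace.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class SaccadeEvent:
    t_on: float
    t_off: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    amplitude: float  # deg, start-to-end displacement
    direction: float  # deg polar angle of the displacement
    peak_velocity: float = float("nan")  # deg/s

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ValueError("t_off must exceed t_on")


@dataclass
class FixationEvent:
    t_on: float
    t_off: float
    xy: tuple[float, float]  # mean gaze position
    next_saccade: SaccadeEvent | None = None
    excluded: bool = False  # True when shorter than the analysis cutoff

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass(frozen=True)
class GoalLabel:
    """Next-saccade direction relative to the RF: 'in', 'opposite' or
    'other' (dropped from the goal analysis)."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in ("in", "opposite", "other"):
            raise ValueError("goal label must be in/opposite/other")


def resample_gaze(trace: GazeTrace, target_rate_hz: float = 200.0) -> GazeTrace:
    """Decimate a native-rate trace to the analysis rate (no smoothing).

    The native rate must be an integer multiple of the target.  Each
    output sample is the native sample at that instant; an output
    sample is invalid when any native sample in its interval is
    invalid, so blink spans propagate.
    """
    dts = np.diff(trace.t)
    if dts.size and (dts.max() - dts.min()) > 1e-6 * dts.mean():
        gaps = np.flatnonzero(np.abs(dts - np.median(dts)) > 1e-6 * np.median(dts))
        raise ValueError(
            f"non-uniform timestamps; {gaps.size} gap(s), first at index {gaps[0]} "
            f"(t={trace.t[gaps[0]]:.3f} ms, dt={dts[gaps[0]]:.3f} ms)")
    native = trace.rate_hz
    factor = native / target_rate_hz
    if factor < 1 or abs(factor - round(factor)) > 1e-6:
        raise ValueError("target rate must divide the native rate")
    f = int(round(factor))
    n_out = trace.t.size // f
    valid = trace.valid[:n_out * f].reshape(n_out, f).all(axis=1)
    sl = slice(0, n_out * f, f)
    return GazeTrace(trace.t[sl], trace.x[sl], trace.y[sl], valid)


def interpolate_blinks(trace: GazeTrace) -> GazeTrace:
    """Fill invalid interior spans by linear interpolation between the
    flanking valid samples.  Spans touching either end of the trace
    have no flank on one side and stay invalid."""
    v = trace.valid
    if v.all():
        return replace(trace)
    x = trace.x.copy()
    y = trace.y.copy()
    valid = v.copy()
    idx = np.flatnonzero(v)
    if idx.size >= 2:
        interior = np.zeros_like(v)
        interior[idx[0]:idx[-1] + 1] = True
        fill = (~v) & interior
        x[fill] = np.interp(trace.t[fill], trace.t[v], trace.x[v])
        y[fill] = np.interp(trace.t[fill], trace.t[v], trace.y[v])
        valid[fill] = True
    return GazeTrace(trace.t.copy(), x, y, valid)


def _velocity(trace: GazeTrace, smooth: int = 2) -> np.ndarray:
    """Speed in deg/s by central differences with a short boxcar
    (the criterion threshold is the only part that is prescribed)."""
    dt_s = trace.dt / 1000.0
    vx = np.gradient(trace.x, trace.t / 1000.0)
    vy = np.gradient(trace.y, trace.t / 1000.0)
    if smooth > 1:
        k = np.ones(smooth) / smooth
        vx = np.convolve(vx, k, mode="same")
        vy = np.convolve(vy, k, mode="same")
    del dt_s
    return np.hypot(vx, vy)


def detect_saccades(trace: GazeTrace, vel_thresh: float = 50.0,
                    min_amp: float = 1.0) -> list[SaccadeEvent]:
    """Saccades as maximal supra-threshold velocity spans whose
    start-to-end displacement reaches the minimum amplitude."""
    if len(trace) < 3:
        return []
    speed = _velocity(trace)
    above = speed >= vel_thresh
    events: list[SaccadeEvent] = []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(trace))
    for s, e in zip(starts, ends):
        e = min(e, len(trace) - 1)
        if e <= s:
            continue
        dx = trace.x[e] - trace.x[s]
        dy = trace.y[e] - trace.y[s]
        amp = float(np.hypot(dx, dy))
        if amp < min_amp:
            continue
        events.append(SaccadeEvent(
            t_on=float(trace.t[s]), t_off=float(trace.t[e]),
            start_xy=(float(trace.x[s]), float(trace.y[s])),
            end_xy=(float(trace.x[e]), float(trace.y[e])),
            amplitude=amp, direction=float(np.rad2deg(np.arctan2(dy, dx))),
            peak_velocity=float(speed[s:e + 1].max()),
        ))
    return events


def extract_fixations(trace: GazeTrace, saccades: list[SaccadeEvent],
                      min_dur: float = 200.0) -> list[FixationEvent]:
    """Inter-saccadic intervals as fixations.

    Fixations shorter than ``min_dur`` are kept but flagged
    ``excluded``; the final interval (no terminating saccade) keeps
    ``next_saccade=None`` and is ineligible for goal labelling.
    """
    if len(trace) == 0:
        return []
    bounds: list[tuple[float, float, SaccadeEvent | None]] = []
    t0 = float(trace.t[0])
    for sac in sorted(saccades, key=lambda s: s.t_on):
        if sac.t_on > t0:
            bounds.append((t0, sac.t_on, sac))
        t0 = sac.t_off
    if trace.t[-1] > t0:
        bounds.append((t0, float(trace.t[-1]), None))
    out = []
    for t_on, t_off, sac in bounds:
        m = (trace.t >= t_on) & (trace.t <= t_off)
        xy = (float(trace.x[m].mean()), float(trace.y[m].mean())) if m.any() else (np.nan, np.nan)
        out.append(FixationEvent(t_on=t_on, t_off=t_off, xy=xy, next_saccade=sac,
                                 excluded=(t_off - t_on) < min_dur))
    return out


def mean_shift_mode(points: np.ndarray, bandwidth: float = 0.5,
                    max_bandwidth: float = 0.75, step: float = 0.05,
                    tol: float = 1e-6, max_iter: int = 200):
    """Dominant-cluster mode of a 2-D point set by mean shift.

    Flat-kernel mean shift is run from every point; converged modes
    within half a bandwidth are merged into clusters.  The mode of the
    largest cluster is returned.  When the two largest clusters tie in
    count, the bandwidth is raised stepwise; if no dominant cluster
    emerges by ``max_bandwidth`` the location is rejected and ``None``
    is returned (a normal, non-exceptional outcome).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    if pts.shape[0] == 1:
        return (float(pts[0, 0]), float(pts[0, 1]))
    for h in np.arange(bandwidth, max_bandwidth + step / 2, step):
        modes = np.empty_like(pts)
        for i, p in enumerate(pts):
            m = p.copy()
            for _ in range(max_iter):
                d2 = np.sum((pts - m) ** 2, axis=1)
                inside = d2 <= h * h
                new = pts[inside].mean(axis=0)
                if np.sum((new - m) ** 2) < tol * tol:
                    m = new
                    break
                m = new
            modes[i] = m
        # merge modes into clusters
        labels = -np.ones(len(pts), dtype=int)
        centres: list[np.ndarray] = []
        for i, m in enumerate(modes):
            for j, c in enumerate(centres):
                if np.sum((m - c) ** 2) <= (h / 2) ** 2:
                    labels[i] = j
                    break
            else:
                labels[i] = len(centres)
                centres.append(m)
        counts = np.bincount(labels)
        order = np.argsort(counts)[::-1]
        if len(order) == 1 or counts[order[0]] > counts[order[1]]:
            members = labels == order[0]
            mode = modes[members].mean(axis=0)
            return (float(mode[0]), float(mode[1]))
    return None


def angdiff(a_deg, b_deg):
    """Signed smallest angular difference a - b in (-180, 180]."""
    return -((b_deg - a_deg + 180.0) % 360.0 - 180.0)


def label_saccade_goal(fix: FixationEvent, rf_centre_xy: tuple[float, float],
                       cone_halfwidth: float = 45.0,
                       mode: str = "cone") -> GoalLabel:
    """Label a fixation by its next-saccade direction relative to the RF.

    The RF is gaze-anchored, so the goal direction is simply the polar
    angle of the RF-centre offset (the direction from the fixation
    position toward where the RF lies on the screen).  With
    ``mode='cone'`` the label is 'in'/'opposite' within symmetric cones
    around that direction and its antipode, 'other' elsewhere; with
    ``mode='hemifield'`` every saccade is labelled by the nearer half.
    """
    if fix.next_saccade is None:
        raise ValueError("fixation has no terminating saccade")
    rx, ry = rf_centre_xy
    ecc = float(np.hypot(rx, ry))
    if ecc < 2.0:
        raise ValueError("RF too close to the fovea (<2 deg eccentricity)")
    goal_dir = float(np.rad2deg(np.arctan2(ry, rx)))
    d = abs(angdiff(fix.next_saccade.direction, goal_dir))
    if mode == "hemifield":
        return GoalLabel("in" if d <= 90.0 else "opposite")
    if d <= cone_halfwidth:
        return GoalLabel("in")
    if d >= 180.0 - cone_halfwidth:
        return GoalLabel("opposite")
    return GoalLabel("other")
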