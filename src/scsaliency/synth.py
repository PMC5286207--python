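"""Synthetic videos, gaze and spikes with known ground truth.

No recordings accompany the study this pipeline targets, so every
stage is exercised on generated data: scripted scenes whose events
carry each of the six feature types (luminance, colour, edges,
flicker, motion), fixation-saccade gaze with realistic duration
statistics (95% of fixation durations within roughly 95-545 ms) and an
optional salience-seeking policy, and inhomogeneous-Poisson spike
trains whose rate follows lagged RF saliency -- gated by the
saccade-goal for intermediate-layer (SCi-like) neurons.  Everything is
deterministic under a seed and emits its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import NeuronData, NeuronRecord, align_windows, spike_density
from .gaze import GazeTrace
from .retina import ScreenGeometry

__all__ = [
    "SceneEvent",
    "SceneScript",
    "SyntheticNeuronSpec",
    "render_clip",
    "simulate_gaze",
    "simulate_spikes",
    "script_saliency",
    "simulate_session",
    "planted_lag_trial",
    "FIX_DUR_MEDIAN_MS",
    "FIX_DUR_LOG_SIGMA",
]

# lognormal fixation durations: median and log-sigma chosen so that the
# central 95% of durations spans ~95-545 ms
FIX_DUR_MEDIAN_MS = 227.5
FIX_DUR_LOG_SIGMA = 0.4457

EVENT_KINDS = ("lum-disk", "colour-disk", "grating", "flicker-patch", "moving-dot")


@dataclass
class SceneEvent:
    onset_ms: float
    duration_ms: float
    x_deg: float
    y_deg: float
    kind: str
    intensity: float = 1.0
    size_deg: float = 4.0
    params: dict = field(default_factory=dict)  # colour, orientation_deg, speed_deg_s, dir_deg

    def active(self, t_ms: float) -> bool:
        return self.onset_ms <= t_ms < self.onset_ms + self.duration_ms

    def position(self, t_ms: float) -> tuple[float, float]:
        if self.kind == "moving-dot" and self.active(t_ms):
            v = self.params.get("speed_deg_s", 10.0)
            d = np.deg2rad(self.params.get("dir_deg", 0.0))
            dt = (t_ms - self.onset_ms) / 1000.0
            return (self.x_deg + v * dt * np.cos(d), self.y_deg + v * dt * np.sin(d))
        return (self.x_deg, self.y_deg)


@dataclass
class SceneScript:
    events: list[SceneEvent] = field(default_factory=list)
    background: float = 0.35  # display-encoded grey level
    texture_amp: float = 0.0  # seeded smooth luminance texture
    drift_deg_s: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self, geom: ScreenGeometry) -> None:
        for ev in self.events:
            if abs(ev.x_deg) > geom.width_deg / 2 or abs(ev.y_deg) > geom.height_deg / 2:
                raise ValueError(f"event at ({ev.x_deg}, {ev.y_deg}) is off-screen")
            if ev.kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {ev.kind!r}")


def _texture(h: int, w: int, amp: float, seed: int) -> np.ndarray:
    if amp <= 0:
        return np.zeros((h, w))
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    tex = gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 24.0, mode="wrap")
    tex /= max(np.abs(tex).max(), 1e-12)
    return amp * tex


def render_clip(script: SceneScript, geom: ScreenGeometry, duration_ms: float,
                fps: float = 60.0, px_per_deg: float = 2.0) -> np.ndarray:
    """Render a scripted scene to display-encoded RGB frames.

    Returns (T, H, W, 3) floats in [0, 1] at the requested working
    resolution; deterministic given the script seed.
    """
    script.validate(geom)
    h = int(round(geom.height_deg * px_per_deg))
    w = int(round(geom.width_deg * px_per_deg))
    n = int(round(duration_ms * fps / 1000.0))
    yy, xx = np.mgrid[0:h, 0:w]
    x_deg = (xx - (w - 1) / 2.0) / px_per_deg
    y_deg = ((h - 1) / 2.0 - yy) / px_per_deg
    tex = _texture(h, w, script.texture_amp, script.seed)
    frames = np.empty((n, h, w, 3))
    for fi in range(n):
        t = fi * 1000.0 / fps
        dx = script.drift_deg_s[0] * t / 1000.0
        dy = script.drift_deg_s[1] * t / 1000.0
        if script.texture_amp > 0:
            base = script.background + np.roll(
                np.roll(tex, int(round(dy * px_per_deg)), axis=0),
                int(round(dx * px_per_deg)), axis=1)
        else:
            base = np.full((h, w), script.background)
        frame = np.repeat(base[..., None], 3, axis=-1).copy()
        for ev in script.events:
            if not ev.active(t):
                continue
            ex, ey = ev.position(t)
            rr = np.hypot(x_deg - ex, y_deg - ey)
            r0 = (ev.size_deg if ev.kind == "moving-dot" else ev.size_deg) / 2.0
            mask = np.clip((r0 - rr) * px_per_deg + 0.5, 0.0, 1.0)
            if ev.kind in ("lum-disk", "moving-dot"):
                patch = np.clip(script.background + ev.intensity, 0, 1)
                col = np.array([patch, patch, patch])
            elif ev.kind == "colour-disk":
                col = np.asarray(ev.params.get("colour", (1.0, 0.1, 0.1)), dtype=float)
                col = np.clip(col * (0.5 + 0.5 * ev.intensity), 0, 1)
            elif ev.kind == "flicker-patch":
                period = max(1, int(ev.params.get("period_frames", 4)))
                hi = (fi // period) % 2 == 0
                v = np.clip(script.background + (ev.intensity if hi else -ev.intensity), 0, 1)
                col = np.array([v, v, v])
            elif ev.kind == "grating":
                th = np.deg2rad(ev.params.get("orientation_deg", 45.0))
                sf = ev.params.get("cycles_per_deg", 0.4)
                phase = np.cos(2 * np.pi * sf * (x_deg * np.cos(th) + y_deg * np.sin(th)))
                g = np.clip(script.background + ev.intensity * 0.5 * phase, 0, 1)
                for c in range(3):
                    frame[..., c] = frame[..., c] * (1 - mask) + g * mask
                continue
            for c in range(3):
                frame[..., c] = frame[..., c] * (1 - mask) + col[c] * mask
        frames[fi] = frame
    return frames


def _strongest_event(script: SceneScript, t_ms: float) -> SceneEvent | None:
    live = [ev for ev in script.events if ev.active(t_ms)]
    if not live:
        return None
    return max(live, key=lambda e: e.intensity)


def simulate_gaze(script: SceneScript, geom: ScreenGeometry, duration_ms: float,
                  rate_hz: float = 200.0, p_salient: float = 0.5,
                  rt_gain: float = 0.05, seed: int = 0,
                  dur_median_ms: float = FIX_DUR_MEDIAN_MS,
                  dur_log_sigma: float = FIX_DUR_LOG_SIGMA):
    """Alternating fixations and 20-40 ms saccades.

    With probability ``p_salient`` the next saccade targets the
    strongest currently scripted event (falling back to a uniform
    location when none is live), else a uniform screen location.
    Fixations that end in an event-directed saccade are shortened by
    ``rt_gain`` (the reaction-time advantage of salient targets).
    Returns (GazeTrace, fixation log DataFrame).
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / rate_hz
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt
    x = np.zeros(n)
    y = np.zeros(n)
    margin = 2.0
    half_w = geom.width_deg / 2 - margin
    half_h = geom.height_deg / 2 - margin
    pos = np.array([0.0, 0.0])
    i = 0
    log = []
    while i < n:
        dur = dur_median_ms * np.exp(dur_log_sigma * rng.standard_normal())
        dur = float(np.clip(dur, 50.0, 1500.0))
        salient_branch = rng.random() < p_salient
        t_end_nominal = t[i] + dur
        ev = _strongest_event(script, t_end_nominal) if salient_branch else None
        if ev is not None:
            dur *= (1.0 - rt_gain)
        n_fix = max(1, int(round(dur / dt)))
        j = min(i + n_fix, n)
        x[i:j] = pos[0]
        y[i:j] = pos[1]
        if ev is not None:
            target = np.array(ev.position(t[i] + dur))
            target[0] = np.clip(target[0], -half_w, half_w)
            target[1] = np.clip(target[1], -half_h, half_h)
        else:
            target = np.array([rng.uniform(-half_w, half_w),
                               rng.uniform(-half_h, half_h)])
        log.append({"t_on": t[i], "t_off": t[min(j, n - 1)], "x": pos[0], "y": pos[1],
                    "salient_branch": bool(ev is not None),
                    "target_x": target[0], "target_y": target[1]})
        i = j
        if i >= n:
            break
        amp = np.linalg.norm(target - pos)
        sac_ms = float(np.clip(20.0 + amp, 20.0, 40.0))
        n_sac = max(1, int(round(sac_ms / dt)))
        k = min(i + n_sac, n)
        # raised-cosine position profile
        u = (np.arange(k - i) + 1) / n_sac
        prof = 0.5 * (1 - np.cos(np.pi * np.clip(u, 0, 1)))
        x[i:k] = pos[0] + (target[0] - pos[0]) * prof
        y[i:k] = pos[1] + (target[1] - pos[1]) * prof
        i = k
        pos = target
    return GazeTrace(t, x, y), pd.DataFrame(log)


def script_saliency(script: SceneScript, fix_log: pd.DataFrame,
                    rf_centre_xy: tuple[float, float], sigma_deg: float = 4.0):
    """Ground-truth RF 'saliency' per fixation.

    The RF is gaze-anchored: during a fixation at (x, y) it covers the
    screen location (x, y) + RF offset.  Each live event contributes
    its intensity through a Gaussian of its distance to that location.
    Returns the per-fixation array (same order as the log).
    """
    log = fix_log.reset_index(drop=True)
    t_mid = 0.5 * (log["t_on"].to_numpy() + log["t_off"].to_numpy())
    px = log["x"].to_numpy() + rf_centre_xy[0]
    py = log["y"].to_numpy() + rf_centre_xy[1]
    out = np.zeros(len(log))
    for ev in script.events:
        live = (t_mid >= ev.onset_ms) & (t_mid < ev.onset_ms + ev.duration_ms)
        if not live.any():
            continue
        ex = np.full(live.sum(), ev.x_deg)
        ey = np.full(live.sum(), ev.y_deg)
        if ev.kind == "moving-dot":
            pos = np.array([ev.position(t) for t in t_mid[live]])
            ex, ey = pos[:, 0], pos[:, 1]
        d2 = (ex - px[live]) ** 2 + (ey - py[live]) ** 2
        out[live] += ev.intensity * np.exp(-d2 / (2 * sigma_deg**2))
    return out


@dataclass
class SyntheticNeuronSpec:
    """Ground-truth response model of a simulated neuron: rate(t) =
    baseline + gain * saliency(t - latency), the gain applying only
    when the upcoming saccade goal is in the RF for SCi-like cells."""

    rf_centre_xy: tuple[float, float] = (8.0, 0.0)
    layer_class: str = "SCs"
    baseline_hz: float = 10.0
    gain_hz: float = 30.0
    latency_ms: float = 50.0
    goal_gated: bool | None = None  # default: True iff SCi
    seed: int = 0

    def __post_init__(self) -> None:
        if not 25.0 <= self.latency_ms <= 125.0:
            raise ValueError("latency must lie in [25, 125] ms")
        if self.baseline_hz < 0 or self.gain_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.goal_gated is None:
            self.goal_gated = self.layer_class == "SCi"


def simulate_spikes(spec: SyntheticNeuronSpec, saliency: np.ndarray,
                    goal_in: np.ndarray | None = None, dt_ms: float = 5.0,
                    seed: int | None = None, clamp_log: list | None = None) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (ms) from a saliency series.

    ``saliency`` is sampled every ``dt_ms``; the rate is the baseline
    plus gain times the latency-shifted saliency, multiplied by the
    goal-in indicator when the spec is goal-gated.  Negative rates are
    clamped to zero (and counted in ``clamp_log`` if given).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sal = np.asarray(saliency, dtype=float)
    gate = np.ones_like(sal) if goal_in is None or not spec.goal_gated \
        else np.asarray(goal_in, dtype=float)
    lag = int(round(spec.latency_ms / dt_ms))
    drive = np.zeros_like(sal)
    if lag < sal.size:
        drive[lag:] = (sal * gate)[:sal.size - lag]
    rate = spec.baseline_hz + spec.gain_hz * drive
    n_neg = int(np.count_nonzero(rate < 0))
    if n_neg and clamp_log is not None:
        clamp_log.append(n_neg)
    rate = np.maximum(rate, 0.0)
    counts = rng.poisson(rate * dt_ms / 1000.0)
    times = []
    for i in np.flatnonzero(counts):
        times.extend(i * dt_ms + rng.uniform(0, dt_ms, counts[i]))
    return np.sort(np.asarray(times))


# ---------------------------------------------------------------------------
# lightweight session generator (no video): the per-fixation statistics
# the condition analyses consume, with full ground truth
# ---------------------------------------------------------------------------

def _fixation_schedule(rng, duration_ms, dur_median_ms, dur_log_sigma):
    rows = []
    t = 0.0
    while t < duration_ms:
        dur = float(np.clip(dur_median_ms * np.exp(dur_log_sigma * rng.standard_normal()),
                            50.0, 1500.0))
        sac = float(rng.uniform(20.0, 40.0))
        if t + dur > duration_ms:
            break
        rows.append((t, t + dur))
        t += dur + sac
    return rows


def simulate_session(n_scs: int = 30, n_sci: int = 25, n_fixations: int = 300,
                     seed: int = 0, baseline_hz: float = 10.0,
                     gain_hz: float = 30.0, latency_ms: float = 50.0,
                     p_goal: tuple[float, float, float] = (0.25, 0.25, 0.5),
                     min_fix_dur_ms: float = 200.0):
    """Synthetic population for parameter-recovery runs.

    Per neuron, fixation-saccade timing is drawn from the calibrated
    duration distribution until at least ``n_fixations`` analysable
    (>= 200 ms) fixations exist; each fixation carries an independent
    uniform RF saliency and an in/opposite/other goal label.  Spikes
    follow each neuron's ground-truth rate model (goal-gated for SCi).
    Returns
    (neurons, ground_truth) where neurons is a list of
    :class:`~scsaliency.analysis.NeuronData`.
    """
    rng = np.random.default_rng(seed)
    neurons: list[NeuronData] = []
    layers = ["SCs"] * n_scs + ["SCi"] * n_sci
    dt = 5.0
    # enough wall time that ~n_fixations fixations survive the cutoff
    keep_frac = 0.55
    duration_ms = (FIX_DUR_MEDIAN_MS * 1.15 + 30.0) * n_fixations / keep_frac
    for ni, layer in enumerate(layers):
        sub = np.random.default_rng(rng.integers(2**31 - 1))
        spec = SyntheticNeuronSpec(
            rf_centre_xy=(8.0, 0.0), layer_class=layer,
            baseline_hz=baseline_hz, gain_hz=gain_hz, latency_ms=latency_ms,
            seed=int(sub.integers(2**31 - 1)))
        fixes = _fixation_schedule(sub, duration_ms, FIX_DUR_MEDIAN_MS, FIX_DUR_LOG_SIGMA)
        n_t = int(duration_ms / dt)
        tgrid = np.arange(n_t) * dt
        sal = np.zeros(n_t)
        gate = np.zeros(n_t)
        rows = []
        goals = sub.choice(["in", "opposite", "other"], size=len(fixes), p=p_goal)
        sals = sub.uniform(0.0, 1.0, size=len(fixes))
        for (t_on, t_off), g, s in zip(fixes, goals, sals):
            m = (tgrid >= t_on) & (tgrid < t_off)
            sal[m] = s
            gate[m] = 1.0 if g == "in" else 0.0
            rows.append({"t_on": t_on, "t_off": t_off, "duration": t_off - t_on,
                         "saliency": s, "goal": g})
        spikes = simulate_spikes(spec, sal, gate, dt_ms=dt)
        t_d, dens = spike_density(spikes, duration_ms, kernel="epsp")
        df = pd.DataFrame(rows)
        df = df[df["duration"] >= min_fix_dur_ms].reset_index(drop=True)
        t_fix, dfix = align_windows(dens, t_d, df["t_on"].to_numpy(), (-100.0, 500.0))
        t_sac, dsac = align_windows(dens, t_d, df["t_off"].to_numpy(), (-300.0, 100.0))
        m_ep = (t_fix >= 0) & (t_fix < 200.0)
        df["rate"] = np.nanmean(dfix[:, m_ep], axis=1)
        rec = NeuronRecord(id=f"{layer}-{ni:03d}", rf_centre_xy=spec.rf_centre_xy,
                           layer_class=layer, visual_flag=True,
                           motor_flag=(layer == "SCi"))
        neurons.append(NeuronData(record=rec, samples=df, t_fix=t_fix, dens_fix=dfix,
                                  t_sac=t_sac, dens_sac=dsac,
                                  extras={"spec": spec, "n_spikes": spikes.size}))
    truth = {"baseline_hz": baseline_hz, "gain_hz": gain_hz,
             "latency_ms": latency_ms, "seed": seed}
    return neurons, truth


def behavioural_session(duration_ms: float = 180_000.0, event_every_ms: float = 900.0,
                        rf_centre_xy: tuple[float, float] = (8.0, 0.0),
                        p_salient: float = 0.6, rt_gain: float = 0.05,
                        seed: int = 0, cone_halfwidth: float = 45.0,
                        min_fix_dur_ms: float = 200.0) -> pd.DataFrame:
    """Free-viewing behavioural run for the saccade-frequency/RT analyses.

    A stream of scripted luminance events (one live at any time, at
    random screen positions) is viewed by the salience-seeking gaze
    policy; each analysable fixation is labelled with its ground-truth
    RF saliency, next-saccade goal and duration.  Returns the samples
    table that :func:`scsaliency.analysis.behavioural_saliency`
    consumes.
    """
    from .gaze import angdiff

    rng = np.random.default_rng(seed)
    geom = ScreenGeometry()
    margin = 6.0
    events = [SceneEvent(t, event_every_ms, rng.uniform(-geom.width_deg / 2 + margin,
                                                        geom.width_deg / 2 - margin),
                         rng.uniform(-geom.height_deg / 2 + margin,
                                     geom.height_deg / 2 - margin),
                         "lum-disk", 1.0, 4.0)
              for t in np.arange(0.0, duration_ms, event_every_ms)]
    script = SceneScript(events=events, seed=seed)
    _, log = simulate_gaze(script, geom, duration_ms, p_salient=p_salient,
                           rt_gain=rt_gain, seed=seed + 1)
    sal = script_saliency(script, log, rf_centre_xy)
    dx = log["target_x"].to_numpy() - log["x"].to_numpy()
    dy = log["target_y"].to_numpy() - log["y"].to_numpy()
    sdir = np.rad2deg(np.arctan2(dy, dx))
    goal_dir = np.rad2deg(np.arctan2(rf_centre_xy[1], rf_centre_xy[0]))
    d = np.abs(angdiff(sdir, goal_dir))
    goal = np.where(d <= cone_halfwidth, "in",
                    np.where(d >= 180.0 - cone_halfwidth, "opposite", "other"))
    df = pd.DataFrame({"neuron": "behav", "saliency": sal, "goal": goal,
                       "duration": log["t_off"].to_numpy() - log["t_on"].to_numpy(),
                       "salient_branch": log["salient_branch"].to_numpy()})
    return df[df["duration"] >= min_fix_dur_ms].reset_index(drop=True)


def planted_lag_trial(latency_ms: float, seed: int, duration_ms: float = 100_000.0,
                      baseline_hz: float = 10.0, gain_hz: float = 40.0) -> float:
    """One synthetic neuron-clip for delay recovery: piecewise-constant
    per-fixation saliency drives spikes at a known latency; the
    Gaussian-smoothed density and the saliency series go through the
    mutual-information delay estimator.  Returns the recovered delay."""
    from .saliency import mi_delay

    rng = np.random.default_rng(seed)
    dt = 5.0
    n = int(duration_ms / dt)
    tgrid = np.arange(n) * dt
    sal = np.zeros(n)
    for t_on, t_off in _fixation_schedule(rng, duration_ms, FIX_DUR_MEDIAN_MS,
                                          FIX_DUR_LOG_SIGMA):
        sal[(tgrid >= t_on) & (tgrid < t_off)] = rng.uniform(0, 1)
    spec = SyntheticNeuronSpec(layer_class="SCs", baseline_hz=baseline_hz,
                               gain_hz=gain_hz, latency_ms=latency_ms,
                               seed=int(rng.integers(2**31 - 1)))
    spikes = simulate_spikes(spec, sal, None, dt_ms=dt)
    _, rate = spike_density(spikes, duration_ms, kernel="gauss")
    rate = rate[:n]
    return mi_delay(sal, rate).delay_ms
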