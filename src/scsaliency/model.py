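"""The assembled space-variant saliency model.

Wires the stages together: gaze-centred retinal frames (DKL planes at
the working resolution) feed a 9-frame luminance buffer; chromatic/
luminance planes and spatio-temporal energy images are read through
per-unit eccentricity-dependent DoG detectors onto the square model
grid; each of the 60 low-level maps passes through salience
competition and activation-field pooling; high-level maps and the
combined saliency map follow.  Also hosts the probe-sweep measurements
that characterize the model's receptive-field geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque

import numpy as np

from . import features as F
from .features import FeatureStack, GridSampler, ScaleSpace
from .mapping import OttesParams, ResamplingParams, SCGrid, build_sc_grid, fit_resampling_params
from .retina import RetinalFrame, ScreenGeometry, gaze_shift_embed, resize_to_ppd, rgb_to_dkl
from .steerable import SteerableBank

__all__ = ["ModelConfig", "SCSaliencyModel", "measure_activation_field", "half_max_span"]


@dataclass(frozen=True)
class ModelConfig:
    """Tunable constants of the model (defaults follow the design
    constants; the working resolution balances filter fidelity against
    runtime and is freely rescalable)."""

    field_deg: float = 100.0
    px_per_deg: float = 4.0          # working retinal resolution
    grid_size: int = 200             # square model grid (both hemifields)
    rate_hz: float = 200.0           # retinal stream rate
    buffer_len: int = 9              # luminance frames held for temporal filters
    K_chroma: float = 6.7            # DoG surround/centre ratio, chromatic/luminance
    K_st: float = 3.2                # DoG ratio, spatio-temporal channels
    speeds: tuple = F.DEFAULT_SPEEDS  # px/frame at the working rate
    comp_exc_deg: float = 3.0
    comp_inh_deg: float = 9.0
    gi_frac: float = 0.02            # global inhibition, fraction of post-addback max
    pool_radius: int = 3             # grid px
    sigma_x_px: float = 1.5          # steerable spatial sigma
    sigma_t_frames: float = 1.5
    gamma: float = 2.2

    @property
    def field_px(self) -> int:
        return int(round(self.field_deg * self.px_per_deg))

    @property
    def grid_px_per_deg(self) -> float:
        """Nominal grid scale used for the symmetric competition filter."""
        return self.grid_size / self.field_deg


class SCSaliencyModel:
    """End-to-end model instance; construct once, stream frames through."""

    def __init__(self, config: ModelConfig = ModelConfig(),
                 resampling: ResamplingParams | None = None,
                 ottes: OttesParams = OttesParams(),
                 fit_restarts: int = 100, fit_seed: int = 0):
        self.config = config
        self.ottes = ottes
        if resampling is None:
            resampling = fit_resampling_params(ottes, n_restarts=fit_restarts, seed=fit_seed)
        self.resampling = resampling
        self.grid: SCGrid = build_sc_grid(resampling, size=config.grid_size,
                                          ottes=ottes, pool_radius=config.pool_radius)
        self.bank = SteerableBank(sigma_x=config.sigma_x_px,
                                  sigma_t=config.sigma_t_frames,
                                  n_taps_t=config.buffer_len)
        self._chroma = GridSampler(self.grid, config.K_chroma,
                                   config.px_per_deg, config.field_px)
        self._st = GridSampler(self.grid, config.K_st,
                               config.px_per_deg, config.field_px)
        self._buffer: deque[np.ndarray] = deque(maxlen=config.buffer_len)

    # -- retinal stream ------------------------------------------------

    def retinal_frame(self, screen_frame_small: np.ndarray,
                      gaze_xy: tuple[float, float], t_ms: float = 0.0) -> RetinalFrame:
        """Embed one working-resolution screen frame at a gaze sample
        and convert to DKL planes."""
        cfg = self.config
        emb = gaze_shift_embed(screen_frame_small, gaze_xy, cfg.px_per_deg, cfg.field_deg)
        lum, rg, by = rgb_to_dkl(emb, gamma=cfg.gamma)
        return RetinalFrame(lum=lum, rg=rg, by=by, t=t_ms,
                            px_per_deg=cfg.px_per_deg, field_deg=cfg.field_deg)

    def _finish_map(self, m: np.ndarray) -> np.ndarray:
        cfg = self.config
        m = F.competition_operator(m, cfg.grid_px_per_deg, cfg.comp_exc_deg,
                                   cfg.comp_inh_deg, cfg.gi_frac)
        return F.pool_activation_field(m, cfg.pool_radius)

    def feature_stack(self, frame: RetinalFrame) -> FeatureStack | None:
        """Push one retinal frame; returns the 60+6 map stack once the
        temporal buffer is full (None before that)."""
        self._buffer.append(frame.lum)
        if len(self._buffer) < self.config.buffer_len:
            return None
        low: dict[str, np.ndarray] = {}
        # chromatic / luminance double-opponency (|DoG|, K=6.7)
        for tag, plane in (("lum", frame.lum), ("rg", frame.rg), ("by", frame.by)):
            low[f"{tag}:0"] = self._finish_map(np.abs(self._chroma(plane)))
        # oriented edges, flicker, directional motion (DoG K=3.2, half-wave)
        en = F.spatiotemporal_energy(np.stack(self._buffer), self.bank,
                                     speeds=self.config.speeds)
        for (th, sc), img in en.orientation.items():
            low[f"ori:{int(th)}:s{sc}"] = self._finish_map(
                np.maximum(self._st(img), 0.0))
        low["flk:0"] = self._finish_map(np.maximum(self._st(en.flicker), 0.0))
        fwd = {k: np.maximum(self._st(img), 0.0) for k, img in en.motion_fwd.items()}
        bwd = {k: np.maximum(self._st(img), 0.0) for k, img in en.motion_bwd.items()}
        for (v, th, sc, sign), m in F.opponent_motion(fwd, bwd).items():
            low[f"mot:{v:g}:{int(th)}:s{sc}:{sign}"] = self._finish_map(m)
        from .saliency import combine_high_level

        stack = FeatureStack(low_level=low, t=frame.t)
        stack.high_level = combine_high_level(stack)
        return stack

    def reset(self) -> None:
        self._buffer.clear()

    def saliency_map(self, stack: FeatureStack) -> np.ndarray:
        """Feature-agnostic map: equal-weight combination of the six
        high-level maps."""
        return np.mean([stack.high_level[k] for k in FeatureStack.HIGH_LEVEL_NAMES],
                       axis=0)

    # -- clip processing ----------------------------------------------

    def process_clip(self, frames: np.ndarray, frame_times_ms: np.ndarray,
                     gaze_t_ms: np.ndarray, gaze_x: np.ndarray, gaze_y: np.ndarray,
                     geom: ScreenGeometry, frames_px_per_deg: float | None = None):
        """Stream a clip: one retinal frame (and, once the buffer
        fills, one FeatureStack) per gaze sample, reusing the resized
        display frame while the video is unchanged.  ``frames`` are at
        the display's native resolution unless ``frames_px_per_deg``
        says otherwise.  Yields (t_ms, stack)."""
        cfg = self.config
        self.reset()
        small_cache: dict[int, np.ndarray] = {}
        fidx = np.searchsorted(frame_times_ms, gaze_t_ms, side="right") - 1
        fidx = np.clip(fidx, 0, len(frames) - 1)
        for gi, t in enumerate(gaze_t_ms):
            fi = int(fidx[gi])
            if fi not in small_cache:
                small_cache.clear()  # keep at most one resized frame
                small_cache[fi] = resize_to_ppd(frames[fi], geom, cfg.px_per_deg,
                                                src_px_per_deg=frames_px_per_deg)
            rf = self.retinal_frame(small_cache[fi], (gaze_x[gi], gaze_y[gi]), t)
            stack = self.feature_stack(rf)
            if stack is not None:
                yield t, stack

    def rf_feature_series(self, stacks, unit_rc: tuple[int, int]):
        """Collect the six high-level values at one grid unit over
        time.  ``stacks`` iterates (t, FeatureStack).  Returns
        (t_ms array, (6, T) array)."""
        ts, vals = [], []
        r, c = unit_rc
        for t, st in stacks:
            ts.append(t)
            vals.append([st.high_level[k][r, c] for k in FeatureStack.HIGH_LEVEL_NAMES])
        return np.asarray(ts), np.asarray(vals).T


# ---------------------------------------------------------------------------
# probe-sweep characterization
# ---------------------------------------------------------------------------

def half_max_span(positions: np.ndarray, responses: np.ndarray) -> float:
    """Width of the response profile at half its maximum, by linear
    interpolation outward from the peak."""
    positions = np.asarray(positions, dtype=float)
    r = np.asarray(responses, dtype=float)
    pk = int(np.argmax(r))
    half = r[pk] / 2.0
    lo = positions[0]
    for i in range(pk, 0, -1):
        if r[i - 1] < half:
            f = (r[i] - half) / (r[i] - r[i - 1])
            lo = positions[i] - f * (positions[i] - positions[i - 1])
            break
    hi = positions[-1]
    for i in range(pk, len(r) - 1):
        if r[i + 1] < half:
            f = (r[i] - half) / (r[i] - r[i + 1])
            hi = positions[i] + f * (positions[i + 1] - positions[i])
            break
    return float(hi - lo)


def measure_activation_field(model: SCSaliencyModel, ecc_deg: float,
                             probe_diam_deg: float = 1.0,
                             span_deg: float | None = None,
                             step_deg: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Probe-sweep of a unit's activation field on the luminance channel.

    A small bright disk is swept along the horizontal meridian; for
    each position the full luminance pathway (space-variant DoG,
    competition, pooling) is evaluated and the response of the unit
    whose RF centre sits at the requested eccentricity is recorded.
    Returns (probe positions, responses); the half-max span of this
    profile is the activation-field diameter.
    """
    cfg = model.config
    grid = model.grid
    unit = grid.nearest_unit(ecc_deg, 0.0)
    if span_deg is None:
        span_deg = max(8.0, 0.5 * ecc_deg + 6.0)
    n = cfg.field_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    positions = np.arange(ecc_deg - span_deg, ecc_deg + span_deg + step_deg / 2, step_deg)
    responses = np.empty_like(positions)
    for i, px in enumerate(positions):
        cx = c + px * cfg.px_per_deg
        rr = np.hypot(yy - c, xx - cx) / cfg.px_per_deg
        img = np.clip((probe_diam_deg / 2.0 - rr) * cfg.px_per_deg + 0.5, 0.0, 1.0)
        m = np.abs(model._chroma(ScaleSpace(img)))
        m = model._finish_map(m)
        responses[i] = m[unit]
    return positions, responses
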