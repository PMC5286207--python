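"""Gaze-centred retinal input: shift, embed, decimate, colour-convert.

The model's retina is a square field simulating 100 x 100 degrees of
the viewing environment, centred on gaze.  Each eye-position sample
produces a new retinal frame even when the display is unchanged: the
screen content is shifted so the pixel under gaze sits at the field
centre, and everything beyond the screen is black (the recording room
was dark with the area around the monitor blacked out).  Frames are
linearized (display gamma), rescaled to the working resolution with a
3-tap binomial decimator, and converted to the Derrington-Krauskopf-
Lennie opponent colour space (luminance, red-green, blue-yellow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "ScreenGeometry",
    "RetinalFrame",
    "gaze_shift_embed",
    "decimate_frame",
    "rgb_to_dkl",
    "resize_to_ppd",
    "load_frames",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry linking pixels to degrees of visual angle.

    Defaults subtend 82 x 52 degrees (a large display viewed at 70 cm)
    with a uniform 20 px/deg; the flat-screen tangent distortion of a
    physical monitor is outside this linearized model, so a real
    calibration should supply per-axis numbers that agree to within 5%.
    """

    width_px: int = 1640
    height_px: int = 1040
    width_deg: float = 82.0
    height_deg: float = 52.0

    def __post_init__(self) -> None:
        px = self.width_px / self.width_deg
        py = self.height_px / self.height_deg
        if px <= 0 or py <= 0:
            raise ValueError("degenerate screen geometry")
        if abs(px - py) / max(px, py) > 0.05:
            raise ValueError("pixel aspect differs between axes by more than 5%")

    @property
    def px_per_deg(self) -> float:
        return 0.5 * (self.width_px / self.width_deg + self.height_px / self.height_deg)


@dataclass
class RetinalFrame:
    """Gaze-centred DKL planes over the square simulated field."""

    lum: np.ndarray
    rg: np.ndarray
    by: np.ndarray
    t: float = 0.0
    px_per_deg: float = 4.0
    field_deg: float = 100.0

    def __post_init__(self) -> None:
        if not (self.lum.shape == self.rg.shape == self.by.shape):
            raise ValueError("DKL planes must share one shape")


def resize_to_ppd(frame: np.ndarray, geom: ScreenGeometry, px_per_deg: float,
                  src_px_per_deg: float | None = None) -> np.ndarray:
    """Resample a screen frame to the model's working resolution.

    Uses repeated binomial decimation while the source is at least 2x
    the target density, then bilinear interpolation for the residual
    factor.  ``src_px_per_deg`` defaults to the display geometry's
    native density (override it for frames already downscaled).
    Returns an array of shape ~(height_deg*ppd, width_deg*ppd).
    """
    img = np.asarray(frame, dtype=float)
    src_ppd = geom.px_per_deg if src_px_per_deg is None else src_px_per_deg
    if abs(src_ppd - px_per_deg) < 1e-9 * px_per_deg:
        return img.astype(float)
    while src_ppd >= 2.0 * px_per_deg and min(img.shape[:2]) > 4:
        img = decimate_frame(img)
        src_ppd /= 2.0
    out_h = max(2, int(round(geom.height_deg * px_per_deg)))
    out_w = max(2, int(round(geom.width_deg * px_per_deg)))
    rr = np.linspace(0, img.shape[0] - 1, out_h)
    cc = np.linspace(0, img.shape[1] - 1, out_w)
    r0 = np.floor(rr).astype(int)
    c0 = np.floor(cc).astype(int)
    r1 = np.minimum(r0 + 1, img.shape[0] - 1)
    c1 = np.minimum(c0 + 1, img.shape[1] - 1)
    fr = (rr - r0)[:, None]
    fc = (cc - c0)[None, :]
    if img.ndim == 3:
        fr = fr[..., None]
        fc = fc[..., None]
    out = (img[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
           + img[np.ix_(r1, c0)] * fr * (1 - fc)
           + img[np.ix_(r0, c1)] * (1 - fr) * fc
           + img[np.ix_(r1, c1)] * fr * fc)
    return out


def gaze_shift_embed(frame: np.ndarray, gaze_deg: tuple[float, float],
                     px_per_deg: float, field_deg: float = 100.0,
                     background: float = 0.0) -> np.ndarray:
    """Embed a (working-resolution) screen frame in the simulated field,
    shifted so the pixel under gaze lands at the field centre.

    ``frame`` must already be at ``px_per_deg`` (see
    :func:`resize_to_ppd`); gaze is (x, y) in degrees from screen
    centre, x rightward, y upward.  Off-screen area is filled with
    ``background`` (black).  An off-screen gaze is processed the same
    way; the screen content simply shifts further toward the field edge.
    """
    frame = np.asarray(frame, dtype=float)
    n = int(round(field_deg * px_per_deg))
    shape = (n, n) if frame.ndim == 2 else (n, n, frame.shape[2])
    out = np.full(shape, background, dtype=float)
    h, w = frame.shape[:2]
    # screen-centre pixel position within the field
    gx, gy = gaze_deg
    ctr_r = (n - 1) / 2.0 + gy * px_per_deg - (h - 1) / 2.0
    ctr_c = (n - 1) / 2.0 - gx * px_per_deg - (w - 1) / 2.0
    r0 = int(round(ctr_r))
    c0 = int(round(ctr_c))
    rs, re = max(r0, 0), min(r0 + h, n)
    cs, ce = max(c0, 0), min(c0 + w, n)
    if rs < re and cs < ce:
        out[rs:re, cs:ce] = frame[rs - r0:re - r0, cs - c0:ce - c0]
    return out


_BINOMIAL3 = np.array([1.0, 2.0, 1.0]) / 4.0


def decimate_frame(img: np.ndarray) -> np.ndarray:
    """One application of 3-tap binomial smoothing ([1,2,1]/4 per axis)
    followed by 2x subsampling."""
    img = np.asarray(img, dtype=float)
    sm = convolve1d(img, _BINOMIAL3, axis=0, mode="nearest")
    sm = convolve1d(sm, _BINOMIAL3, axis=1, mode="nearest")
    return sm[::2, ::2]


def load_frames(path, timestamps_table=None):
    """Read a clip as (frames, frame_times_ms).

    ``path`` may be a video file (anything imageio/ffmpeg can decode)
    or a directory of numbered image files.  Frame timestamps come
    from a sidecar table (delimited text with a ``time_ms`` column,
    one row per frame) when given; otherwise they are synthesized at
    the container's frame rate (default 60 fps for image directories).
    Frames are float RGB in [0, 1].
    """
    import imageio.v3 as iio
    from pathlib import Path as _P

    p = _P(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir()
                       if f.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no image files in {p}")
        frames = np.stack([iio.imread(f) for f in files]).astype(float)
        fps = 60.0
    else:
        frames = np.stack(list(iio.imiter(p))).astype(float)
        try:
            meta = iio.immeta(p)
            fps = float(meta.get("fps", 60.0))
        except Exception:
            fps = 60.0
    if frames.ndim == 3:  # greyscale
        frames = np.repeat(frames[..., None], 3, axis=-1)
    frames = frames[..., :3]
    if frames.max() > 1.0:
        frames = frames / 255.0
    if timestamps_table is not None:
        import pandas as pd

        df = pd.read_csv(timestamps_table, sep="\t")
        if "time_ms" not in df.columns:
            df = pd.read_csv(timestamps_table, sep=",")
        t = df["time_ms"].to_numpy(float)
        if t.size != len(frames):
            raise ValueError("timestamp table length does not match frame count")
    else:
        t = np.arange(len(frames)) * 1000.0 / fps
    return frames, t


# sRGB (D65) -> XYZ, and XYZ -> LMS (Hunt-Pointer-Estevez, D65-normalized)
_RGB2XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
_XYZ2LMS = np.array([
    [0.40024, 0.70760, -0.08081],
    [-0.22630, 1.16532, 0.04570],
    [0.00000, 0.00000, 0.91822],
])
DEFAULT_RGB2LMS = _XYZ2LMS @ _RGB2XYZ


def rgb_to_dkl(img: np.ndarray, rgb2lms: np.ndarray = DEFAULT_RGB2LMS,
               gamma: float = 2.2, clip_log: list | None = None):
    """Convert a gamma-encoded RGB image to DKL-style opponent planes.

    Returns (lum, rg, by).  The axes are defined relative to the
    display white point so that every achromatic input maps to exactly
    rg = by = 0:

    * lum = (L + M) / (L_w + M_w)
    * rg  = (L M_w - M L_w) / (L_w M_w)   (L-cone excess vs grey)
    * by  = (S (L_w + M_w) - (L + M) S_w) / (S_w (L_w + M_w))

    The conversion matrix is display-dependent; the default is a
    generic sRGB chain and can be replaced with a monitor calibration.
    Out-of-range linearized values are clipped (counted in
    ``clip_log`` if a list is supplied).
    """
    rgb = np.asarray(img, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected (H, W, 3) RGB")
    n_out = int(np.count_nonzero((rgb < 0) | (rgb > 1)))
    if clip_log is not None and n_out:
        clip_log.append(n_out)
    lin = np.clip(rgb, 0.0, 1.0) ** gamma
    lms = lin @ rgb2lms.T
    lw, mw, sw = rgb2lms @ np.ones(3)
    L, M, S = lms[..., 0], lms[..., 1], lms[..., 2]
    lum = (L + M) / (lw + mw)
    rg = (L * mw - M * lw) / (lw * mw)
    by = (S * (lw + mw) - (L + M) * sw) / (sw * (lw + mw))
    return lum, rg, by
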