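"""Centre-surround feature machinery on the space-variant model grid.

Every low-level feature map is built the same way: a feature image in
gaze-centred retinal coordinates (a DKL plane, or a spatio-temporal
energy image) is read through eccentricity-dependent difference-of-
Gaussian (DoG) detectors, one per model-grid unit, realized as the
difference of two samples of a Gaussian scale space at the unit's
receptive-field centre.  Chromatic/luminance channels use surround/
centre ratio K = 6.7 and take the absolute DoG response (double
opponency); spatio-temporal channels use K = 3.2 and half-wave
rectification.  Each map then passes through one iteration of the
Itti-Koch salience competition operator and a circular-neighbourhood
pooling that models the large, size-selective collicular activation
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, gaussian_filter, map_coordinates, zoom

from .steerable import SteerableBank, direction_vector

__all__ = [
    "eccentricity_size_law",
    "DoGSpec",
    "make_dog",
    "ScaleSpace",
    "GridSampler",
    "dog_disk_response",
    "preferred_disk_size",
    "spatiotemporal_energy",
    "opponent_motion",
    "competition_operator",
    "pool_activation_field",
    "FeatureStack",
    "ORIENTATIONS",
    "DEFAULT_SPEEDS",
]

ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
DEFAULT_SPEEDS = (1.0, 4.0, 16.0)  # px/frame at the working rate


def eccentricity_size_law(R):
    """Preferred (optimal) stimulus size in degrees at eccentricity R.

    Linear through 0.75 deg at the fovea and 5 deg at 40 deg
    eccentricity, extrapolated beyond.
    """
    return 0.75 + (5.0 - 0.75) / 40.0 * np.asarray(R, dtype=float)


@dataclass(frozen=True)
class DoGSpec:
    """Centre-surround detector tuned to an optimal stimulus size.

    ``S`` is the disk diameter (deg) that maximizes the response;
    ``K`` the surround/centre sigma ratio; the Gaussian sigmas follow
    from requiring the response to a centred disk, with unit-mass
    Gaussians, to peak exactly at diameter S.
    """

    S: float
    K: float
    sigma_c: float
    sigma_s: float

    def disk_response(self, diam_deg: float) -> float:
        """Analytic response to a centred unit-contrast disk (continuous
        DoG; the model's scale-space realization approximates this)."""
        r = diam_deg / 2.0
        return float(
            -np.expm1(-(r**2) / (2 * self.sigma_c**2))
            + np.expm1(-(r**2) / (2 * self.sigma_s**2))
        )


def make_dog(S: float, K: float) -> DoGSpec:
    """DoG spec from optimal size S (deg) and ratio K > 1.

    Setting d/dr of the disk response to zero gives
    sigma_c = (S/2) sqrt((1 - K^-2) / (4 ln K)), sigma_s = K sigma_c.
    """
    if S <= 0 or K <= 1:
        raise ValueError("need S > 0 and K > 1")
    sigma_c = (S / 2.0) * np.sqrt((1.0 - K**-2) / (4.0 * np.log(K)))
    return DoGSpec(S=S, K=K, sigma_c=float(sigma_c), sigma_s=float(K * sigma_c))


class ScaleSpace:
    """Lazy Gaussian scale space of one image.

    Levels are geometric in sigma (half-octave by default); blurred
    copies are computed on demand and cached.  ``sample`` reads values
    at fractional pixel positions and arbitrary sigmas by bilinear
    spatial interpolation plus linear interpolation across the two
    bracketing levels, which is how the model realizes DoG detectors
    ("a sample at a lower level minus one at a higher level").
    """

    def __init__(self, img: np.ndarray, sigma0_px: float = 0.25,
                 ratio: float = np.sqrt(2.0)):
        self.img = np.asarray(img, dtype=float)
        self.sigma0 = float(sigma0_px)
        self.ratio = float(ratio)
        self._levels: dict[int, np.ndarray] = {}

    def level(self, k: int) -> np.ndarray:
        if k not in self._levels:
            self._levels[k] = gaussian_filter(self.img, self.sigma0 * self.ratio**k,
                                              mode="nearest")
        return self._levels[k]

    def level_of(self, sigma_px) -> np.ndarray:
        """Fractional level index for a sigma in pixels (clipped at 0)."""
        s = np.maximum(np.asarray(sigma_px, dtype=float), self.sigma0)
        return np.log(s / self.sigma0) / np.log(self.ratio)

    def sample(self, rows, cols, sigma_px) -> np.ndarray:
        lv = np.atleast_1d(self.level_of(sigma_px))
        rows = np.atleast_1d(np.asarray(rows, dtype=float))
        cols = np.atleast_1d(np.asarray(cols, dtype=float))
        lo = np.floor(lv).astype(int)
        frac = lv - lo
        out = np.empty_like(rows, dtype=float)
        for k in np.unique(lo):
            m = lo == k
            coords = np.vstack([rows[m], cols[m]])
            a = map_coordinates(self.level(k), coords, order=1, mode="nearest")
            b = map_coordinates(self.level(k + 1), coords, order=1, mode="nearest")
            out[m] = a * (1.0 - frac[m]) + b * frac[m]
        return out


class GridSampler:
    """Per-unit space-variant DoG read-out of a retinal-space image.

    Precomputes, for a model grid / K / working resolution, the pixel
    coordinates of every unit's RF centre and its centre and surround
    sigmas (from the eccentricity size law), then evaluates the signed
    DoG response map for any image of the matching geometry.
    """

    def __init__(self, grid, K: float, px_per_deg: float, field_px: int):
        self.K = float(K)
        self.px_per_deg = float(px_per_deg)
        self.field_px = int(field_px)
        c = (field_px - 1) / 2.0
        self.rows = (c - grid.y_deg * px_per_deg).ravel()
        self.cols = (c + grid.x_deg * px_per_deg).ravel()
        spec_sigma = np.array([make_dog(S, K).sigma_c for S in
                               np.unique(np.round(grid.S_deg, 6))])
        # vectorized: sigma_c is linear in S
        unit = make_dog(1.0, K)
        self.sigma_c_px = (grid.S_deg.ravel() * unit.sigma_c) * px_per_deg
        self.sigma_s_px = self.sigma_c_px * K
        self.shape = grid.S_deg.shape
        del spec_sigma

    def __call__(self, img_or_space) -> np.ndarray:
        """Signed DoG map on the grid (rectification is the caller's)."""
        ss = img_or_space if isinstance(img_or_space, ScaleSpace) else ScaleSpace(img_or_space)
        if ss.img.shape[0] != self.field_px:
            raise ValueError("image does not match the sampler's field size")
        centre = ss.sample(self.rows, self.cols, self.sigma_c_px)
        surround = ss.sample(self.rows, self.cols, self.sigma_s_px)
        return (centre - surround).reshape(self.shape)


def dog_disk_response(spec: DoGSpec, diam_deg: float, px_per_deg: float = 8.0,
                      extent_deg: float | None = None) -> float:
    """Response of a DoG detector to a centred luminance disk, evaluated
    through the scale-space realization (rendered image, interpolated
    level samples) rather than the closed form."""
    if extent_deg is None:
        extent_deg = diam_deg + 8.0 * spec.sigma_s + 2.0
    n = int(np.ceil(extent_deg * px_per_deg)) | 1
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - c, xx - c) / px_per_deg
    img = np.clip((diam_deg / 2.0 - rr) * px_per_deg + 0.5, 0.0, 1.0)  # ~1px soft edge
    ss = ScaleSpace(img)
    val_c = ss.sample([c], [c], [spec.sigma_c * px_per_deg])[0]
    val_s = ss.sample([c], [c], [spec.sigma_s * px_per_deg])[0]
    return float(val_c - val_s)


def preferred_disk_size(spec: DoGSpec, diams=None, px_per_deg: float | None = None) -> float:
    """Disk diameter maximizing the detector's response (numerical sweep).

    The rendering resolution adapts to the detector so the centre
    Gaussian stays well sampled without oversizing the sweep images.
    """
    if px_per_deg is None:
        px_per_deg = float(np.clip(16.0 / spec.S, 3.0, 8.0))
    if diams is None:
        diams = np.geomspace(spec.S / 4.0, spec.S * 4.0, 81)
    resp = [dog_disk_response(spec, d, px_per_deg) for d in diams]
    return float(diams[int(np.argmax(resp))])


# ---------------------------------------------------------------------------
# spatio-temporal energies
# ---------------------------------------------------------------------------

@dataclass
class EnergyImages:
    """Retinal-space quadrature-energy images from one 9-frame buffer.

    ``orientation``: {(theta, scale): image} for static edges;
    ``flicker``: purely temporal energy; ``motion_fwd``/``motion_bwd``:
    {(speed, theta, scale): image} for the two opposed drift directions
    of each oriented pair.
    """

    orientation: dict
    flicker: np.ndarray
    motion_fwd: dict
    motion_bwd: dict


def spatiotemporal_energy(buffer: np.ndarray, bank: SteerableBank | None = None,
                          speeds=DEFAULT_SPEEDS,
                          orientations=ORIENTATIONS) -> EnergyImages:
    """Oriented-edge, flicker and directional motion energies.

    ``buffer`` is a (9, H, W) stack of the most recent luminance frames.
    Two spatial scales are used: the working ("retinal") resolution and
    a binomially decimated half resolution (energies upsampled back so
    all images share the working geometry).
    """
    if bank is None:
        bank = SteerableBank()
    buffer = np.asarray(buffer, dtype=float)
    if buffer.ndim != 3 or buffer.shape[0] != bank.n_taps_t:
        raise ValueError(f"buffer must be ({bank.n_taps_t}, H, W)")

    from .retina import decimate_frame  # local import to avoid cycle

    stacks = {0: buffer, 1: np.stack([decimate_frame(f) for f in buffer])}
    orientation: dict = {}
    motion_fwd: dict = {}
    motion_bwd: dict = {}
    flicker = None
    for sc, stack in stacks.items():
        basis = bank.basis(stack)

        def up(img):
            if sc == 0:
                return img
            fy = buffer.shape[1] / img.shape[0]
            fx = buffer.shape[2] / img.shape[1]
            return zoom(img, (fy, fx), order=1, mode="nearest", grid_mode=True)

        for th in orientations:
            w = direction_vector(th, 0.0, bank.sigma_x, bank.sigma_t)
            orientation[(th, sc)] = up(bank.energy(basis, w))
            for v in speeds:
                # speed is defined at the working resolution; the coarse
                # scale sees it halved in its own pixels
                v_px = v / (2.0**sc)
                wf = direction_vector(th, v_px, bank.sigma_x, bank.sigma_t)
                wb = direction_vector(th, -v_px, bank.sigma_x, bank.sigma_t)
                motion_fwd[(v, th, sc)] = up(bank.energy(basis, wf))
                motion_bwd[(v, th, sc)] = up(bank.energy(basis, wb))
        if sc == 0:
            flicker = bank.energy(basis, np.array([0.0, 0.0, 1.0]))
    return EnergyImages(orientation=orientation, flicker=flicker,
                        motion_fwd=motion_fwd, motion_bwd=motion_bwd)


def opponent_motion(fwd: dict, bwd: dict) -> dict:
    """Directional opponency: both half-wave-rectified signed
    differences for every opposed pair at matched speed/orientation/
    scale.  24 raw pairs -> 48 opponent maps."""
    out = {}
    for key in fwd:
        d = fwd[key] - bwd[key]
        out[key + ("pos",)] = np.maximum(d, 0.0)
        out[key + ("neg",)] = np.maximum(-d, 0.0)
    return out


# ---------------------------------------------------------------------------
# within-map competition and pooling (on the model grid)
# ---------------------------------------------------------------------------

def competition_operator(m: np.ndarray, px_per_deg: float = 2.0,
                         exc_size_deg: float = 3.0, inh_size_deg: float = 9.0,
                         gi_frac: float = 0.02) -> np.ndarray:
    """One iteration of the Itti-Koch salience competition.

    Filter with a large DoG (3 deg excitatory / 9 deg inhibitory
    Gaussians at the nominal grid scale), add the result back, subtract
    a global-inhibition constant (a fixed fraction of the post-addback
    maximum), and half-wave rectify.  Isolated peaks survive; many
    equal peaks suppress each other.
    """
    m = np.asarray(m, dtype=float)
    filt = (gaussian_filter(m, exc_size_deg * px_per_deg, mode="nearest")
            - gaussian_filter(m, inh_size_deg * px_per_deg, mode="nearest"))
    added = m + filt
    c = gi_frac * added.max() if added.size else 0.0
    return np.maximum(added - max(c, 0.0), 0.0)


def _disc_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy**2 + xx**2 <= r**2).astype(float)


def pool_activation_field(m: np.ndarray, radius: int = 3) -> np.ndarray:
    """Replace each grid point by the sum over a circular neighbourhood,
    simulating the large but size-selective collicular activation
    fields (their visual-space extent grows with eccentricity because
    the pooling is symmetric in grid space)."""
    return convolve(np.asarray(m, dtype=float), _disc_kernel(radius), mode="nearest")


@dataclass
class FeatureStack:
    """All 60 low-level maps and 6 high-level maps for one time step,
    on the model grid."""

    low_level: dict = field(default_factory=dict)
    high_level: dict = field(default_factory=dict)
    t: float = 0.0

    HIGH_LEVEL_NAMES = ("lum", "rg", "by", "orientation", "flicker", "motion")

    def counts(self) -> tuple[int, int]:
        return len(self.low_level), len(self.high_level)
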