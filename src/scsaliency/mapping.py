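"""Visual-field <-> superior-colliculus coordinate machinery.

The retinotectal projection is strongly space-variant: most of the SC
surface is devoted to the central visual field.  Ottes, Van Gisbergen &
Eggermont described this as a complex-logarithmic mapping from visual
polar coordinates (eccentricity ``R`` in degrees, polar angle ``Phi``
measured from the horizontal meridian) to millimetres on the collicular
sheet (``u`` rostral-caudal, ``v`` medial-lateral), with one sheet per
hemifield.  This module implements

* the analytic Ottes mapping and its exact inverse,
* a simpler separable log-polar "variable resolution" resampling whose
  scale constants are fitted, by least squares over matched grid nodes,
  to the Ottes image of a rectangular sheet (4.5 mm x 3.5 mm per
  hemifield) -- this is what defines the square model grid on which all
  image processing runs,
* the 200 x 200 model grid itself (receptive-field centres, preferred
  stimulus sizes), and
* conversion of a circular SC "point image" into a visual-space
  receptive-field boundary polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .features import eccentricity_size_law

__all__ = [
    "OttesParams",
    "VisualPoint",
    "SCPoint",
    "ResamplingParams",
    "SCGrid",
    "ottes_forward",
    "ottes_inverse",
    "fit_resampling_params",
    "build_sc_grid",
    "rf_boundary",
]


@dataclass(frozen=True)
class OttesParams:
    """Constants of the visual-to-SC log-polar mapping.

    ``A`` (deg) sets the size of the foveal singularity-free zone;
    ``B_u`` and ``B_v`` (mm) scale the rostral-caudal and
    medial-lateral axes of the collicular sheet.
    """

    A: float = 3.0
    B_u: float = 1.4
    B_v: float = 1.8

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B_u <= 0 or self.B_v <= 0:
            raise ValueError("Ottes constants must be positive")


@dataclass(frozen=True)
class VisualPoint:
    """Point in the visual field: eccentricity R (deg) and polar angle
    Phi (deg, from the horizontal meridian, in (-180, 180])."""

    R: float
    Phi: float

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("eccentricity must be >= 0")

    @property
    def xy(self) -> tuple[float, float]:
        a = np.deg2rad(self.Phi)
        return (self.R * np.cos(a), self.R * np.sin(a))

    @staticmethod
    def from_xy(x: float, y: float) -> "VisualPoint":
        return VisualPoint(float(np.hypot(x, y)), float(np.rad2deg(np.arctan2(y, x))))


@dataclass(frozen=True)
class SCPoint:
    """Point on one collicular sheet: u (mm, rostral-caudal), v (mm,
    medial-lateral), plus which hemifield's sheet it lives on."""

    u: float
    v: float
    hemifield: str = "right"  # visual hemifield represented by this sheet


def _mirror_to_right(R, Phi_deg):
    """Fold a visual point into right-hemifield convention.

    Returns (phi_local_deg in [-90, 90], hemifield). Points on the
    vertical meridian are assigned to the right sheet.
    """
    Phi = np.asarray(Phi_deg, dtype=float)
    right = np.abs(((Phi + 180.0) % 360.0) - 180.0) <= 90.0
    phi_local = np.where(right, Phi, 180.0 - Phi)
    # wrap into (-180, 180]
    phi_local = ((phi_local + 180.0) % 360.0) - 180.0
    return phi_local, right


def ottes_forward(p: VisualPoint, params: OttesParams = OttesParams()) -> SCPoint:
    """Map a visual point to collicular sheet coordinates.

    Implemented as the complex-log form ``w = ln((z + A) / A)`` with
    ``z = R exp(i Phi)`` (hemifield-local angle), scaled by B_u / B_v.
    The fovea maps to the sheet origin and the horizontal meridian to
    the line v = 0.
    """
    phi_local, right = _mirror_to_right(p.R, p.Phi)
    z = p.R * np.exp(1j * np.deg2rad(phi_local))
    w = np.log((z + params.A) / params.A)
    return SCPoint(
        u=float(params.B_u * w.real),
        v=float(params.B_v * w.imag),
        hemifield="right" if right else "left",
    )


def ottes_inverse(q: SCPoint, params: OttesParams = OttesParams()) -> VisualPoint:
    """Exact analytic inverse of :func:`ottes_forward`.

    Equivalent to the reverse-mapping equations
    ``R = A sqrt(exp(2u/B_u) - 2 exp(u/B_u) cos(v/B_v) + 1)`` and
    ``Phi = atan2(exp(u/B_u) sin(v/B_v), exp(u/B_u) cos(v/B_v) - 1)``.
    """
    z = params.A * (np.exp(q.u / params.B_u + 1j * q.v / params.B_v) - 1.0)
    R = float(np.abs(z))
    phi_local = float(np.rad2deg(np.angle(z)))
    if q.hemifield == "left":
        phi = 180.0 - phi_local
        phi = ((phi + 180.0) % 360.0) - 180.0
        if phi == -180.0:
            phi = 180.0
    else:
        phi = phi_local
    return VisualPoint(R=R, Phi=phi)


def _ottes_inverse_xy(u, v, params: OttesParams):
    """Vectorized inverse (right-hemifield sheet) returning Cartesian degrees."""
    z = params.A * (np.exp(np.asarray(u) / params.B_u + 1j * np.asarray(v) / params.B_v) - 1.0)
    return z.real, z.imag


@dataclass
class ResamplingParams:
    """Scale constants of the separable log-polar resampling.

    One hemifield maps the column fraction ``s`` in [0, 1] to
    eccentricity ``R = a (exp(c_u s) - 1)`` and the row fraction offset
    ``srow - 1/2`` to hemifield-local polar angle ``Phi = c_v (srow - 1/2)``
    (radians).  ``a`` is in degrees, ``c_u``/``c_v`` dimensionless.
    """

    a: float
    c_u: float
    c_v: float
    objective: float = float("nan")
    n_restarts: int = 0
    seed: int | None = None
    degenerate: bool = False

    def col_to_R(self, s):
        return self.a * (np.exp(self.c_u * np.asarray(s, dtype=float)) - 1.0)

    def R_to_col(self, R):
        return np.log1p(np.asarray(R, dtype=float) / self.a) / self.c_u

    def row_to_phi(self, srow):
        """Row fraction in [0,1] -> hemifield-local polar angle, degrees."""
        return np.rad2deg(self.c_v * (np.asarray(srow, dtype=float) - 0.5))

    def phi_to_row(self, phi_deg):
        return np.deg2rad(np.asarray(phi_deg, dtype=float)) / self.c_v + 0.5

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "ResamplingParams":
        return ResamplingParams(**json.loads(Path(path).read_text()))


def _sheet_target_points(params: OttesParams, sheet_mm=(4.5, 3.5), n_nodes=(24, 32)):
    """Visual-space (x, y) image of a rectangular sheet grid under the
    exact Ottes inverse, together with the node fractions."""
    su = np.linspace(0.0, 1.0, n_nodes[0])
    sv = np.linspace(0.0, 1.0, n_nodes[1])
    SU, SV = np.meshgrid(su, sv, indexing="ij")
    u = sheet_mm[0] * SU
    v = sheet_mm[1] * (SV - 0.5)
    x, y = _ottes_inverse_xy(u, v, params)
    return SU, SV, x, y


def fit_resampling_params(
    params: OttesParams = OttesParams(),
    sheet_mm: tuple[float, float] = (4.5, 3.5),
    n_restarts: int = 1000,
    seed: int = 0,
    n_nodes: tuple[int, int] = (24, 32),
) -> ResamplingParams:
    """Fit the resampling scale constants to the Ottes sheet image.

    A rectangular grid of nodes on one collicular sheet is projected to
    visual space twice: exactly (Ottes inverse) and through the
    separable log-polar transform.  The summed squared visual-space
    distance between matched nodes is minimized with Nelder-Mead
    simplex restarts drawn log-uniformly within a factor of 10 of an
    analytic initial guess.  Deterministic given ``seed``.
    """
    SU, SV, tx, ty = _sheet_target_points(params, sheet_mm, n_nodes)

    def objective(logp):
        a, c_u, c_v = np.exp(logp)
        # keep the transform physical: the row axis must span less than a
        # full turn of polar angle (the discrete node grid would otherwise
        # admit aliased optima with wild c_v), and exp(c_u) must not overflow
        pen = 0.0
        if c_v > 2.0 * np.pi:
            pen += 1e9 * (c_v - 2.0 * np.pi) ** 2
        if c_u > 50.0:
            pen += 1e9 * (c_u - 50.0) ** 2
        R = a * (np.exp(np.minimum(c_u, 50.0) * SU) - 1.0)
        phi = np.minimum(c_v, 2.0 * np.pi) * (SV - 0.5)
        x = R * np.cos(phi)
        y = R * np.sin(phi)
        return float(np.sum((x - tx) ** 2 + (y - ty) ** 2)) + pen

    # analytic guess: match the Ottes meridian/row scalings directly
    init = np.log(
        [params.A, sheet_mm[0] / params.B_u, sheet_mm[1] / params.B_v]
    )
    rng = np.random.default_rng(seed)
    f_init = objective(init)
    best = None
    starts = [init] + [
        init + np.log(10.0) * rng.uniform(-1.0, 1.0, size=3) for _ in range(max(0, n_restarts - 1))
    ]
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    a, c_u, c_v = np.exp(best.x)
    return ResamplingParams(
        a=float(a), c_u=float(c_u), c_v=float(c_v),
        objective=float(best.fun), n_restarts=n_restarts, seed=seed,
        degenerate=bool(best.fun >= f_init and n_restarts > 1),
    )


@dataclass
class SCGrid:
    """The square model grid: two hemifield sheets concatenated side by
    side (left hemifield in columns [0, size/2), mirrored so the foveal
    representations abut at the centre columns).

    Per-unit arrays are indexed ``[row, col]``; ``x_deg``/``y_deg`` are
    receptive-field centres in gaze-centred visual degrees, ``ecc`` the
    eccentricity, and ``S_deg`` the preferred (optimal) stimulus size
    from the eccentricity law.
    """

    size: int
    resampling: ResamplingParams
    ottes: OttesParams = field(default_factory=OttesParams)
    pool_radius: int = 3

    x_deg: np.ndarray = field(init=False, repr=False)
    y_deg: np.ndarray = field(init=False, repr=False)
    ecc: np.ndarray = field(init=False, repr=False)
    phi_local: np.ndarray = field(init=False, repr=False)
    S_deg: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.size
        half = n // 2
        cols = np.arange(n)
        rows = np.arange(n)
        # hemifield-local column fraction: 0 at the centre seam (fovea)
        right = cols >= half
        i_local = np.where(right, cols - half, half - 1 - cols)
        s = i_local / (half - 1)
        srow = rows / (n - 1)
        S, SR = np.meshgrid(s, srow, indexing="xy")  # [row, col]
        R = self.resampling.col_to_R(S)
        phi = np.deg2rad(self.resampling.row_to_phi(SR))
        x = R * np.cos(phi)
        y = R * np.sin(phi)
        sign = np.where(right, 1.0, -1.0)[None, :]
        self.x_deg = x * sign
        self.y_deg = y
        self.ecc = R
        self.phi_local = np.rad2deg(phi)
        self.S_deg = eccentricity_size_law(R)

    @property
    def rf_centres(self) -> np.ndarray:
        """(size, size, 2) array of (x, y) RF centres in degrees."""
        return np.stack([self.x_deg, self.y_deg], axis=-1)

    def nearest_unit(self, x_deg: float, y_deg: float) -> tuple[int, int]:
        """(row, col) of the grid unit whose RF centre is nearest a
        visual-field position."""
        d2 = (self.x_deg - x_deg) ** 2 + (self.y_deg - y_deg) ** 2
        return tuple(int(v) for v in np.unravel_index(np.argmin(d2), d2.shape))

    def unit_index(self, p: VisualPoint) -> tuple[int, int]:
        x, y = p.xy
        return self.nearest_unit(x, y)


def build_sc_grid(
    resampling: ResamplingParams,
    size: int = 200,
    ottes: OttesParams = OttesParams(),
    pool_radius: int = 3,
) -> SCGrid:
    """Assemble the model grid from fitted resampling constants."""
    if size % 2:
        raise ValueError("grid size must be even (one hemifield per half)")
    return SCGrid(size=size, resampling=resampling, ottes=ottes, pool_radius=pool_radius)


def rf_boundary(
    centre: VisualPoint,
    point_image_diam_mm: float = 1.5,
    params: OttesParams = OttesParams(),
    n_vertices: int = 64,
) -> np.ndarray:
    """Receptive-field boundary polygon in visual space.

    A circle of the given diameter on the collicular sheet, centred on
    the image of the RF centre, is mapped back to visual space point by
    point.  Because the mapping is logarithmic in eccentricity the
    polygon extends further peripheral than foveal of its centre.
    Returns an (n, 2) array of (x, y) in degrees.
    """
    if centre.R < 2.0:
        raise ValueError("RF too close to the fovea (<2 deg eccentricity)")
    q = ottes_forward(centre, params)
    r = point_image_diam_mm / 2.0
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    u = q.u + r * np.cos(ang)
    v = q.v + r * np.sin(ang)
    # clip to the hemifield sheet: |local angle| <= 90 deg, u >= 0
    vmax = params.B_v * np.pi / 2.0
    clipped = (np.abs(v) > vmax) | (u < 0)
    if clipped.any():
        import warnings

        warnings.warn("RF boundary crosses the vertical meridian; clipped to hemifield")
        v = np.clip(v, -vmax, vmax)
        u = np.maximum(u, 0.0)
    x, y = _ottes_inverse_xy(u, v, params)
    if q.hemifield == "left":
        x = -x
    return np.column_stack([x, y])
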