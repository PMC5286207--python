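"""Separable 3-D second-derivative-of-Gaussian steerable filters.

Spatio-temporal energy (oriented edges, flicker, directional motion) is
measured with the quadrature pair G2/H2: the second directional
derivative of a space-time Gaussian and its Hilbert transform along the
steering direction.  Both steer analytically: every oriented filter is
a fixed polynomial-in-direction combination of a small set of x/y/t
separable basis filters, so a whole orientation/speed bank costs one
pass of separable basis convolutions plus cheap weighted sums.

With an anisotropic Gaussian (spatial sigma in pixels, temporal sigma
in frames) the separable monomial basis is ``x^i y^j t^k G`` in
sigma-normalized coordinates.  G2 steers over the degree-{0,2}
monomials; H2 is the standard cubic-times-Gaussian least-squares fit to
the exact Hilbert transform (computed here from the Dawson function)
and steers over the degree-{1,3} monomials.

A steering direction is a unit vector in sigma-normalized space-time.
``direction_vector`` builds the vector tuned to a drifting edge of
given spatial orientation and speed: a structure moving with velocity
``v`` (px/frame) along its spatial normal ``(cos th, sin th)`` varies
fastest along ``(cos th * sx, sin th * sx, -v * st)`` in normalized
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np
from scipy.ndimage import convolve1d
from scipy.special import dawsn

__all__ = ["SteerableBank", "direction_vector", "hilbert_g2_fit"]


@lru_cache(maxsize=1)
def hilbert_g2_fit() -> tuple[float, float]:
    """Least-squares cubic fit (c1 u + c3 u^3) exp(-u^2/2) to the exact
    Hilbert transform of g''(u), g(u) = exp(-u^2/2).

    H{g}(u) = (2/sqrt(pi)) D(u/sqrt(2)) with D the Dawson function;
    H commutes with d/du, so the target is its second derivative.
    """
    u = np.linspace(-6.0, 6.0, 4001)
    h = (2.0 / np.sqrt(np.pi)) * dawsn(u / np.sqrt(2.0))
    d2h = np.gradient(np.gradient(h, u), u)
    A = np.column_stack([u, u**3]) * np.exp(-(u**2) / 2.0)[:, None]
    (c1, c3), *_ = np.linalg.lstsq(A, d2h, rcond=None)
    return float(c1), float(c3)


def _monomials(degree: int):
    """All (i, j, k) with i + j + k == degree."""
    return [
        (i, j, degree - i - j)
        for i in range(degree, -1, -1)
        for j in range(degree - i, -1, -1)
    ]


def _multinom(i: int, j: int, k: int) -> float:
    return factorial(i + j + k) / (factorial(i) * factorial(j) * factorial(k))


def direction_vector(theta_deg: float, speed_px_per_frame: float,
                     sigma_x: float, sigma_t: float) -> np.ndarray:
    """Unit steering vector (sigma-normalized) for a pattern with
    spatial normal ``theta`` drifting at ``speed`` px/frame along that
    normal.  speed 0 gives a static oriented-edge detector; use
    ``theta=None``-free flicker via (0, 0, 1) directly."""
    th = np.deg2rad(theta_deg)
    w = np.array([np.cos(th) * sigma_x, np.sin(th) * sigma_x,
                  -speed_px_per_frame * sigma_t])
    return w / np.linalg.norm(w)


class SteerableBank:
    """Basis convolutions and steering for G2/H2 energies on a frame buffer.

    Parameters
    ----------
    sigma_x : spatial Gaussian sigma in pixels.
    sigma_t : temporal Gaussian sigma in frames.
    n_taps_t : temporal support (frames); output is aligned to the
        central frame of the buffer.
    """

    def __init__(self, sigma_x: float = 1.5, sigma_t: float = 1.5,
                 n_taps_t: int = 9, truncate: float = 3.5):
        self.sigma_x = float(sigma_x)
        self.sigma_t = float(sigma_t)
        self.n_taps_t = int(n_taps_t)
        rx = max(1, int(np.ceil(truncate * sigma_x)))
        xs = np.arange(-rx, rx + 1) / sigma_x
        rt = (n_taps_t - 1) // 2
        ts = np.arange(-rt, rt + 1) / sigma_t
        g = lambda u: np.exp(-(u**2) / 2.0)
        norm = g(xs).sum()
        normt = g(ts).sum()
        # monomial-weighted 1-D kernels, Gaussian factor normalized to unit sum
        self._kx = {p: (xs**p) * g(xs) / norm for p in range(4)}
        self._kt = {p: (ts**p) * g(ts) / normt for p in range(4)}
        # discrete second moments (truncation makes them fall a little
        # short of 1); used to keep the steered G2 exactly DC-free
        self._m2x = float(self._kx[2].sum())
        self._m2t = float(self._kt[2].sum())
        self._g2_monos = _monomials(2)
        self._h2_monos = _monomials(1) + _monomials(3)

    # -- basis ---------------------------------------------------------

    def basis(self, stack: np.ndarray) -> dict[tuple[int, int, int], np.ndarray]:
        """Convolve a (T, H, W) luminance buffer with every needed
        separable monomial basis filter; returns single frames (the
        temporal kernels collapse the buffer onto its centre frame)."""
        stack = np.asarray(stack, dtype=float)
        if stack.shape[0] != self.n_taps_t:
            raise ValueError(
                f"buffer must hold {self.n_taps_t} frames, got {stack.shape[0]}"
            )
        needed = set(self._g2_monos) | set(self._h2_monos) | {(0, 0, 0)}
        # temporal stage first: buffer (T,H,W) -> frame (H,W) per temporal power
        t_frames: dict[int, np.ndarray] = {}
        for k in {m[2] for m in needed}:
            t_frames[k] = np.tensordot(self._kt[k][::-1], stack, axes=(0, 0))
        out: dict[tuple[int, int, int], np.ndarray] = {}
        y_cache: dict[tuple[int, int], np.ndarray] = {}
        for (i, j, k) in needed:
            if (j, k) not in y_cache:
                y_cache[(j, k)] = convolve1d(t_frames[k], self._kx[j], axis=0, mode="nearest")
            out[(i, j, k)] = convolve1d(y_cache[(j, k)], self._kx[i], axis=1, mode="nearest")
        return out

    # -- steering ------------------------------------------------------

    def g2_coeffs(self, w: np.ndarray) -> dict[tuple[int, int, int], float]:
        """Second directional derivative of the unit Gaussian along w:
        (w.x)^2 G - G in sigma-normalized coordinates."""
        a, b, c = w
        coeffs = {m: _multinom(*m) * a ** m[0] * b ** m[1] * c ** m[2]
                  for m in self._g2_monos}
        coeffs[(0, 0, 0)] = -((a * a + b * b) * self._m2x + c * c * self._m2t)
        return coeffs

    def h2_coeffs(self, w: np.ndarray) -> dict[tuple[int, int, int], float]:
        a, b, c = w
        c1, c3 = hilbert_g2_fit()
        coeffs = {m: c1 * _multinom(*m) * a ** m[0] * b ** m[1] * c ** m[2]
                  for m in _monomials(1)}
        for m in _monomials(3):
            coeffs[m] = c3 * _multinom(*m) * a ** m[0] * b ** m[1] * c ** m[2]
        return coeffs

    def steer(self, basis: dict, coeffs: dict) -> np.ndarray:
        out = None
        for m, c in coeffs.items():
            if c == 0.0:
                continue
            term = c * basis[m]
            out = term if out is None else out + term
        return out

    def energy(self, basis: dict, w: np.ndarray) -> np.ndarray:
        """Quadrature magnitude sqrt(G2^2 + H2^2) for steering vector w
        (phase-invariant: responds to both step edges and bars)."""
        g2 = self.steer(basis, self.g2_coeffs(w))
        h2 = self.steer(basis, self.h2_coeffs(w))
        return np.sqrt(g2 * g2 + h2 * h2)
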