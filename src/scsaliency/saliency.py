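"""Combining feature maps into the saliency response, and reading it
out at a neuron's receptive field.

The six high-level features (luminance contrast, red-green, blue-
yellow, orientation, flicker, motion) are equal-weight combinations of
the 60 low-level maps of matching type.  Per neuron, feature time
series collected at the RF centre are normalized leave-one-out (each
test clip by the per-feature maximum over all other clips), each
feature is aligned to the spike density by maximizing mutual
information over delays up to 150 ms, and the aligned features are
square-rooted and combined with equal weights into the saliency
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .features import FeatureStack

__all__ = [
    "combine_high_level",
    "loo_normalize",
    "DelayProfile",
    "mi_delay",
    "saliency_response",
    "rf_saliency",
    "rf_unit_mask",
    "fixation_window_mean",
]

_TYPE_OF = {
    "lum": "lum", "rg": "rg", "by": "by",
    "ori": "orientation", "flk": "flicker", "mot": "motion",
}


def combine_high_level(stack: FeatureStack) -> dict[str, np.ndarray]:
    """Equal-weight combination of same-type low-level maps into the
    six high-level maps.  Low-level map names are prefixed with their
    type tag (lum/rg/by/ori/flk/mot)."""
    groups: dict[str, list[np.ndarray]] = {k: [] for k in FeatureStack.HIGH_LEVEL_NAMES}
    for name, m in stack.low_level.items():
        tag = name.split(":")[0]
        if tag not in _TYPE_OF:
            raise KeyError(f"unrecognized low-level map name {name!r}")
        groups[_TYPE_OF[tag]].append(m)
    out = {}
    for k, maps in groups.items():
        if not maps:
            raise ValueError(f"no low-level maps of type {k!r}")
        out[k] = np.mean(maps, axis=0)
    return out


def loo_normalize(series_by_clip: dict, test_clip, eps: float = 0.0,
                  log: list | None = None) -> np.ndarray:
    """Leave-one-out normalization of one clip's feature time series.

    ``series_by_clip`` maps clip id -> (6, T) non-negative feature
    series.  The test clip is divided, per feature, by the maximum of
    that feature over all *other* clips, so its own values never enter
    its normalizer.  A feature whose training maximum is zero is
    dropped (set to NaN) for that fold and logged.
    """
    if len(series_by_clip) < 2:
        raise ValueError("need at least two clips for leave-one-out")
    if test_clip not in series_by_clip:
        raise KeyError(test_clip)
    train_max = None
    for cid, s in series_by_clip.items():
        if cid == test_clip:
            continue
        m = np.max(np.asarray(s, dtype=float), axis=-1)
        train_max = m if train_max is None else np.maximum(train_max, m)
    test = np.asarray(series_by_clip[test_clip], dtype=float).copy()
    out = np.full_like(test, np.nan)
    ok = train_max > eps
    out[ok] = test[ok] / train_max[ok, None]
    if log is not None and (~ok).any():
        log.append({"clip": test_clip, "dropped_features": np.flatnonzero(~ok).tolist()})
    return out


@dataclass
class DelayProfile:
    """Mutual information over candidate delays; ``delay_ms`` is the
    first argmax (ties resolved toward the smaller delay)."""

    delays_ms: np.ndarray
    mi: np.ndarray
    delay_ms: float
    degenerate: bool = False  # constant input: flat profile, delay 0


def _equal_occupancy_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Digitize into ~equal-count bins (quantile edges)."""
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    ia = _equal_occupancy_bins(a, bins)
    ib = _equal_occupancy_bins(b, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ia, ib), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mi_delay(feature: np.ndarray, rate: np.ndarray, max_delay_ms: float = 150.0,
             dt_ms: float = 5.0, bins: int = 16) -> DelayProfile:
    """Optimal feature-to-response delay by mutual information.

    Both series share a ``dt_ms`` clock (the rate series is the 5 ms
    binned, 50 ms Gaussian-smoothed spike density).  MI is estimated
    from the 2-D histogram with equal-occupancy marginals at each
    candidate delay (feature advanced by the delay) and the argmax is
    returned; the estimator's bias is immaterial because only the
    argmax over delays is used.
    """
    feature = np.asarray(feature, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if feature.shape != rate.shape:
        raise ValueError("series must share one length")
    delays = np.arange(0.0, max_delay_ms + dt_ms / 2, dt_ms)
    if np.ptp(feature) == 0 or np.ptp(rate) == 0:
        return DelayProfile(delays, np.zeros_like(delays), 0.0, degenerate=True)
    mi = np.empty_like(delays)
    for i, d in enumerate(delays):
        k = int(round(d / dt_ms))
        f = feature[:feature.size - k] if k else feature
        r = rate[k:]
        mi[i] = _mutual_information(f, r, bins)
    best = int(np.argmax(mi))  # first maximum: ties break to smaller delay
    return DelayProfile(delays, mi, float(delays[best]))


def saliency_response(features: np.ndarray) -> np.ndarray:
    """Equal-weight combination of square-rooted, delay-aligned
    high-level features: mean over features of sqrt(feature).

    ``features`` is (6, T) (or any leading feature axis), non-negative;
    NaN features (dropped folds) are ignored in the mean.
    """
    f = np.asarray(features, dtype=float)
    if np.nanmin(f) < 0:
        raise ValueError("features must be non-negative")
    return np.nanmean(np.sqrt(f), axis=0)


def rf_unit_mask(grid, polygon: np.ndarray) -> np.ndarray:
    """Boolean mask of grid units whose RF centres fall inside a
    visual-space polygon (from :func:`scsaliency.mapping.rf_boundary`)."""
    path = MplPath(polygon)
    pts = np.column_stack([grid.x_deg.ravel(), grid.y_deg.ravel()])
    mask = path.contains_points(pts).reshape(grid.x_deg.shape)
    if not mask.any():
        raise ValueError("RF region covers no grid units at this resolution")
    return mask


def rf_saliency(saliency_map: np.ndarray, mask: np.ndarray) -> float:
    """Normalized sum (mean over covered units) of the saliency output
    within the RF region."""
    if not mask.any():
        raise ValueError("empty RF mask")
    return float(np.asarray(saliency_map, dtype=float)[mask].mean())


def fixation_window_mean(series: np.ndarray, t_ms: np.ndarray, t_on: float,
                         window_ms: tuple[float, float] = (0.0, 200.0)) -> float:
    """Time-average of a 200 Hz series over a window relative to
    fixation onset (the per-fixation saliency statistic)."""
    rel = np.asarray(t_ms, dtype=float) - t_on
    m = (rel >= window_ms[0]) & (rel < window_ms[1])
    if not m.any():
        raise ValueError("window contains no samples")
    return float(np.asarray(series, dtype=float)[m].mean())
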