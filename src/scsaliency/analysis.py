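"""Fixation-locked neural and behavioural analyses.

Turns spike trains plus per-fixation model saliency into the study's
result set: neuron classification (visual-only superficial SCs vs
visuomotor intermediate SCi), spike-density estimation, per-neuron
saliency/rate rank correlations, saliency-tertile response curves,
saccade-goal (in vs opposite the RF) splits, a neurons x features
dependence matrix, and saliency effects on saccade behaviour
(frequency and reaction time of RF-directed saccades).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NeuronRecord",
    "epsp_kernel",
    "spike_density",
    "align_windows",
    "classify_neuron",
    "normalize_rate",
    "assign_tertiles",
    "per_neuron_correlation",
    "NeuronData",
    "tertile_curves",
    "goal_split_analysis",
    "feature_dependence",
    "behavioural_saliency",
]


@dataclass
class NeuronRecord:
    """Identity and geometry of a recorded neuron."""

    id: str
    rf_centre_xy: tuple[float, float]  # deg, gaze-anchored
    layer_class: str | None = None  # 'SCs' | 'SCi' | None (unclassified)
    visual_flag: bool | None = None
    motor_flag: bool | None = None

    @property
    def rf_eccentricity(self) -> float:
        return float(np.hypot(*self.rf_centre_xy))


# ---------------------------------------------------------------------------
# spike density
# ---------------------------------------------------------------------------

def epsp_kernel(dt_ms: float = 1.0, rise_ms: float = 5.0, decay_ms: float = 20.0,
                extent_ms: float = 200.0) -> np.ndarray:
    """Causal kernel resembling an excitatory post-synaptic potential,
    (1 - exp(-t/rise)) * exp(-t/decay) for t >= 0, unit integral in
    seconds so convolution with a spike train yields spk/s."""
    t = np.arange(0.0, extent_ms, dt_ms)
    k = (1.0 - np.exp(-t / rise_ms)) * np.exp(-t / decay_ms)
    return k / (k.sum() * dt_ms / 1000.0)


def spike_density(spikes_ms: np.ndarray, duration_ms: float,
                  kernel: str = "epsp", dt_ms: float | None = None,
                  gauss_sigma_ms: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Continuous firing-rate estimate from spike times.

    ``kernel='epsp'`` (1 ms bins, causal 5/20 ms kernel) for event-
    aligned analyses; ``kernel='gauss'`` (5 ms bins, 50 ms Gaussian)
    for the model-fitting path.  Returns (t_ms, rate_spks_per_s).
    """
    spikes = np.asarray(spikes_ms, dtype=float)
    if spikes.size and (spikes.min() < 0 or spikes.max() > duration_ms):
        raise ValueError("spike times must lie within the clip bounds")
    if kernel == "epsp":
        dt = 1.0 if dt_ms is None else dt_ms
        k = epsp_kernel(dt)
        mode_shift = 0  # causal: spike contributes only forward in time
    elif kernel == "gauss":
        dt = 5.0 if dt_ms is None else dt_ms
        half = int(np.ceil(4 * gauss_sigma_ms / dt))
        tt = np.arange(-half, half + 1) * dt
        k = np.exp(-(tt**2) / (2 * gauss_sigma_ms**2))
        k /= k.sum() * dt / 1000.0
        mode_shift = half
    else:
        raise ValueError("kernel must be 'epsp' or 'gauss'")
    edges = np.arange(0.0, duration_ms + dt, dt)
    counts, _ = np.histogram(spikes, bins=edges)
    rate = np.convolve(counts, k)[mode_shift:mode_shift + counts.size]
    t = edges[:-1]
    return t, rate


def align_windows(rate: np.ndarray, t_ms: np.ndarray, events_ms: np.ndarray,
                  window_ms: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Cut the rate series into event-aligned windows.

    Returns (rel_t, matrix) with matrix shape (n_events, T); windows
    running off the series are NaN-padded.
    """
    dt = float(t_ms[1] - t_ms[0])
    n0 = int(round(window_ms[0] / dt))
    n1 = int(round(window_ms[1] / dt))
    rel_t = np.arange(n0, n1) * dt
    out = np.full((len(events_ms), n1 - n0), np.nan)
    for i, ev in enumerate(np.asarray(events_ms, dtype=float)):
        c = int(round((ev - t_ms[0]) / dt))
        lo, hi = c + n0, c + n1
        s_lo, s_hi = max(lo, 0), min(hi, rate.size)
        if s_lo < s_hi:
            out[i, s_lo - lo:s_hi - lo] = rate[s_lo:s_hi]
    return rel_t, out


# ---------------------------------------------------------------------------
# classification and normalization
# ---------------------------------------------------------------------------

def _window_rates(trials: list[np.ndarray], window: tuple[float, float]) -> np.ndarray:
    w = (window[1] - window[0]) / 1000.0
    return np.array([np.count_nonzero((np.asarray(tr) >= window[0])
                                      & (np.asarray(tr) < window[1])) / w
                     for tr in trials])


def classify_neuron(stim_aligned_trials: list[np.ndarray] | None,
                    sacc_aligned_trials: list[np.ndarray] | None,
                    alpha: float = 0.05, min_trials: int = 10):
    """Visual/motor flags from delayed-saccade (or free-viewing
    fallback) trials and the resulting layer class.

    Visual: mean rate 40-120 ms post stimulus greater than the -80-0 ms
    baseline (one-sided paired test).  Motor: rate within +/-25 ms of
    saccade onset greater than the -150 to -50 ms pre-saccadic
    baseline.  Visual without motor -> SCs; visual with motor -> SCi;
    not visually responsive -> excluded (layer ``None``).  Fewer than
    ``min_trials`` usable trials on a test -> unclassified (``None``
    flags).
    """
    def flag(trials, win, base):
        if trials is None or len(trials) < min_trials:
            return None
        a = _window_rates(trials, win)
        b = _window_rates(trials, base)
        if np.all(a == b):
            return False
        return bool(stats.ttest_rel(a, b, alternative="greater").pvalue < alpha)

    visual = flag(stim_aligned_trials, (40.0, 120.0), (-80.0, 0.0))
    motor = flag(sacc_aligned_trials, (-25.0, 25.0), (-150.0, -50.0))
    if visual is None:
        return None, motor, None
    if not visual:
        return False, motor, None  # not visually responsive: excluded
    layer = "SCi" if motor else "SCs"
    return True, bool(motor) if motor is not None else None, layer


def normalize_rate(density: np.ndarray, t_ms: np.ndarray,
                   window_ms: tuple[float, float] = (0.0, 500.0)):
    """0-1 rescaling of a spike density function, (x - min)/(max - min),
    with the min/max taken within the post-fixation window.

    Returns (normalized, flat_flag); a constant density normalizes to
    zeros with the flag set.  Scale-invariant by construction.
    """
    density = np.asarray(density, dtype=float)
    m = (np.asarray(t_ms) >= window_ms[0]) & (np.asarray(t_ms) < window_ms[1])
    ref = density[m] if m.any() else density
    ref = ref[np.isfinite(ref)]
    lo, hi = (ref.min(), ref.max()) if ref.size else (0.0, 0.0)
    if hi <= lo:
        return np.zeros_like(density), True
    return (density - lo) / (hi - lo), False


def assign_tertiles(values: np.ndarray) -> np.ndarray:
    """Split by rank into low/medium/high (0/1/2) with sizes differing
    by at most one; ties keep their stable input order."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    out = np.empty(values.size, dtype=int)
    for lev, chunk in enumerate(np.array_split(order, 3)):
        out[chunk] = lev
    return out


def per_neuron_correlation(saliency: np.ndarray, rate: np.ndarray,
                           min_n: int = 65):
    """Spearman correlation between per-fixation model saliency and
    firing rate; two-sided p.  Requires the study's minimum fixation
    count per neuron; degenerate (zero-variance) inputs return NaN."""
    saliency = np.asarray(saliency, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if saliency.size < min_n:
        raise ValueError(f"need at least {min_n} fixations, got {saliency.size}")
    if np.ptp(saliency) == 0 or np.ptp(rate) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(saliency, rate)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# population containers and condition analyses
# ---------------------------------------------------------------------------

@dataclass
class NeuronData:
    """Everything the condition analyses need for one neuron.

    ``samples`` has one row per included fixation with columns
    ``saliency`` (RF saliency, 0-200 ms window), ``rate`` (epoch mean
    rate), ``duration`` (ms), ``goal`` ('in'/'opposite'/'other'/None)
    and optionally per-feature ``sal_<name>`` columns.  ``dens_fix``
    and ``dens_sac`` are fixation- and saccade-aligned density windows
    (rows matching ``samples``), with time axes ``t_fix``/``t_sac``.
    """

    record: NeuronRecord
    samples: pd.DataFrame
    t_fix: np.ndarray | None = None
    dens_fix: np.ndarray | None = None
    t_sac: np.ndarray | None = None
    dens_sac: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def layer(self) -> str | None:
        return self.record.layer_class


_EPOCHS = {"fixation": (0.0, 200.0), "saccade": (-150.0, -50.0)}


def _epoch_mean(t: np.ndarray, dens: np.ndarray, epoch: tuple[float, float]) -> np.ndarray:
    m = (t >= epoch[0]) & (t < epoch[1])
    return np.nanmean(dens[:, m], axis=1)


def _aligned(nd: NeuronData, alignment: str):
    if alignment == "fixation":
        return nd.t_fix, nd.dens_fix, np.ones(len(nd.samples), dtype=bool)
    # saccade-aligned analyses need the -150..-50 ms window saccade-free,
    # so fixations shorter than 150 ms before the saccade are dropped
    ok = (nd.samples["duration"].to_numpy() >= 150.0) & nd.samples["goal"].notna().to_numpy()
    return nd.t_sac, nd.dens_sac, ok


def _norm_condition_curves(t, curves: dict, norm_window=(0.0, 500.0)):
    """0-1 rescale a set of per-condition mean curves jointly (one
    min/max per neuron across its conditions), preserving
    between-condition amplitude differences."""
    stacked = np.concatenate([c for c in curves.values() if c is not None])
    msk = (t >= norm_window[0]) & (t < norm_window[1])
    ref = stacked if not msk.any() else np.concatenate(
        [c[msk] for c in curves.values() if c is not None])
    ref = ref[np.isfinite(ref)]
    lo, hi = (ref.min(), ref.max()) if ref.size else (0.0, 0.0)
    if hi <= lo:
        return {k: np.zeros_like(v) if v is not None else None for k, v in curves.items()}
    return {k: (v - lo) / (hi - lo) if v is not None else None for k, v in curves.items()}


def tertile_curves(neurons: list[NeuronData], alignment: str = "fixation",
                   norm_mode: str = "across"):
    """Saliency-tertile condition curves and epoch means.

    Per neuron, fixations are ranked into tertiles of RF saliency; the
    mean aligned density per tertile is 0-1 normalized (jointly across
    the three conditions by default) and averaged across neurons.
    Returns (curves, table): ``curves[level] = (t, mean, sem)`` and a
    long-format per-neuron condition table for repeated-measures
    testing.
    """
    epoch = _EPOCHS[alignment]
    rows = []
    percurve: dict[int, list[np.ndarray]] = {0: [], 1: [], 2: []}
    t_axis = None
    for nd in neurons:
        t, dens, ok = _aligned(nd, alignment)
        if t is None or not ok.any():
            continue
        t_axis = t
        sal = nd.samples["saliency"].to_numpy()[ok]
        tert = assign_tertiles(sal)
        curves = {}
        for lev in (0, 1, 2):
            sel = tert == lev
            curves[lev] = np.nanmean(dens[ok][sel], axis=0) if sel.any() else None
        if norm_mode == "across":
            curves = _norm_condition_curves(t, curves,
                                            (0.0, 500.0) if alignment == "fixation" else (t[0], t[-1]))
        else:
            curves = {k: normalize_rate(v, t)[0] if v is not None else None
                      for k, v in curves.items()}
        for lev, c in curves.items():
            if c is None:
                continue
            percurve[lev].append(c)
            m = (t >= epoch[0]) & (t < epoch[1])
            rows.append({"neuron": nd.record.id, "layer": nd.layer,
                         "tertile": ("low", "medium", "high")[lev],
                         "epoch_mean": float(np.nanmean(c[m]))})
    out_curves = {}
    for lev, lst in percurve.items():
        if lst:
            arr = np.vstack(lst)
            out_curves[("low", "medium", "high")[lev]] = (
                t_axis, np.nanmean(arr, axis=0), _sem(arr))
    return out_curves, pd.DataFrame(rows)


def _sem(arr: np.ndarray) -> np.ndarray:
    if arr.shape[0] < 2:
        return np.zeros(arr.shape[1])
    return np.nanstd(arr, axis=0, ddof=1) / np.sqrt(arr.shape[0])


@dataclass
class GoalSplitResult:
    table: pd.DataFrame                    # neuron, layer, goal, level, epoch_mean
    tests: dict                            # (layer, goal) -> dict(t, p, significant)
    curves: dict                           # (layer, goal, level) -> (t, mean, sem)
    divergence: dict = field(default_factory=dict)  # (layer, goal) -> bool per bin


def goal_split_analysis(neurons: list[NeuronData], alignment: str = "fixation",
                        alpha: float = 0.05) -> GoalSplitResult:
    """High-vs-low saliency split by next-saccade goal (in/opposite).

    Per neuron: upper- and lower-tertile fixations, crossed with the
    goal label, give four condition curves, 0-1 normalized jointly.
    Across neurons: per-(layer, goal) one-tailed paired t-test of the
    high-vs-low epoch means, Bonferroni-corrected over the two goal
    conditions, plus per-5-ms-bin paired Wilcoxon divergence marks with
    Bonferroni-Holm correction.
    """
    epoch = _EPOCHS[alignment]
    rows = []
    curve_bank: dict[tuple, list[np.ndarray]] = {}
    t_axis = None
    for nd in neurons:
        t, dens, ok = _aligned(nd, alignment)
        if t is None:
            continue
        s = nd.samples
        goal = s["goal"].astype(object).to_numpy()
        sal = s["saliency"].to_numpy()
        tert = assign_tertiles(sal)
        level = np.where(tert == 2, "high", np.where(tert == 0, "low", None))
        conds = {}
        for g in ("in", "opposite"):
            for lev in ("high", "low"):
                sel = ok & (goal == g) & (level == lev)
                conds[(g, lev)] = np.nanmean(dens[sel], axis=0) if sel.any() else None
        if any(v is None for v in conds.values()):
            continue  # neuron dropped from this contrast
        t_axis = t
        conds = _norm_condition_curves(
            t, conds, (0.0, 500.0) if alignment == "fixation" else (t[0], t[-1]))
        m = (t >= epoch[0]) & (t < epoch[1])
        for (g, lev), c in conds.items():
            curve_bank.setdefault((nd.layer, g, lev), []).append(c)
            rows.append({"neuron": nd.record.id, "layer": nd.layer, "goal": g,
                         "level": lev, "epoch_mean": float(np.nanmean(c[m]))})
    table = pd.DataFrame(rows)
    tests: dict = {}
    curves: dict = {}
    divergence: dict = {}
    for key, lst in curve_bank.items():
        arr = np.vstack(lst)
        curves[key] = (t_axis, np.nanmean(arr, axis=0), _sem(arr))
    if len(table):
        for layer in table["layer"].dropna().unique():
            for g in ("in", "opposite"):
                sub = table[(table["layer"] == layer) & (table["goal"] == g)]
                piv = sub.pivot(index="neuron", columns="level", values="epoch_mean")
                if not {"high", "low"}.issubset(piv.columns) or len(piv) < 2:
                    continue
                res = stats.ttest_rel(piv["high"], piv["low"], alternative="greater")
                tests[(layer, g)] = {
                    "t": float(res.statistic), "p": float(res.pvalue),
                    "n": int(len(piv)),
                    # Bonferroni over the two goal conditions
                    "significant": bool(res.pvalue < alpha / 2.0),
                }
                hi = curve_bank.get((layer, g, "high"))
                lo = curve_bank.get((layer, g, "low"))
                if hi is not None and lo is not None and len(hi) == len(lo):
                    divergence[(layer, g)] = _divergence_marks(
                        np.vstack(hi), np.vstack(lo), alpha)
    return GoalSplitResult(table=table, tests=tests, curves=curves,
                           divergence=divergence)


def _divergence_marks(hi: np.ndarray, lo: np.ndarray, alpha: float) -> np.ndarray:
    """Per-bin paired Wilcoxon tests across neurons, Bonferroni-Holm
    corrected over bins."""
    nbin = hi.shape[1]
    p = np.ones(nbin)
    for i in range(nbin):
        a, b = hi[:, i], lo[:, i]
        good = np.isfinite(a) & np.isfinite(b)
        if good.sum() >= 5 and np.any(a[good] != b[good]):
            p[i] = stats.wilcoxon(a[good], b[good]).pvalue
    return multipletests(p, alpha=alpha, method="holm")[0]


def feature_dependence(neurons: list[NeuronData],
                       feature_names=("lum", "rg", "by", "orientation", "flicker", "motion"),
                       alpha: float = 0.05, goal: str | None = "in"):
    """Neurons x features activation-difference matrix.

    Entry (neuron, feature) is the mean 0-1-normalized epoch rate for
    the feature's high tertile minus its low tertile, using per-feature
    RF saliency (``sal_<feature>`` sample columns).  Population test:
    one-tailed one-sample t per feature, Bonferroni-corrected.
    Returns (matrix DataFrame, tests DataFrame).
    """
    recs = {}
    for nd in neurons:
        s = nd.samples
        sel = np.ones(len(s), dtype=bool)
        if goal is not None:
            sel &= (s["goal"] == goal).to_numpy()
        if sel.sum() < 6:
            continue
        rate = s["rate"].to_numpy(float)[sel]
        lo_r, hi_r = rate.min(), rate.max()
        norm = (rate - lo_r) / (hi_r - lo_r) if hi_r > lo_r else np.zeros_like(rate)
        row = {}
        for f in feature_names:
            col = f"sal_{f}"
            if col not in s.columns:
                row[f] = np.nan
                continue
            tert = assign_tertiles(s[col].to_numpy(float)[sel])
            row[f] = float(norm[tert == 2].mean() - norm[tert == 0].mean())
        recs[nd.record.id] = row
    matrix = pd.DataFrame.from_dict(recs, orient="index")[list(feature_names)]
    tests = []
    k = len(feature_names)
    for f in feature_names:
        vals = matrix[f].dropna()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            res = stats.ttest_1samp(vals, 0.0, alternative="greater")
            tests.append({"feature": f, "mean": float(vals.mean()),
                          "t": float(res.statistic), "p": float(res.pvalue),
                          "significant": bool(res.pvalue < alpha / k)})
        else:
            tests.append({"feature": f, "mean": float(vals.mean()) if len(vals) else np.nan,
                          "t": np.nan, "p": np.nan, "significant": False})
    return matrix, pd.DataFrame(tests)


@dataclass
class BehaviouralResult:
    n_in_high: int
    n_in_low: int
    rt_high_mean: float
    rt_low_mean: float
    p_counts: float
    p_rt: float


def behavioural_saliency(samples: pd.DataFrame) -> BehaviouralResult:
    """Saliency effects on saccade behaviour.

    Among fixations in the saliency tertile extremes (pooled over
    neurons), compares (a) how often the next saccade goes in the RF
    (binomial test on the high/low split of goal-in saccades) and
    (b) the reaction time -- fixation duration -- of goal-in saccades
    (one-sided rank-sum, high faster).
    ``samples`` needs columns saliency, goal, duration, neuron.
    """
    parts = []
    for _, sub in samples.groupby("neuron"):
        tert = assign_tertiles(sub["saliency"].to_numpy(float))
        lab = np.where(tert == 2, "high", np.where(tert == 0, "low", "mid"))
        parts.append(sub.assign(level=lab))
    df = pd.concat(parts, ignore_index=True)
    df = df[df["level"].isin(["high", "low"])]
    inn = df[df["goal"] == "in"]
    n_hi = int((inn["level"] == "high").sum())
    n_lo = int((inn["level"] == "low").sum())
    p_counts = stats.binomtest(n_hi, n_hi + n_lo, 0.5,
                               alternative="greater").pvalue if n_hi + n_lo else 1.0
    rt_hi = inn.loc[inn["level"] == "high", "duration"].to_numpy(float)
    rt_lo = inn.loc[inn["level"] == "low", "duration"].to_numpy(float)
    if rt_hi.size and rt_lo.size:
        p_rt = stats.mannwhitneyu(rt_hi, rt_lo, alternative="less").pvalue
    else:
        p_rt = 1.0
    return BehaviouralResult(
        n_in_high=n_hi, n_in_low=n_lo,
        rt_high_mean=float(rt_hi.mean()) if rt_hi.size else float("nan"),
        rt_low_mean=float(rt_lo.mean()) if rt_lo.size else float("nan"),
        p_counts=float(p_counts), p_rt=float(p_rt))
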