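"""Neural pattern similarity (NPS), spatiotemporal pattern similarity (STPS)
and inter-subject correlation (ISC).

These three analyses correlate raw activity patterns directly instead of
going through RDMs:

- **NPS** — the Pearson correlation between the trial-averaged patterns
  evoked by exactly two conditions, per subject (and optionally per channel
  and sliding time window).
- **STPS** — for each condition label, the average pairwise Pearson
  correlation between the flattened space-by-time patterns of all trials
  sharing that label; high STPS means trials of a condition evoke a
  consistent spatiotemporal pattern. A within-minus-between-label contrast
  is available.
- **ISC** — the Pearson correlation of the same signal between every pair
  of subjects (canonical order i < j), per channel/voxel and window;
  a leave-one-out variant correlates each subject against the average of
  the others.

All statistics are plain Pearson correlations and therefore invariant to
any positive rescaling and shift of the input signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .arrays import NeuroArray, WindowSpec

__all__ = ["NPSMap", "ISCPairMap", "nps", "stps", "isc"]


@dataclass(frozen=True)
class NPSMap:
    """Per-index Pearson r between two conditions' patterns."""

    values: np.ndarray
    axes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "axes", tuple(self.axes))


@dataclass(frozen=True)
class ISCPairMap:
    """Per subject-pair ``(r, p)``; ``pairs[k] = (i, j)`` with ``i < j``."""

    values: np.ndarray
    axes: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "axes", tuple(self.axes))
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        if self.values.shape[-1] != 2:
            raise ValueError("last axis must hold (r, p)")


def _pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two 1-d vectors; NaN if either is constant."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return float("nan")
    return float(np.clip(a @ b / denom, -1.0, 1.0))


def _pearson_r_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    r = _pearson_r(a, b)
    n = a.size
    if not np.isfinite(r) or n < 3:
        return r, float("nan")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * sps.t.sf(abs(t), n - 2))


def _window_slices(n_times: int, per_window: bool, window: WindowSpec | None):
    if per_window:
        window = window or WindowSpec()
        return window.slices(n_times)
    return [slice(0, n_times)]


def nps(
    data: NeuroArray,
    per_channel: bool = False,
    per_window: bool = False,
    window: WindowSpec | None = None,
) -> NPSMap:
    """Neural pattern similarity between exactly two conditions.

    For EEG-like data ``[2, subject, trial, channel, time]`` trials are
    averaged within condition; at each index the two conditions'
    channel-by-window patterns are flattened and Pearson-correlated.
    fMRI-like data ``[2, subject, x, y, z]`` yield one r per subject over
    all finite voxels. Constant patterns give NaN.
    """
    if data.n_conditions != 2:
        raise ValueError(f"NPS needs exactly 2 conditions, got {data.n_conditions}")

    if data.modality == "fmri":
        vals = data.values  # [2, sub, x, y, z]
        n_sub = vals.shape[1]
        out = np.empty(n_sub)
        for s in range(n_sub):
            a, b = vals[0, s].ravel(), vals[1, s].ravel()
            finite = np.isfinite(a) & np.isfinite(b)
            out[s] = _pearson_r(a[finite], b[finite])
        return NPSMap(out, ("subject",))

    data.require_modality("eeg")
    avg = data.values.mean(axis=2)  # [2, sub, chl, time]
    _, n_sub, n_chl, n_times = avg.shape
    chl_groups = [[c] for c in range(n_chl)] if per_channel else [list(range(n_chl))]
    slices = _window_slices(n_times, per_window, window)

    out = np.empty((n_sub, len(chl_groups), len(slices)))
    for s in range(n_sub):
        for gi, group in enumerate(chl_groups):
            for wi, sl in enumerate(slices):
                a = avg[0, s, group, sl].ravel()
                b = avg[1, s, group, sl].ravel()
                out[s, gi, wi] = _pearson_r(a, b)
    axes = ["subject"]
    keep = [True, per_channel, per_window]
    shape = tuple(d for d, k in zip(out.shape, keep) if k)
    if per_channel:
        axes.append("channel")
    if per_window:
        axes.append("window")
    return NPSMap(out.reshape(shape), tuple(axes))


def stps(
    data: NeuroArray,
    labels,
    per_channel: bool = False,
    per_window: bool = False,
    window: WindowSpec | None = None,
    contrast: str = "within",
) -> NPSMap:
    """Spatiotemporal pattern similarity per condition label.

    ``data`` is trial-level: axes ``[subject, trial, channel, time]``;
    ``labels`` assigns one condition label per trial (each label needs at
    least 2 trials). For each label, subject (and optional channel/window
    index) the statistic is the mean pairwise Pearson r between the
    flattened channel-by-window patterns of all same-label trial pairs.
    ``contrast="within_minus_between"`` subtracts the mean correlation of
    trial pairs with differing labels.

    Output axes: ``(label, subject[, channel][, window])``.
    """
    if data.axes != ("subject", "trial", "channel", "time"):
        raise ValueError(
            f"STPS expects trial-level axes (subject, trial, channel, time), got {data.axes}"
        )
    if contrast not in ("within", "within_minus_between"):
        raise ValueError("contrast must be 'within' or 'within_minus_between'")
    labels = np.asarray(labels)
    vals = data.values
    n_sub, n_trial, n_chl, n_times = vals.shape
    if labels.shape != (n_trial,):
        raise ValueError(f"need one label per trial ({n_trial}), got {labels.shape}")
    uniq = np.unique(labels)
    for lab in uniq:
        if np.sum(labels == lab) < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 trials")

    chl_groups = [[c] for c in range(n_chl)] if per_channel else [list(range(n_chl))]
    slices = _window_slices(n_times, per_window, window)

    out = np.empty((len(uniq), n_sub, len(chl_groups), len(slices)))
    for s in range(n_sub):
        for gi, group in enumerate(chl_groups):
            for wi, sl in enumerate(slices):
                pats = vals[s][:, group, sl].reshape(n_trial, -1)
                corr = _pairwise_corr(pats)
                for li, lab in enumerate(uniq):
                    sel = labels == lab
                    within = corr[np.ix_(sel, sel)][np.triu_indices(sel.sum(), k=1)]
                    value = np.nanmean(within)
                    if contrast == "within_minus_between":
                        between = corr[np.ix_(sel, ~sel)]
                        value -= np.nanmean(between) if between.size else 0.0
                    out[li, s, gi, wi] = value
    axes = ["label", "subject"]
    keep = [True, True, per_channel, per_window]
    shape = tuple(d for d, k in zip(out.shape, keep) if k)
    if per_channel:
        axes.append("channel")
    if per_window:
        axes.append("window")
    return NPSMap(out.reshape(shape), tuple(axes))


def _pairwise_corr(rows: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of row vectors; NaN rows where constant."""
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norms[:, None]
        corr = np.clip(z @ z.T, -1.0, 1.0)
    corr[norms == 0, :] = np.nan
    corr[:, norms == 0] = np.nan
    return corr


def isc(
    data: NeuroArray,
    per_window: bool = False,
    window: WindowSpec | None = None,
    method: str = "pairwise",
) -> ISCPairMap:
    """Inter-subject correlation of a shared time-resolved signal.

    ``data`` has axes ``[subject, channel, time]`` or
    ``[subject, x, y, z, time]``. For every canonical subject pair
    ``(i, j), i < j`` (or, with ``method="loo"``, every subject against the
    mean of all others), the two time series are Pearson-correlated within
    each window at each channel/voxel, giving ``(r, p)`` with the
    parametric two-sided p.
    """
    if data.axes not in (("subject", "channel", "time"), ("subject", "x", "y", "z", "time")):
        raise ValueError(
            "ISC expects axes (subject, channel, time) or (subject, x, y, z, time), "
            f"got {data.axes}"
        )
    if method not in ("pairwise", "loo"):
        raise ValueError("method must be 'pairwise' or 'loo'")
    vals = data.values
    n_sub = vals.shape[0]
    if n_sub < 2:
        raise ValueError("ISC needs at least 2 subjects")
    feature_shape = vals.shape[1:-1]
    n_times = vals.shape[-1]
    slices = _window_slices(n_times, per_window, window)

    if method == "pairwise":
        pairs = tuple(combinations(range(n_sub), 2))
        series = [(vals[i], vals[j]) for i, j in pairs]
    else:
        pairs = tuple((i, -1) for i in range(n_sub))
        series = []
        for i in range(n_sub):
            others = np.delete(vals, i, axis=0).mean(axis=0)
            series.append((vals[i], others))

    out = np.empty((len(pairs),) + feature_shape + (len(slices), 2))
    for k, (a, b) in enumerate(series):
        for fi in np.ndindex(*feature_shape):
            for wi, sl in enumerate(slices):
                out[(k, *fi, wi)] = _pearson_r_p(a[fi][sl], b[fi][sl])
    axes = ("pair",) + data.axes[1:-1] + (("window",) if per_window else ())
    if not per_window:
        out = out.reshape((len(pairs),) + feature_shape + (2,))
    return ISCPairMap(out, axes, pairs)
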