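"""Representational dissimilarity matrices (RDMs) from condition patterns.

An RDM over ``n`` conditions is the ``n x n`` symmetric matrix with zero
diagonal whose entry ``D[i, j] = 1 - similarity(d_i, d_j)`` (correlation
distance) or a metric distance (Euclidean, Mahalanobis) between the pattern
vectors of conditions ``i`` and ``j``.

RDMs can be computed at several granularities — per subject, per channel,
per sliding time window, per ROI, per searchlight unit — and are collected
in an :class:`RDMMap` indexed by the enabled granularity axes. A unit whose
data are unusable (non-finite voxels, zero-variance pattern under the
correlation measure inside a searchlight) is marked missing with an all-NaN
slice rather than raising, so one bad blob never aborts a whole-brain run.

Conventions fixed here and relied on elsewhere:

- trials are averaged within condition before any distance is computed;
- voxels are flattened x-fastest, then y, then z (Fortran order);
- correlation distance is ``1 - Pearson r``, kept on its natural [0, 2] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist, squareform
from sklearn.covariance import ledoit_wolf

from .arrays import NeuroArray, SearchlightGrid, WindowSpec

__all__ = [
    "MEASURES",
    "ZeroVarianceError",
    "RDM",
    "RDMMap",
    "rdm_from_patterns",
    "behavioral_rdms",
    "eeg_rdms",
    "fmri_roi_rdm",
    "fmri_searchlight_rdms",
]

MEASURES = ("correlation", "euclidean", "mahalanobis")


class ZeroVarianceError(ValueError):
    """A pattern has no variance, so Pearson correlation is undefined."""


@dataclass(frozen=True)
class RDM:
    """A square symmetric dissimilarity matrix over conditions."""

    values: np.ndarray
    measure: str = "correlation"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"RDM must be square, got shape {values.shape}")
        if values.shape[0] < 2:
            raise ValueError("RDM needs at least 2 conditions")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; choose from {MEASURES}")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def is_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def validate(self, atol: float = 1e-10) -> None:
        """Check symmetry, zero diagonal and the measure's value range."""
        v = self.values
        if self.is_missing:
            return
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("RDM is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=atol):
            raise ValueError("RDM diagonal is not zero")
        if self.measure == "correlation":
            if v.min() < -atol or v.max() > 2 + atol:
                raise ValueError("correlation-distance entries must lie in [0, 2]")
        elif v.min() < -atol:
            raise ValueError("distance entries must be non-negative")

    def permute_conditions(self, order: np.ndarray) -> "RDM":
        order = np.asarray(order)
        return RDM(self.values[np.ix_(order, order)], self.measure)


@dataclass(frozen=True)
class RDMMap:
    """RDMs indexed by granularity axes (subject, channel, window, x, y, z).

    ``values`` has shape ``index_shape + (n_conditions, n_conditions)``;
    ``axes`` names the index axes in order. Missing units hold all-NaN
    slices.
    """

    values: np.ndarray
    axes: tuple[str, ...]
    measure: str = "correlation"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "axes", tuple(self.axes))
        if values.ndim != len(self.axes) + 2:
            raise ValueError(
                f"values ndim {values.ndim} inconsistent with index axes {self.axes}"
            )
        if values.shape[-1] != values.shape[-2]:
            raise ValueError("trailing axes must be square (condition x condition)")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[-1]

    @property
    def index_shape(self) -> tuple[int, ...]:
        return self.values.shape[:-2]

    def missing_mask(self) -> np.ndarray:
        """Boolean array over the index shape; True where the RDM is missing."""
        return np.isnan(self.values).any(axis=(-2, -1))

    def indices(self):
        return product(*(range(s) for s in self.index_shape))

    def rdm(self, index: tuple[int, ...] = ()) -> RDM:
        return RDM(self.values[tuple(index)], self.measure)


# ---------------------------------------------------------------------------
# single-RDM computation


def _finalize(d: np.ndarray, measure: str) -> np.ndarray:
    """Enforce exact symmetry, zero diagonal and the measure's range."""
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    if measure == "correlation":
        d = np.clip(d, 0.0, 2.0)
    else:
        d = np.clip(d, 0.0, None)
    return d


def _mahalanobis_vi(patterns: np.ndarray) -> np.ndarray:
    """Inverse covariance for the Mahalanobis distance.

    The feature covariance is estimated from the condition patterns with
    Ledoit-Wolf analytic shrinkage (needed because the number of conditions
    is typically far below the number of features), then pseudo-inverted.
    """
    cov, _ = ledoit_wolf(patterns, assume_centered=False)
    return np.linalg.pinv(cov)


def rdm_from_patterns(patterns: np.ndarray, measure: str = "correlation") -> RDM:
    """Compute one RDM from a ``condition x feature`` pattern matrix.

    Parameters
    ----------
    patterns
        Array ``[n_conditions, n_features]``; each row is one condition's
        pattern vector.
    measure
        ``"correlation"`` (``1 - Pearson r``), ``"euclidean"`` or
        ``"mahalanobis"``.

    Raises
    ------
    ZeroVarianceError
        If a row is constant under the correlation measure.
    ValueError
        Non-finite input, fewer than 2 conditions, or fewer than 2 features
        under the correlation measure.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError(f"patterns must be 2-d, got shape {patterns.shape}")
    n_cond, n_feat = patterns.shape
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    if not np.isfinite(patterns).all():
        raise ValueError("patterns contain non-finite values")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")

    if measure == "correlation":
        if n_feat < 2:
            raise ValueError("correlation distance needs at least 2 features")
        sd = patterns.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)
            raise ZeroVarianceError(
                f"condition(s) {bad.tolist()} have zero-variance patterns; "
                "Pearson correlation is undefined"
            )
        d = 1.0 - np.corrcoef(patterns)
    elif measure == "euclidean":
        d = squareform(pdist(patterns, metric="euclidean"))
    else:  # mahalanobis
        vi = _mahalanobis_vi(patterns)
        d = squareform(pdist(patterns, metric="mahalanobis", VI=vi))
    return RDM(_finalize(d, measure), measure)


def _correlation_rdms_stack(patterns: np.ndarray) -> np.ndarray:
    """Correlation-distance RDMs for a stack ``[..., n_cond, k]`` of pattern
    matrices, vectorized; degenerate slices (non-finite values or a
    zero-variance row) come back all-NaN."""
    patterns = np.asarray(patterns, dtype=float)
    k = patterns.shape[-1]
    mean = patterns.mean(axis=-1, keepdims=True)
    centered = patterns - mean
    sd = centered.std(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / (sd[..., None] * np.sqrt(k))
        corr = z @ np.swapaxes(z, -1, -2)
    d = 1.0 - corr
    d = (d + np.swapaxes(d, -1, -2)) / 2.0
    idx = np.arange(patterns.shape[-2])
    d[..., idx, idx] = 0.0
    d = np.clip(d, 0.0, 2.0)
    bad = ~np.isfinite(patterns).all(axis=(-2, -1)) | (sd == 0).any(axis=-1)
    d[bad] = np.nan
    return d


# ---------------------------------------------------------------------------
# modality front-ends


def behavioral_rdms(
    data: NeuroArray, per_subject: bool = True, measure: str = "correlation"
) -> RDMMap:
    """RDMs from behavioral data ``[condition, subject, trial]``.

    With ``per_subject`` one RDM per subject is computed from that subject's
    per-condition trial vectors; otherwise a single RDM from the
    subject-averaged trial vectors. Trial counts must agree across
    conditions (the rectangular array enforces this; NaN placeholders are
    rejected).
    """
    data.require_modality("behavior")
    data.require_conditions(2)
    if not np.isfinite(data.values).all():
        raise ValueError(
            "behavioral data contain non-finite values; unequal trial counts "
            "across conditions are not supported"
        )
    vals = data.values  # [cond, sub, trial]
    if per_subject:
        n_sub = vals.shape[1]
        rdms = [
            rdm_from_patterns(vals[:, s, :], measure).values for s in range(n_sub)
        ]
        return RDMMap(np.stack(rdms), ("subject",), measure)
    patterns = vals.mean(axis=1)  # [cond, trial]
    return RDMMap(rdm_from_patterns(patterns, measure).values, (), measure)


def eeg_rdms(
    data: NeuroArray,
    per_subject: bool = True,
    per_channel: bool = False,
    per_window: bool = False,
    window: WindowSpec | None = None,
    channels: list[int] | None = None,
    measure: str = "correlation",
) -> RDMMap:
    """RDMs from EEG-like data ``[condition, subject, trial, channel, time]``.

    Trials are averaged within condition first. The pattern for one
    condition at one index is the trial-averaged data restricted to the
    active channel subset and time window, flattened. Output index axes, in
    order: subject (if ``per_subject``), channel (if ``per_channel``),
    window (if ``per_window``).

    ``channels`` restricts the channel subset when ``per_channel`` is off;
    an explicit empty subset is an error.
    """
    data.require_modality("eeg")
    data.require_conditions(2)
    vals = data.values.mean(axis=2)  # [cond, sub, chl, time]
    n_cond, n_sub, n_chl, n_times = vals.shape

    if not per_subject:
        vals = vals.mean(axis=1, keepdims=True)
        n_sub = 1
    if per_channel:
        chl_groups = [[c] for c in range(n_chl)]
    else:
        subset = list(range(n_chl)) if channels is None else list(channels)
        if len(subset) == 0:
            raise ValueError("empty channel subset")
        if any(c < 0 or c >= n_chl for c in subset):
            raise ValueError(f"channel subset {subset} out of range for {n_chl} channels")
        chl_groups = [subset]
    if per_window:
        if window is None:
            window = WindowSpec()
        win_slices = window.slices(n_times)
    else:
        win_slices = [slice(0, n_times)]

    index_shape = []
    axes = []
    if per_subject:
        index_shape.append(n_sub)
        axes.append("subject")
    if per_channel:
        index_shape.append(len(chl_groups))
        axes.append("channel")
    if per_window:
        index_shape.append(len(win_slices))
        axes.append("window")

    out = np.empty((n_sub, len(chl_groups), len(win_slices), n_cond, n_cond))
    for s in range(n_sub):
        for gi, group in enumerate(chl_groups):
            for wi, sl in enumerate(win_slices):
                patterns = vals[:, s, group, sl].reshape(n_cond, -1)
                out[s, gi, wi] = rdm_from_patterns(patterns, measure).values
    shape = tuple(index_shape) + (n_cond, n_cond)
    squeezed = out.reshape(
        tuple(
            d
            for d, keep in zip(
                out.shape[:3], (per_subject, per_channel, per_window)
            )
            if keep
        )
        + (n_cond, n_cond)
    )
    assert squeezed.shape == shape
    return RDMMap(squeezed, tuple(axes), measure)


def _flatten_x_fastest(volumes: np.ndarray) -> np.ndarray:
    """Flatten trailing (x, y, z) axes with x varying fastest, then y, then z."""
    lead = volumes.shape[:-3]
    reordered = np.moveaxis(volumes, (-3, -2, -1), (-1, -2, -3))  # (..., z, y, x)
    return reordered.reshape(lead + (-1,))


def fmri_roi_rdm(
    data: NeuroArray,
    mask: np.ndarray,
    per_subject: bool = True,
    measure: str = "correlation",
) -> RDMMap:
    """RDMs from an ROI of fMRI-like data ``[condition, subject, x, y, z]``.

    The pattern per condition is the mask-selected voxels flattened
    x-fastest. Voxels that are non-finite under any condition (or subject)
    are dropped from every pattern; an ROI left empty is an error.
    """
    data.require_modality("fmri")
    data.require_conditions(2)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != data.values.shape[2:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {data.values.shape[2:]}"
        )
    if not mask.any():
        raise ValueError("mask selects no voxels")
    flat_mask = _flatten_x_fastest(mask.astype(float)).astype(bool)
    vals = _flatten_x_fastest(data.values)  # [cond, sub, n_vox]
    vals = vals[:, :, flat_mask]
    finite = np.isfinite(vals).all(axis=(0, 1))
    vals = vals[:, :, finite]
    if vals.shape[-1] == 0:
        raise ValueError("ROI is empty after dropping non-finite voxels")
    n_cond, n_sub = vals.shape[:2]
    if per_subject:
        rdms = [rdm_from_patterns(vals[:, s], measure).values for s in range(n_sub)]
        return RDMMap(np.stack(rdms), ("subject",), measure)
    return RDMMap(rdm_from_patterns(vals.mean(axis=1), measure).values, (), measure)


def fmri_searchlight_rdms(
    data: NeuroArray,
    grid: SearchlightGrid,
    measure: str = "correlation",
) -> RDMMap:
    """One RDM per searchlight calculation unit per subject.

    A unit's pattern is its ``k_x * k_y * k_z`` voxels flattened x-fastest.
    Units containing non-finite voxels — or, under the correlation measure,
    a zero-variance pattern — yield a missing (all-NaN) RDM instead of
    raising. Output axes: ``(subject, x, y, z)`` over the unit grid.
    """
    data.require_modality("fmri")
    data.require_conditions(2)
    if grid.image_size != data.values.shape[2:]:
        raise ValueError(
            f"grid image size {grid.image_size} does not match data {data.values.shape[2:]}"
        )
    kx, ky, kz = grid.kernel
    sx, sy, sz = grid.strides
    # windows over the volume axes -> [cond, sub, ux, uy, uz, kx, ky, kz]
    win = sliding_window_view(data.values, (kx, ky, kz), axis=(2, 3, 4))
    win = win[:, :, ::sx, ::sy, ::sz]
    patterns = _flatten_x_fastest(win)  # [cond, sub, ux, uy, uz, k]
    patterns = np.moveaxis(patterns, 0, -2)  # [sub, ux, uy, uz, cond, k]
    n_cond = patterns.shape[-2]

    if measure == "correlation":
        d = _correlation_rdms_stack(patterns)
    else:
        shape = patterns.shape[:-2]
        d = np.empty(shape + (n_cond, n_cond))
        flat = patterns.reshape((-1, n_cond, patterns.shape[-1]))
        dflat = d.reshape((-1, n_cond, n_cond))
        for i in range(flat.shape[0]):
            if not np.isfinite(flat[i]).all():
                dflat[i] = np.nan
                continue
            dflat[i] = rdm_from_patterns(flat[i], measure).values
    return RDMMap(d, ("subject", "x", "y", "z"), measure)
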