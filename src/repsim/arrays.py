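"""Shape-checked array containers shared by every analysis module.

All computations in this package operate on plain NumPy arrays whose axis
order follows fixed modality conventions:

=========  =====================================================
modality   axis order
=========  =====================================================
behavior   ``[condition, subject, trial]``
EEG-like   ``[condition, subject, trial, channel, time]``
fMRI-like  ``[condition, subject, x, y, z]``
=========  =====================================================

:class:`NeuroArray` pairs an array with explicit axis labels and validates
them strictly: an array whose axes are in the wrong order is rejected, never
silently transposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor
from typing import Sequence

import numpy as np

__all__ = [
    "AXIS_NAMES",
    "MODALITY_AXES",
    "NeuroArray",
    "SearchlightGrid",
    "WindowSpec",
    "PlantedDesign",
]

#: Recognised axis labels.
AXIS_NAMES = ("condition", "subject", "trial", "channel", "time", "x", "y", "z")

#: Canonical axis order per modality.
MODALITY_AXES = {
    "behavior": ("condition", "subject", "trial"),
    "eeg": ("condition", "subject", "trial", "channel", "time"),
    "fmri": ("condition", "subject", "x", "y", "z"),
}


@dataclass(frozen=True)
class NeuroArray:
    """An N-d numeric array plus one label per axis.

    Parameters
    ----------
    values
        Numeric array of any dimensionality.
    axes
        One label per axis, drawn from :data:`AXIS_NAMES`, unique.
    """

    values: np.ndarray
    axes: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        axes = tuple(self.axes)
        object.__setattr__(self, "axes", axes)
        if len(axes) != values.ndim:
            raise ValueError(
                f"{len(axes)} axis labels for a {values.ndim}-d array"
            )
        if len(set(axes)) != len(axes):
            raise ValueError(f"axis labels must be unique, got {axes}")
        unknown = set(axes) - set(AXIS_NAMES)
        if unknown:
            raise ValueError(f"unknown axis labels {sorted(unknown)}")
        if any(s < 1 for s in values.shape):
            raise ValueError(f"all axis sizes must be >= 1, got shape {values.shape}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def behavior(cls, values: np.ndarray) -> "NeuroArray":
        """Behavioral data ``[condition, subject, trial]``."""
        return cls(np.asarray(values), MODALITY_AXES["behavior"])

    @classmethod
    def eeg(cls, values: np.ndarray) -> "NeuroArray":
        """EEG-like data ``[condition, subject, trial, channel, time]``."""
        return cls(np.asarray(values), MODALITY_AXES["eeg"])

    @classmethod
    def fmri(cls, values: np.ndarray) -> "NeuroArray":
        """fMRI-like data ``[condition, subject, x, y, z]``."""
        return cls(np.asarray(values), MODALITY_AXES["fmri"])

    # -- helpers ----------------------------------------------------------

    @property
    def modality(self) -> str | None:
        for name, axes in MODALITY_AXES.items():
            if self.axes == axes:
                return name
        return None

    def axis_size(self, name: str) -> int:
        return self.values.shape[self.axes.index(name)]

    @property
    def n_conditions(self) -> int:
        return self.axis_size("condition")

    def require_modality(self, modality: str) -> None:
        expected = MODALITY_AXES[modality]
        if self.axes != expected:
            raise ValueError(
                f"expected {modality} axes {expected}, got {self.axes}; "
                "arrays are never transposed implicitly"
            )

    def require_conditions(self, minimum: int = 2) -> None:
        if self.n_conditions < minimum:
            raise ValueError(
                f"need at least {minimum} conditions, got {self.n_conditions}"
            )


@dataclass(frozen=True)
class SearchlightGrid:
    """Geometry of a 3-D searchlight: kernel size and strides over a volume.

    A kernel of ``kernel`` voxels slides over an image of ``image_size``
    voxels in steps of ``strides``; along each axis ``a`` the number of
    placements is ``floor((X_a - k_a) / s_a) + 1``.
    """

    image_size: tuple[int, int, int]
    kernel: tuple[int, int, int] = (3, 3, 3)
    strides: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_size", tuple(int(v) for v in self.image_size))
        object.__setattr__(self, "kernel", tuple(int(v) for v in self.kernel))
        object.__setattr__(self, "strides", tuple(int(v) for v in self.strides))
        for X, k, s in zip(self.image_size, self.kernel, self.strides):
            if X < 1 or k < 1:
                raise ValueError("image and kernel sizes must be >= 1")
            if k > X:
                raise ValueError(f"kernel {self.kernel} larger than image {self.image_size}")
            if s < 1:
                raise ValueError("strides must be >= 1")

    @property
    def n_units(self) -> tuple[int, int, int]:
        """Placements per axis: ``floor((X - k) / s) + 1``."""
        return tuple(
            floor((X - k) / s) + 1
            for X, k, s in zip(self.image_size, self.kernel, self.strides)
        )

    @property
    def total_units(self) -> int:
        nx, ny, nz = self.n_units
        return nx * ny * nz

    def unit_origin(self, unit_index: tuple[int, int, int]) -> tuple[int, int, int]:
        """Voxel coordinate of the low corner of a given calculation unit."""
        return tuple(i * s for i, s in zip(unit_index, self.strides))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding time window: ``time_win`` samples advancing by ``time_step``.

    Windows are half-open ``[start, start + time_win)``; over ``n_times``
    samples there are ``floor((n_times - time_win) / time_step) + 1`` windows,
    mirroring the searchlight stride arithmetic.
    """

    time_win: int = 5
    time_step: int = 5

    def __post_init__(self) -> None:
        if self.time_win < 1 or self.time_step < 1:
            raise ValueError("time_win and time_step must be positive integers")

    def n_windows(self, n_times: int) -> int:
        if self.time_win > n_times:
            raise ValueError(
                f"window of {self.time_win} samples longer than series of {n_times}"
            )
        return floor((n_times - self.time_win) / self.time_step) + 1

    def starts(self, n_times: int) -> np.ndarray:
        return np.arange(self.n_windows(n_times)) * self.time_step

    def slices(self, n_times: int) -> list[slice]:
        return [slice(s, s + self.time_win) for s in self.starts(n_times)]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of a synthetic dataset with planted condition structure.

    Each condition carries a fixed template (drawn once from ``seed``,
    shared across subjects and trials) scaled by ``signal_effect`` and
    restricted to ``signal_support``; i.i.d. Gaussian noise with standard
    deviation ``noise_sd`` is added on top. With ``signal_effect = 0`` the
    data are exchangeable across conditions (a pure-noise null).
    """

    n_conditions: int = 6
    n_subjects: int = 6
    n_trials: int = 10
    signal_effect: float = 1.0
    noise_sd: float = 1.0
    signal_support: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_conditions, self.n_subjects, self.n_trials) < 1:
            raise ValueError("n_conditions, n_subjects, n_trials must be >= 1")
        if self.signal_effect < 0:
            raise ValueError("signal_effect must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def support_indices(self) -> tuple | None:
        if self.signal_support is None:
            return None
        return tuple(self.signal_support)
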