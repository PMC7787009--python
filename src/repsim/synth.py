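"""Synthetic datasets with planted representational structure.

Every generator is a pure function of a :class:`~repsim.arrays.PlantedDesign`
(and any extra geometry arguments): the same design yields bit-identical
output. Condition templates are drawn first from the design's seed — once per
design, shared across subjects and trials — then noise, so that the noiseless
templates can be recovered independently with :func:`condition_templates` to
build model RDMs for recovery tests.

The noise model is deliberately simple (i.i.d. Gaussian): it gives an
exchangeable null whose permutation calibration can be checked analytically.
It does not emulate autocorrelated physiological noise, hemodynamics, or ERP
morphology.
"""

from __future__ import annotations

import numpy as np

from .arrays import NeuroArray, PlantedDesign

__all__ = [
    "condition_templates",
    "generate_behavior",
    "generate_eeg_like",
    "generate_fmri_like",
]

# Seed-stream labels keep template and noise draws independent and stable.
_TEMPLATE_STREAM = 0
_NOISE_STREAM = 1


def _rng(design: PlantedDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(design.seed), stream])


def condition_templates(design: PlantedDesign, shape: tuple[int, ...]) -> np.ndarray:
    """Per-condition standard-normal templates of the given feature shape.

    Returns an array ``[n_conditions, *shape]`` that depends only on the
    design's seed and the requested shape — the noiseless signal that the
    generators plant (before scaling by ``signal_effect`` and masking by
    ``signal_support``).
    """
    rng = _rng(design, _TEMPLATE_STREAM)
    return rng.standard_normal((design.n_conditions, *shape))


def _support_mask(design: PlantedDesign, shape: tuple[int, ...]) -> np.ndarray:
    """Binary mask over the feature shape; all-ones when support is None."""
    mask = np.zeros(shape, dtype=float)
    support = design.support_indices()
    if support is None:
        mask[...] = 1.0
        return mask
    if len(shape) == 3:  # voxel blob: iterable of (x, y, z) triples
        for vox in support:
            vox = tuple(int(i) for i in vox)
            if any(i < 0 or i >= s for i, s in zip(vox, shape)):
                raise ValueError(f"support voxel {vox} outside image {shape}")
            mask[vox] = 1.0
    else:  # channel indices; signal spans all time points of those channels
        for ch in support:
            ch = int(ch)
            if ch < 0 or ch >= shape[0]:
                raise ValueError(f"support channel {ch} out of range for {shape[0]} channels")
            mask[ch] = 1.0
    return mask


def generate_behavior(design: PlantedDesign) -> NeuroArray:
    """Behavioral data ``[condition, subject, trial]``.

    Each condition's mean is shifted by ``signal_effect`` times a fixed
    per-condition scalar template; trials add Gaussian noise.
    """
    templates = condition_templates(design, ())  # one scalar per condition
    rng = _rng(design, _NOISE_STREAM)
    noise = rng.normal(
        0.0, design.noise_sd, (design.n_conditions, design.n_subjects, design.n_trials)
    )
    signal = design.signal_effect * templates[:, None, None]
    return NeuroArray.behavior(signal + noise)


def generate_eeg_like(
    design: PlantedDesign, n_channels: int, n_times: int
) -> NeuroArray:
    """EEG-like data ``[condition, subject, trial, channel, time]``.

    The planted signal is a per-condition channel-by-time template scaled by
    ``signal_effect``, restricted to the support channels, identical for
    every subject and trial.
    """
    if n_channels < 1 or n_times < 1:
        raise ValueError("n_channels and n_times must be >= 1")
    shape = (n_channels, n_times)
    templates = condition_templates(design, shape)
    mask = _support_mask(design, shape)
    rng = _rng(design, _NOISE_STREAM)
    noise = rng.normal(
        0.0,
        design.noise_sd,
        (design.n_conditions, design.n_subjects, design.n_trials, n_channels, n_times),
    )
    signal = design.signal_effect * templates * mask[None, :, :]
    return NeuroArray.eeg(signal[:, None, None, :, :] + noise)


def generate_fmri_like(
    design: PlantedDesign, image_size: tuple[int, int, int]
) -> NeuroArray:
    """fMRI-like data ``[condition, subject, x, y, z]``.

    ``signal_support`` is a set of voxel coordinates (a 3-D blob); outside it
    the volumes are pure noise.
    """
    image_size = tuple(int(v) for v in image_size)
    if len(image_size) != 3 or min(image_size) < 1:
        raise ValueError(f"image_size must be 3 positive integers, got {image_size}")
    templates = condition_templates(design, image_size)
    mask = _support_mask(design, image_size)
    rng = _rng(design, _NOISE_STREAM)
    noise = rng.normal(
        0.0, design.noise_sd, (design.n_conditions, design.n_subjects, *image_size)
    )
    signal = design.signal_effect * templates * mask[None]
    return NeuroArray.fmri(signal[:, None] + noise)


def blob_support(
    center: tuple[int, int, int], radius: int, image_size: tuple[int, int, int]
) -> tuple[tuple[int, int, int], ...]:
    """Voxel coordinates of a cubic blob of half-width ``radius``, clipped
    to the image — a convenient ``signal_support`` for fMRI designs."""
    cx, cy, cz = center
    voxels = []
    for x in range(max(cx - radius, 0), min(cx + radius + 1, image_size[0])):
        for y in range(max(cy - radius, 0), min(cy + radius + 1, image_size[1])):
            for z in range(max(cz - radius, 0), min(cz + radius + 1, image_size[2])):
                voxels.append((x, y, z))
    return tuple(voxels)
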