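"""Group-level inference on similarity maps and multiple-comparison control.

Subject-level similarity statistics (the r-slice of a
:class:`~repsim.compare.SimilarityMap`) are tested against zero with a
one-sample t-test per index, one-sided toward positive similarity by
default. The permutation alternative sign-flips each subject's value —
valid under a null symmetric about zero — and is enumerated exhaustively
(all ``2^n`` sign patterns) whenever that is no more work than the
requested Monte Carlo iterations, in which case the p-value is exact.

Multiple comparisons across map indices are controlled either by
Benjamini-Hochberg FDR or by Bonferroni FWE over the family of all
non-NaN indices in the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .compare import SimilarityMap

__all__ = ["StatMap", "stats_against_zero", "fdr_correct", "fwe_correct"]


@dataclass(frozen=True)
class StatMap:
    """Per-index ``(t, p)`` from a one-sample test across subjects."""

    values: np.ndarray
    axes: tuple[str, ...]
    df: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "axes", tuple(self.axes))
        if self.values.shape[-1] != 2:
            raise ValueError("last axis must hold (t, p)")
        p = self.values[..., 1]
        finite = np.isfinite(p)
        if finite.any() and ((p[finite] < 0).any() or (p[finite] > 1).any()):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def t(self) -> np.ndarray:
        return self.values[..., 0]

    @property
    def p(self) -> np.ndarray:
        return self.values[..., 1]


def _sign_flip_t(r: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t-statistics for every sign pattern; ``r`` is ``[n_sub, M]``,
    ``flips`` is ``[T, n_sub]`` of +/-1. Sums of squares are flip-invariant,
    so only the mean needs recomputing."""
    n = r.shape[0]
    ssq = np.sum(r * r, axis=0)  # [M]
    mean = flips @ r / n  # [T, M]
    var = (ssq[None, :] - n * mean**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mean / np.sqrt(var / n)


def stats_against_zero(
    sim: SimilarityMap,
    permutation: bool = False,
    n_iter: int = 5000,
    seed: int | None = 12345,
    tail: str = "greater",
    fisher_z: bool = False,
) -> StatMap:
    """One-sample test of subjects' similarity values against zero, per index.

    Parameters
    ----------
    sim
        Similarity map whose leading axis is ``subject``; only the r-slice
        is used.
    permutation
        Use the sign-flip permutation null instead of the Student t
        distribution. Exhaustive over all ``2^n_subjects`` patterns when
        that count does not exceed ``n_iter``.
    tail
        ``"greater"`` (default, similarity above zero) or ``"two-sided"``.
    fisher_z
        Apply the Fisher z-transform ``arctanh(r)`` before testing.

    Indices where any subject is NaN, or where the across-subject variance
    is zero, yield ``(NaN, NaN)`` (with a warning for the zero-variance
    case) rather than failing.
    """
    if not sim.axes or sim.axes[0] != "subject":
        raise ValueError(f"similarity map must have a leading subject axis, got {sim.axes}")
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    r = sim.r  # [n_sub, ...]
    n_sub = r.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    index_shape = r.shape[1:]
    flat = r.reshape(n_sub, -1).copy()
    if fisher_z:
        flat = np.arctanh(np.clip(flat, -1 + 1e-12, 1 - 1e-12))

    valid = np.isfinite(flat).all(axis=0)
    sd = flat.std(axis=0, ddof=1)
    degenerate = valid & (sd == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} index(es) have zero variance across "
            "subjects; their (t, p) are NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    usable = valid & (sd > 0)

    t = np.full(flat.shape[1], np.nan)
    p = np.full(flat.shape[1], np.nan)
    df = n_sub - 1
    if usable.any():
        sub = flat[:, usable]
        t_obs = sub.mean(axis=0) / (sub.std(axis=0, ddof=1) / np.sqrt(n_sub))
        t[usable] = t_obs
        if not permutation:
            if tail == "greater":
                p[usable] = sps.t.sf(t_obs, df)
            else:
                p[usable] = 2 * sps.t.sf(np.abs(t_obs), df)
        else:
            if n_iter < 1:
                raise ValueError("n_iter must be >= 1")
            if 2**n_sub <= n_iter:
                flips = np.array(list(product((1.0, -1.0), repeat=n_sub)))
                exhaustive = True
            else:
                rng = np.random.default_rng(seed)
                flips = rng.choice([1.0, -1.0], size=(n_iter, n_sub))
                exhaustive = False
            t_null = _sign_flip_t(sub, flips)
            if tail == "greater":
                count = np.sum(t_null >= t_obs[None, :] - 1e-12, axis=0)
            else:
                count = np.sum(np.abs(t_null) >= np.abs(t_obs)[None, :] - 1e-12, axis=0)
            if exhaustive:
                p[usable] = count / flips.shape[0]
            else:
                p[usable] = (1 + count) / (1 + n_iter)

    values = np.stack([t, p], axis=-1).reshape(index_shape + (2,))
    return StatMap(values, sim.axes[1:], df)


def _correct(p_values: np.ndarray, alpha: float, method: str):
    p = np.asarray(p_values, dtype=float)
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    finite = np.isfinite(p)
    if not finite.any():
        raise ValueError("empty family: no finite p-values")
    if (p[finite] < 0).any() or (p[finite] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    mask = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    rej, adj, _, _ = multipletests(p[finite], alpha=alpha, method=method)
    mask[finite] = rej
    adjusted[finite] = adj
    return mask, adjusted


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(mask, adjusted_p)`` of the input shape; NaN entries are
    excluded from the family and stay NaN (mask False).
    """
    return _correct(p_values, alpha, "fdr_bh")


def fwe_correct(p_values: np.ndarray, alpha: float = 0.05):
    """Bonferroni FWE control: adjusted ``p = min(1, m * p)``.

    Returns ``(mask, adjusted_p)``; NaN handling as in :func:`fdr_correct`.
    """
    return _correct(p_values, alpha, "bonferroni")
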