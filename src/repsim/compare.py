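"""Similarity between RDMs, with parametric and permutation inference.

Two RDMs are compared on their vectorized strictly-upper triangles (the
diagonal is always excluded and only one half of the symmetric matrix is
kept, so shared zeros never inflate the similarity). Five measures are
offered: Spearman, Pearson and Kendall's tau rank/linear correlations
(returning ``(r, p)``), cosine similarity and Euclidean distance (no
parametric p; use the permutation test).

The permutation null relabels the conditions of one RDM — permuting its
rows and columns jointly — and re-vectorizes at each iteration, which
respects the exchangeability structure of a dissimilarity matrix.
Shuffling the vectorized entries independently is available as an explicit
compatibility option (``scheme="entries"``). When the permutation group is
small enough (``n! <= n_iter`` relabelings) the null is enumerated
exhaustively and the p-value is exact; otherwise it is the add-one Monte
Carlo estimate ``(1 + #{null >= observed}) / (1 + n_iter)``, which is never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import squareform

from .arrays import NeuroArray, SearchlightGrid, WindowSpec
from .rdm import RDM, RDMMap, behavioral_rdms, eeg_rdms, fmri_roi_rdm, fmri_searchlight_rdms

__all__ = [
    "COMPARISON_MEASURES",
    "SimilarityMap",
    "vectorize_offdiag",
    "compare_rdms",
    "permutation_null",
    "broadcast_compare",
    "one_step_compare",
]

COMPARISON_MEASURES = ("spearman", "pearson", "kendall", "cosine", "euclidean")

#: Measures for which a *larger* statistic indicates stronger similarity.
_GREATER_IS_SIMILAR = ("spearman", "pearson", "kendall", "cosine")

DEFAULT_N_ITER = 5000
DEFAULT_SEED = 12345


@dataclass(frozen=True)
class SimilarityMap:
    """Per-index ``(r, p)`` pairs from comparing RDMs against a reference.

    ``values`` has shape ``index_shape + (2,)`` — the last axis holds the
    similarity statistic and its p-value. Missing comparisons are
    ``(NaN, NaN)``.
    """

    values: np.ndarray
    axes: tuple[str, ...]
    measure: str = "spearman"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "axes", tuple(self.axes))
        if values.shape[-1] != 2:
            raise ValueError("last axis must have length 2 (r, p)")
        if values.ndim != len(self.axes) + 1:
            raise ValueError("values ndim inconsistent with index axes")
        p = values[..., 1]
        finite = np.isfinite(p)
        if finite.any() and ((p[finite] < 0).any() or (p[finite] > 1).any()):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def r(self) -> np.ndarray:
        return self.values[..., 0]

    @property
    def p(self) -> np.ndarray:
        return self.values[..., 1]

    def to_dataframe(self):
        """Long-format table: one row per index, columns = axes + r + p."""
        import pandas as pd

        idx = np.indices(self.values.shape[:-1]).reshape(len(self.axes), -1)
        data = {name: idx[i] for i, name in enumerate(self.axes)}
        data["r"] = self.r.ravel()
        data["p"] = self.p.ravel()
        return pd.DataFrame(data)


def _as_matrix(rdm) -> np.ndarray:
    if isinstance(rdm, RDM):
        return rdm.values
    m = np.asarray(rdm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square RDM, got shape {m.shape}")
    return m


def vectorize_offdiag(rdm) -> np.ndarray:
    """Strictly-upper-triangle entries of an RDM, row-major.

    For ``n`` conditions the vector has length ``n (n - 1) / 2``. Vectors
    shorter than 3 entries are legal but too short for parametric
    correlation — downstream comparisons then require a permutation test.
    """
    m = _as_matrix(rdm)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


# ---------------------------------------------------------------------------
# statistics on vector pairs


def _statistic(v_a: np.ndarray, v_b: np.ndarray, measure: str) -> float:
    if measure == "spearman":
        return float(sps.spearmanr(v_a, v_b).statistic)
    if measure == "pearson":
        return float(sps.pearsonr(v_a, v_b).statistic)
    if measure == "kendall":
        return float(sps.kendalltau(v_a, v_b).statistic)
    if measure == "cosine":
        denom = np.linalg.norm(v_a) * np.linalg.norm(v_b)
        if denom == 0:
            raise ValueError("cosine similarity undefined for a zero vector")
        return float(v_a @ v_b / denom)
    if measure == "euclidean":
        return float(np.linalg.norm(v_a - v_b))
    raise ValueError(f"unknown measure {measure!r}; choose from {COMPARISON_MEASURES}")


def _statistic_rows(v_a: np.ndarray, rows: np.ndarray, measure: str) -> np.ndarray:
    """The comparison statistic between ``v_a`` and each row of ``rows``."""
    if measure in ("spearman", "pearson"):
        a = sps.rankdata(v_a) if measure == "spearman" else v_a
        b = sps.rankdata(rows, axis=-1) if measure == "spearman" else rows
        a = a - a.mean()
        b = b - b.mean(axis=-1, keepdims=True)
        denom = np.linalg.norm(a) * np.linalg.norm(b, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (b @ a) / denom
    if measure == "kendall":
        return np.array([sps.kendalltau(v_a, row).statistic for row in rows])
    if measure == "cosine":
        denom = np.linalg.norm(v_a) * np.linalg.norm(rows, axis=-1)
        return (rows @ v_a) / denom
    if measure == "euclidean":
        return np.linalg.norm(rows - v_a, axis=-1)
    raise ValueError(f"unknown measure {measure!r}")


def _check_not_constant(v: np.ndarray, name: str, measure: str) -> None:
    if measure in ("spearman", "pearson", "kendall") and np.all(v == v[0]):
        raise ValueError(
            f"off-diagonal vector of {name} is constant; {measure} correlation "
            "is undefined"
        )


def _permuted_vectors(
    v: np.ndarray, perms: np.ndarray, pair_index: np.ndarray, iu: tuple
) -> np.ndarray:
    """Vectorized condition relabeling: row ``t`` is the off-diagonal vector
    of the RDM with conditions reordered by ``perms[t]``."""
    pi, pj = perms[:, iu[0]], perms[:, iu[1]]
    return v[pair_index[pi, pj]]


def permutation_null(
    v_a: np.ndarray,
    v_b: np.ndarray,
    measure: str = "spearman",
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = DEFAULT_SEED,
    scheme: str = "labels",
) -> float:
    """One-sided permutation p-value for the similarity of two RDM vectors.

    ``scheme="labels"`` (default) permutes the condition labels of the
    second RDM; ``scheme="entries"`` shuffles its vector entries. The test
    is one-sided toward similarity: greater statistic for correlation-type
    measures, smaller distance for Euclidean. Exhaustive enumeration is
    used when the permutation group has at most ``n_iter`` elements.
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape or v_a.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if scheme not in ("labels", "entries"):
        raise ValueError("scheme must be 'labels' or 'entries'")
    m = v_a.size
    observed = _statistic(v_a, v_b, measure)

    if scheme == "labels":
        # recover n from m = n (n - 1) / 2 and rebuild the square form
        n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        if n * (n - 1) // 2 != m:
            raise ValueError(f"vector length {m} is not n(n-1)/2 for integer n")
        iu = np.triu_indices(n, k=1)
        pair_index = np.zeros((n, n), dtype=int)
        pair_index[iu] = np.arange(m)
        pair_index = pair_index + pair_index.T  # symmetric pair lookup
        if factorial(n) <= n_iter:
            perms = np.array(list(permutations(range(n))))
            exhaustive = True
        else:
            rng = np.random.default_rng(seed)
            perms = rng.permuted(
                np.tile(np.arange(n), (n_iter, 1)), axis=1
            )
            exhaustive = False
        rows = _permuted_vectors(v_b, perms, pair_index, iu)
    else:
        if factorial(m) <= n_iter:
            perms = np.array(list(permutations(range(m))))
            exhaustive = True
        else:
            rng = np.random.default_rng(seed)
            perms = rng.permuted(np.tile(np.arange(m), (n_iter, 1)), axis=1)
            exhaustive = False
        rows = v_b[perms]

    null = _statistic_rows(v_a, rows, measure)
    null = null[np.isfinite(null)] if not np.isfinite(null).all() else null
    if measure in _GREATER_IS_SIMILAR:
        count = int(np.sum(null >= observed - 1e-12))
    else:
        count = int(np.sum(null <= observed + 1e-12))
    if exhaustive:
        return count / len(rows)
    return (1 + count) / (1 + n_iter)


def compare_rdms(
    rdm_a,
    rdm_b,
    measure: str = "spearman",
    permutation: bool = False,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = DEFAULT_SEED,
    scheme: str = "labels",
) -> tuple[float, float]:
    """Similarity ``(r, p)`` between two RDMs over the same conditions.

    The RDMs are vectorized (strict upper triangle) and compared with the
    chosen measure. ``p`` is the parametric p-value where the measure has
    one (Spearman, Pearson, Kendall) and ``permutation`` is off; with
    ``permutation`` it is the one-sided permutation p-value; for cosine and
    Euclidean without permutation it is NaN.
    """
    a = _as_matrix(rdm_a)
    b = _as_matrix(rdm_b)
    if a.shape != b.shape:
        raise ValueError(
            f"condition-count mismatch: {a.shape[0]} vs {b.shape[0]} conditions"
        )
    v_a = vectorize_offdiag(a)
    v_b = vectorize_offdiag(b)
    if v_a.size < 3 and not permutation:
        raise ValueError(
            f"only {v_a.size} off-diagonal entries; parametric correlation "
            "over fewer than 3 points is unstable — use permutation=True"
        )
    _check_not_constant(v_a, "rdm_a", measure)
    _check_not_constant(v_b, "rdm_b", measure)

    r = _statistic(v_a, v_b, measure)
    if permutation:
        p = permutation_null(v_a, v_b, measure, n_iter=n_iter, seed=seed, scheme=scheme)
    elif measure == "spearman":
        p = float(sps.spearmanr(v_a, v_b).pvalue)
    elif measure == "pearson":
        p = float(sps.pearsonr(v_a, v_b).pvalue)
    elif measure == "kendall":
        p = float(sps.kendalltau(v_a, v_b).pvalue)
    else:
        p = float("nan")
    return r, p


def _rank_correlation_block(
    v_ref: np.ndarray, vecs: np.ndarray, measure: str
) -> np.ndarray:
    """(r, p) of the reference vector against each row, vectorized.

    Same statistic and t-distribution p-value as the per-pair SciPy route,
    computed in one pass — used by :func:`broadcast_compare` for large maps.
    """
    m = v_ref.size
    if measure == "spearman":
        a = sps.rankdata(v_ref)
        b = sps.rankdata(vecs, axis=1)
    else:
        a = v_ref
        b = vecs
    a = a - a.mean()
    b = b - b.mean(axis=1, keepdims=True)
    norm_a = np.linalg.norm(a)
    norm_b = np.linalg.norm(b, axis=1)
    bad = np.flatnonzero(norm_b == 0)
    if norm_a == 0 or bad.size:
        which = "reference RDM" if norm_a == 0 else f"RDM(s) at flat index {bad.tolist()}"
        raise ValueError(
            f"off-diagonal vector of {which} is constant; {measure} "
            "correlation is undefined"
        )
    r = np.clip((b @ a) / (norm_a * norm_b), -1.0, 1.0)
    dof = m - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    p = 2 * sps.t.sf(np.abs(t), dof)
    p[np.abs(r) == 1.0] = 0.0
    return np.stack([r, p], axis=-1)


def broadcast_compare(
    reference,
    rdms: RDMMap,
    measure: str = "spearman",
    permutation: bool = False,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = DEFAULT_SEED,
    scheme: str = "labels",
) -> SimilarityMap:
    """Compare one reference RDM against every RDM in a map.

    Missing RDMs (all-NaN slices) yield ``(NaN, NaN)`` at their index; all
    other indices are unaffected. Spearman/Pearson without permutation run
    through a single vectorized pass; the result is numerically identical
    to comparing index by index.
    """
    ref = _as_matrix(reference)
    if ref.shape[0] != rdms.n_conditions:
        raise ValueError(
            f"condition-count mismatch: reference has {ref.shape[0]}, "
            f"map has {rdms.n_conditions}"
        )
    out = np.full(rdms.index_shape + (2,), np.nan)
    missing = rdms.missing_mask()

    n = rdms.n_conditions
    fast = measure in ("spearman", "pearson") and not permutation and n * (n - 1) // 2 >= 3
    if fast:
        iu = np.triu_indices(n, k=1)
        flat = rdms.values.reshape((-1, n, n))
        keep = ~missing.reshape(-1)
        vecs = flat[keep][:, iu[0], iu[1]]
        if vecs.shape[0]:
            out.reshape(-1, 2)[keep] = _rank_correlation_block(
                vectorize_offdiag(ref), vecs, measure
            )
        return SimilarityMap(out, rdms.axes, measure)

    for index in rdms.indices():
        if missing[index]:
            continue
        try:
            r, p = compare_rdms(
                ref,
                rdms.values[index],
                measure=measure,
                permutation=permutation,
                n_iter=n_iter,
                seed=seed,
                scheme=scheme,
            )
        except ValueError as err:
            raise ValueError(f"at map index {index}: {err}") from err
        out[index] = (r, p)
    return SimilarityMap(out, rdms.axes, measure)


def one_step_compare(
    data_a: NeuroArray,
    data_b: NeuroArray,
    per_subject: bool = True,
    per_channel: bool = False,
    per_window: bool = False,
    window: WindowSpec | None = None,
    grid: SearchlightGrid | None = None,
    mask: np.ndarray | None = None,
    rdm_measure: str = "correlation",
    measure: str = "spearman",
    permutation: bool = False,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = DEFAULT_SEED,
) -> SimilarityMap:
    """One-step representational comparison between two data modalities.

    ``data_a`` is behavioral data (the reference); ``data_b`` is EEG-like
    or fMRI-like. This composes the RDM computations with
    :func:`broadcast_compare` under the same flags — the output is
    elementwise identical to running the two-step pipeline by hand. With
    ``per_subject`` each subject's behavioral RDM is compared against that
    same subject's neural RDMs.
    """
    data_a.require_modality("behavior")
    if data_a.n_conditions != data_b.n_conditions:
        raise ValueError(
            f"condition-count mismatch: {data_a.n_conditions} vs {data_b.n_conditions}"
        )
    bhv = behavioral_rdms(data_a, per_subject=per_subject, measure=rdm_measure)

    modality = data_b.modality
    if modality == "eeg":
        neural = eeg_rdms(
            data_b,
            per_subject=per_subject,
            per_channel=per_channel,
            per_window=per_window,
            window=window,
            measure=rdm_measure,
        )
    elif modality == "fmri":
        if grid is not None:
            neural = fmri_searchlight_rdms(data_b, grid, measure=rdm_measure)
        elif mask is not None:
            neural = fmri_roi_rdm(data_b, mask, per_subject=per_subject, measure=rdm_measure)
        else:
            raise ValueError("fMRI comparison needs a searchlight grid or an ROI mask")
    else:
        raise ValueError(f"unsupported neural modality with axes {data_b.axes}")

    kwargs = dict(
        measure=measure, permutation=permutation, n_iter=n_iter, seed=seed
    )
    if not per_subject:
        return broadcast_compare(bhv.rdm(()), neural, **kwargs)

    if data_a.axis_size("subject") != data_b.axis_size("subject"):
        raise ValueError("per-subject comparison needs matching subject counts")
    if "subject" not in neural.axes or neural.axes[0] != "subject":
        raise ValueError("neural RDM map lacks a leading subject axis")
    per_sub_maps = []
    for s in range(neural.values.shape[0]):
        sub_map = RDMMap(neural.values[s], neural.axes[1:], neural.measure)
        per_sub_maps.append(
            broadcast_compare(bhv.rdm((s,)), sub_map, **kwargs).values
        )
    return SimilarityMap(np.stack(per_sub_maps), neural.axes, measure)
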