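"""Group temporal ICA: concatenation, SVD prewhitening, FastICA.

Subjects' preprocessed time-by-voxel matrices are stacked in time to
form the group matrix; its top-k singular triplets (computed with an
implicitly restarted Lanczos method) define the PCA prewhitening; and a
symmetric-decorrelation FastICA on the whitened temporal matrix yields
temporally independent component time courses.  Spatial maps are
obtained by composing the ICA mixing with the retained principal-
component basis ("back-projection" from PC space to voxel space).

The FastICA implementation here extracts ``n_ics`` components jointly
(parallel/symmetric updates, not deflation), supports the logcosh, exp
and cube contrast functions, and is deterministic given a seed, with
seeded restarts on non-convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import ArpackNoConvergence, svds
from scipy.stats import skew

from .preprocess import VoxelTimeSeriesMatrix

logger = logging.getLogger(__name__)


@dataclass
class GroupMatrix:
    """Temporally concatenated multi-subject matrix.

    subject_boundaries is a list of (subject_id, row_start, row_end)
    with half-open row ranges partitioning all rows in order.
    """

    data: np.ndarray
    subject_boundaries: list[tuple[str, int, int]]
    tr_seconds: float
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]
    #: per-voxel SD removed by standardization, averaged over subjects
    #: (None if inputs were not standardized)
    voxel_scale: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def segment_lengths(self) -> list[int]:
        return [end - start for _, start, end in self.subject_boundaries]


def concatenate_subjects(
    matrices: list[VoxelTimeSeriesMatrix],
) -> GroupMatrix:
    """Stack subjects' rows in input order, recording boundaries."""
    if not matrices:
        raise ValueError("no subjects to concatenate")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.data.shape[1] != ref.data.shape[1] or not np.array_equal(
            m.voxel_index, ref.voxel_index
        ):
            raise ValueError(
                f"subject {m.subject_id!r}: voxel mask does not match "
                f"subject {ref.subject_id!r}"
            )
        if m.tr_seconds != ref.tr_seconds:
            raise ValueError(
                f"subject {m.subject_id!r}: TR {m.tr_seconds} differs from "
                f"{ref.tr_seconds}"
            )
    boundaries = []
    start = 0
    for m in matrices:
        boundaries.append((m.subject_id, start, start + m.n_volumes))
        start += m.n_volumes
    data = np.vstack([m.data for m in matrices])
    scales = [m.voxel_scale for m in matrices]
    voxel_scale = (
        np.mean(scales, axis=0) if all(sc is not None for sc in scales) else None
    )
    logger.info(
        "concatenated %d subjects -> %d x %d group matrix",
        len(matrices),
        data.shape[0],
        data.shape[1],
    )
    return GroupMatrix(
        data=data,
        subject_boundaries=boundaries,
        tr_seconds=ref.tr_seconds,
        voxel_index=ref.voxel_index,
        grid_shape=ref.grid_shape,
        voxel_scale=voxel_scale,
    )


def truncated_svd(
    g: GroupMatrix | np.ndarray,
    k: int,
    tol: float = 0.0,
    seed: int | None = 0,
    maxiter: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k singular triplets (U, s, Vt), singular values descending.

    Uses ARPACK's implicitly restarted Lanczos bidiagonalization, which
    scales to tall-and-wide matrices without forming a covariance
    matrix.  Deterministic for a given ``seed`` (starting vector).
    """
    data = g.data if isinstance(g, GroupMatrix) else np.asarray(g)
    if not 0 < k < min(data.shape):
        raise ValueError(
            f"k={k} must satisfy 0 < k < min(shape)={min(data.shape)}"
        )
    try:
        u, s, vt = svds(
            data,
            k=k,
            tol=tol,
            maxiter=maxiter,
            rng=np.random.default_rng(seed),
        )
    except ArpackNoConvergence as err:  # pragma: no cover - rare
        raise RuntimeError(
            f"truncated SVD did not converge: {len(err.eigenvalues)} of "
            f"{k} triplets found; increase maxiter or tol"
        ) from err
    order = np.argsort(s)[::-1]
    return u[:, order], s[order], vt[order]


@dataclass
class Whitening:
    """Whitened temporal data plus the transform needed to invert it.

    ``temporal`` (T, k) has zero-mean columns with identity sample
    covariance.  ``back_projection`` (k, n_voxels) satisfies
    ``temporal @ back_projection`` = rank-k approximation of the input.
    """

    temporal: np.ndarray
    back_projection: np.ndarray
    singular_values: np.ndarray


def whiten(
    u: np.ndarray, s: np.ndarray, vt: np.ndarray, k: int | None = None
) -> Whitening:
    """PCA prewhitening from an SVD: X ~ U S Vt -> Z = sqrt(T-1) U."""
    k = s.shape[0] if k is None else k
    if k > s.shape[0]:
        raise ValueError(f"k={k} exceeds available triplets ({s.shape[0]})")
    if np.any(s[:k] <= s[0] * 1e-12):
        raise ValueError(
            "vanishing singular value among the top k: degenerate "
            "dimension, reduce k"
        )
    n = u.shape[0]
    scale = np.sqrt(n - 1)
    z = u[:, :k] * scale
    back = (s[:k, None] * vt[:k]) / scale
    return Whitening(temporal=z, back_projection=back, singular_values=s[:k].copy())


@dataclass
class Decomposition:
    """Result of the group temporal ICA.

    ic_timecourses (T, n_ics) columns have unit variance and are
    mutually uncorrelated; spatial_maps (n_ics, n_voxels) are the
    back-projected mixing weights; ``ic_timecourses @ spatial_maps``
    reconstructs the rank-``n_pcs`` approximation of the group matrix
    when n_ics == n_pcs.  Components are ordered by explained variance
    (descending) with sign fixed so each spatial map is positively
    skewed.
    """

    n_pcs: int
    n_ics: int
    singular_values: np.ndarray
    pc_basis: np.ndarray
    ic_timecourses: np.ndarray
    spatial_maps: np.ndarray
    convergence: dict
    #: per-voxel SD of the pre-standardization data (None if unknown)
    voxel_scale: np.ndarray | None = None

    def maps_in_data_units(self) -> np.ndarray:
        """Spatial maps rescaled by each voxel's original SD.

        ``spatial_maps`` lives in standardized-voxel units (it satisfies
        the rank-k reconstruction of the standardized group matrix);
        multiplying by the removed per-voxel SD expresses the component
        loadings in the data's own units, undoing the shape distortion
        the voxelwise standardization imposes on localized sources.
        """
        if self.voxel_scale is None:
            return self.spatial_maps
        return self.spatial_maps * self.voxel_scale[None, :]


_CONTRASTS = {"logcosh", "exp", "cube"}


def _contrast(name: str, wx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """g(wx) and the row-mean of g'(wx) for the FastICA update."""
    if name == "logcosh":
        gwx = np.tanh(wx)
        g_prime = (1.0 - gwx**2).mean(axis=1)
    elif name == "exp":
        e = np.exp(-(wx**2) / 2.0)
        gwx = wx * e
        g_prime = ((1.0 - wx**2) * e).mean(axis=1)
    elif name == "cube":
        gwx = wx**3
        g_prime = (3.0 * wx**2).mean(axis=1)
    else:  # pragma: no cover
        raise ValueError(name)
    return gwx, g_prime


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^{-1/2} W (rows become orthonormal)."""
    evals, evecs = np.linalg.eigh(w @ w.T)
    evals = np.clip(evals, np.finfo(float).tiny, None)
    return (evecs / np.sqrt(evals)) @ evecs.T @ w


def _fastica_core(
    z_t: np.ndarray,
    n_ics: int,
    rng: np.random.Generator,
    contrast: str,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, float]:
    """One FastICA run on whitened data (k, T) -> (W, iters, delta)."""
    k, n = z_t.shape
    w = _sym_decorrelate(rng.standard_normal((n_ics, k)))
    delta = np.inf
    for it in range(1, max_iter + 1):
        wx = w @ z_t
        gwx, g_prime = _contrast(contrast, wx)
        w_new = (gwx @ z_t.T) / n - g_prime[:, None] * w
        w_new = _sym_decorrelate(w_new)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0)))
        w = w_new
        if delta < tol:
            return w, it, delta
    return w, max_iter, delta


def fastica_temporal(
    whitening: Whitening,
    n_ics: int | None = None,
    seed: int = 0,
    contrast: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
    voxel_scale: np.ndarray | None = None,
) -> Decomposition:
    """Extract temporally independent components from whitened data.

    Runs symmetric (parallel) FastICA with the chosen contrast on the
    whitened temporal matrix; on non-convergence, restarts with a fresh
    derived seed up to ``n_restarts`` times before raising.  When
    ``n_ics < n_pcs`` the ICA rotation is estimated in the subspace of
    the top ``n_ics`` whitened dimensions (the convention behind
    "k principal components, k-1 independent components": the extra
    components only stabilize the prewhitening).  Spatial maps are
    obtained by composing the unmixing with the stored PC
    back-projection; component order (variance explained, descending)
    and sign (positively skewed spatial map) are canonicalized.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(_CONTRASTS)}")
    z_full = whitening.temporal
    k = z_full.shape[1]
    n_ics = k if n_ics is None else n_ics
    if not 0 < n_ics <= k:
        raise ValueError(f"n_ics={n_ics} must be in (0, n_pcs={k}]")
    z = z_full[:, :n_ics]
    back = whitening.back_projection[:n_ics]

    z_t = np.ascontiguousarray(z.T)
    seed_seq = np.random.SeedSequence(seed)
    last_delta = np.inf
    for attempt, child in enumerate(seed_seq.spawn(n_restarts + 1)):
        rng = np.random.default_rng(child)
        w, iters, delta = _fastica_core(z_t, n_ics, rng, contrast, tol, max_iter)
        last_delta = delta
        if delta < tol:
            break
        logger.warning(
            "FastICA attempt %d did not converge (delta=%.3g); restarting",
            attempt + 1,
            delta,
        )
    else:
        raise RuntimeError(
            f"FastICA failed to converge in {n_restarts + 1} attempts "
            f"(final delta {last_delta:.3g} > tol {tol})"
        )

    timecourses = z @ w.T  # (T, n_ics), unit variance by construction
    maps = w @ back  # (n_ics, n_voxels)

    # sign: positively skewed spatial map (fallback: strongest voxel +)
    for i in range(n_ics):
        sk = skew(maps[i])
        sign = np.sign(sk)
        if abs(sk) < 1e-8 or sign == 0:
            sign = np.sign(maps[i][np.argmax(np.abs(maps[i]))]) or 1.0
        if sign < 0:
            maps[i] *= -1.0
            timecourses[:, i] *= -1.0
            w[i] *= -1.0

    # order: variance explained in the original data, descending
    order = np.argsort(-np.sum(maps**2, axis=1), kind="stable")
    maps = maps[order]
    timecourses = timecourses[:, order]

    return Decomposition(
        n_pcs=k,
        n_ics=n_ics,
        singular_values=whitening.singular_values.copy(),
        pc_basis=whitening.back_projection.copy(),
        ic_timecourses=timecourses,
        spatial_maps=maps,
        voxel_scale=voxel_scale.copy() if voxel_scale is not None else None,
        convergence={
            "iterations": iters,
            "final_delta": delta,
            "attempts": attempt + 1,
            "contrast": contrast,
            "tol": tol,
        },
    )


def decompose_group(
    g: GroupMatrix,
    n_pcs: int = 76,
    n_ics: int = 75,
    seed: int = 0,
    contrast: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> Decomposition:
    """Convenience driver: truncated SVD -> whiten -> FastICA.

    ``n_pcs``/``n_ics`` are clipped to the matrix size for desk-scale
    runs (the conventional defaults target full-size group analyses).
    """
    max_k = min(g.data.shape) - 1
    n_pcs_eff = min(n_pcs, max_k)
    n_ics_eff = min(n_ics, n_pcs_eff)
    if n_pcs_eff < n_pcs:
        logger.info(
            "n_pcs reduced from %d to %d to fit the %d x %d matrix",
            n_pcs,
            n_pcs_eff,
            *g.data.shape,
        )
    col_means = np.abs(g.data.mean(axis=0)).max()
    if col_means > 1e-6:
        logger.warning(
            "group matrix columns are not mean-centered (max |mean| %.3g); "
            "prewhitening assumes standardized input",
            col_means,
        )
    u, s, vt = truncated_svd(g, k=n_pcs_eff, seed=seed)
    wh = whiten(u, s, vt)
    return fastica_temporal(
        wh,
        n_ics=n_ics_eff,
        seed=seed,
        contrast=contrast,
        tol=tol,
        max_iter=max_iter,
        voxel_scale=g.voxel_scale,
    )
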