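"""Temporal preprocessing of masked per-subject fMRI time series.

A subject's in-mask data is held as a time-by-voxel matrix
(:class:`VoxelTimeSeriesMatrix`).  The preprocessing chain, applied in
fixed order, is

    discard initial volumes -> motion regression -> voxelwise
    standardization -> (optional spatial smoothing) -> Fourier high-pass

The high-pass filter implements the strict frequency-domain rule used to
isolate high-frequency fluctuations: every DFT coefficient at a frequency
strictly below the cutoff (default 0.25 Hz) is set to zero and the series
is transformed back, so that only fluctuations at or above the cutoff
survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548...


@dataclass
class VoxelTimeSeriesMatrix:
    """One subject's masked fMRI run as a time-by-voxel matrix.

    Parameters
    ----------
    data:
        Real (n_volumes, n_voxels) array.
    tr_seconds:
        Sampling interval between volumes, in seconds.
    voxel_index:
        (n_voxels, 3) integer array mapping each column to its 0-based
        (i, j, k) grid coordinate; columns are in mask scan order with the
        first axis varying fastest.
    subject_id:
        Label used in concatenation bookkeeping and reports.
    grid_shape:
        Shape of the 3-D grid the voxel coordinates refer to.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_index: np.ndarray
    subject_id: str
    grid_shape: tuple[int, int, int]
    #: per-voxel SD removed by standardization (None before that step);
    #: lets spatial maps be reported in the data's original units
    voxel_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D time-by-voxel matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(
                f"subject {self.subject_id!r}: non-finite values in data"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.voxel_index.shape != (self.data.shape[1], 3):
            raise ValueError(
                "voxel_index must be (n_voxels, 3) and match data columns"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return nyquist_frequency(self.tr_seconds)


def nyquist_frequency(tr_seconds: float) -> float:
    """Highest critically sampled frequency, 1/(2*TR), in Hz."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return 1.0 / (2.0 * tr_seconds)


@dataclass(frozen=True)
class FilterSpec:
    """High-pass filter settings.

    cutoff_hz is the lowest retained frequency; coefficients strictly
    below it are zeroed.  The bin exactly at the cutoff is kept.  zero_dc
    controls whether the DC bin is zeroed as well (it always lies below
    any positive cutoff, so this flag only matters when the filter is
    used as a pure DC-remover with cutoff at the first positive bin).
    """

    cutoff_hz: float = 0.25
    zero_dc: bool = True

    def validate(self, tr_seconds: float) -> None:
        nyq = nyquist_frequency(tr_seconds)
        if not (0.0 < self.cutoff_hz < nyq):
            raise ValueError(
                f"cutoff_hz={self.cutoff_hz} must lie in (0, Nyquist="
                f"{nyq:.4f} Hz) for TR={tr_seconds} s"
            )


def discard_initial_volumes(
    m: VoxelTimeSeriesMatrix, n_discard: int
) -> VoxelTimeSeriesMatrix:
    """Drop the first ``n_discard`` volumes (transient-effect removal)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= m.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {m.n_volumes} volumes "
            f"(subject {m.subject_id!r}): result would be empty"
        )
    return replace(m, data=m.data[n_discard:].copy())


def regress_motion(
    m: VoxelTimeSeriesMatrix, motion: np.ndarray
) -> VoxelTimeSeriesMatrix:
    """Regress out the 6 rigid-body motion parameters voxelwise.

    Fits each voxel time course on [intercept, 3 translations, 3
    rotations] by least squares and returns the residuals.  A
    rank-deficient design is handled by the SVD-based pseudo-inverse with
    a logged warning.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a time-by-6 array")
    if motion.shape[0] != m.n_volumes:
        raise ValueError(
            f"motion rows ({motion.shape[0]}) != volumes ({m.n_volumes}) "
            f"for subject {m.subject_id!r}"
        )
    design = np.column_stack([np.ones(m.n_volumes), motion])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "subject %s: rank-deficient motion design (rank %d of %d); "
            "using pseudo-inverse",
            m.subject_id,
            rank,
            design.shape[1],
        )
    beta, *_ = np.linalg.lstsq(design, m.data, rcond=None)
    resid = m.data - design @ beta
    return replace(m, data=resid)


def standardize_voxels(m: VoxelTimeSeriesMatrix) -> VoxelTimeSeriesMatrix:
    """Scale every voxel time course to mean 0, SD 1.

    Constant columns cannot be standardized; they are set to all zero
    and their count is logged.  The removed per-voxel SD is retained on
    the result (``voxel_scale``) so downstream spatial maps can be
    expressed in the data's original units.
    """
    mean = m.data.mean(axis=0)
    sd = m.data.std(axis=0)
    centered = m.data - mean
    scale_floor = np.finfo(np.float64).tiny
    constant = sd <= np.maximum(np.abs(mean), 1.0) * 1e-12
    safe_sd = np.where(constant | (sd < scale_floor), 1.0, sd)
    out = centered / safe_sd
    if constant.any():
        out[:, constant] = 0.0
        logger.info(
            "subject %s: %d constant voxel column(s) set to zero",
            m.subject_id,
            int(constant.sum()),
        )
    return replace(m, data=out, voxel_scale=safe_sd.copy())


def _highpass_mask(n: int, tr: float, spec: FilterSpec) -> np.ndarray:
    """Boolean keep-mask over rfft bins (True = retained)."""
    freqs = np.fft.rfftfreq(n, d=tr)
    # keep bins at/above cutoff; tolerate rounding so an on-grid cutoff
    # bin is retained
    keep = freqs >= spec.cutoff_hz * (1.0 - 1e-12)
    if not spec.zero_dc:
        keep[0] = True
    return keep


def highpass_fourier(
    m: VoxelTimeSeriesMatrix, spec: FilterSpec | None = None
) -> VoxelTimeSeriesMatrix:
    """Zero all DFT coefficients strictly below the cutoff frequency.

    Operates on the real FFT so conjugate symmetry is preserved and the
    output is exactly real.  Bins at or above the cutoff pass unchanged
    to machine precision; the filter is idempotent.
    """
    spec = spec or FilterSpec()
    spec.validate(m.tr_seconds)
    keep = _highpass_mask(m.n_volumes, m.tr_seconds, spec)
    coeffs = np.fft.rfft(m.data, axis=0)
    coeffs[~keep, :] = 0.0
    out = np.fft.irfft(coeffs, n=m.n_volumes, axis=0)
    return replace(m, data=out)


def lowpass_complement(
    m: VoxelTimeSeriesMatrix, spec: FilterSpec | None = None
) -> VoxelTimeSeriesMatrix:
    """The complementary filter: keep only bins the high-pass removes.

    ``highpass(x) + lowpass_complement(x) == x`` and their energies add
    to the input energy (Parseval).
    """
    spec = spec or FilterSpec()
    spec.validate(m.tr_seconds)
    keep = _highpass_mask(m.n_volumes, m.tr_seconds, spec)
    coeffs = np.fft.rfft(m.data, axis=0)
    coeffs[keep, :] = 0.0
    out = np.fft.irfft(coeffs, n=m.n_volumes, axis=0)
    return replace(m, data=out)


def smooth_gaussian(
    m: VoxelTimeSeriesMatrix, fwhm_voxels: float | tuple[float, float, float]
) -> VoxelTimeSeriesMatrix:
    """Spatially smooth each volume with a separable Gaussian kernel.

    Smoothing is restricted to in-mask voxels: the kernel is renormalized
    at mask edges by dividing the smoothed data by the smoothed mask, so
    signal is not diluted into out-of-mask zeros.  fwhm 0 is the
    identity.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_voxels, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("fwhm_voxels must be non-negative")
    if np.all(fwhm == 0):
        return replace(m, data=m.data.copy())
    sigma = fwhm * FWHM_TO_SIGMA

    mask = np.zeros(m.grid_shape, dtype=np.float64)
    idx = tuple(m.voxel_index.T)
    mask[idx] = 1.0
    weight = ndimage.gaussian_filter(mask, sigma=sigma, mode="constant", cval=0.0)

    out = np.empty_like(m.data)
    vol = np.zeros(m.grid_shape, dtype=np.float64)
    for t in range(m.n_volumes):
        vol[...] = 0.0
        vol[idx] = m.data[t]
        sm = ndimage.gaussian_filter(vol, sigma=sigma, mode="constant", cval=0.0)
        out[t] = (sm[idx] / weight[idx])
    return replace(m, data=out)


@dataclass
class PreprocessRecord:
    """Provenance of one subject's preprocessing run."""

    subject_id: str
    n_discarded: int
    motion_regressed: bool
    constant_columns: int
    smoothed_fwhm: tuple[float, float, float] | None
    filter_cutoff_hz: float | None
    steps: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_discarded": self.n_discarded,
            "motion_regressed": self.motion_regressed,
            "constant_columns": self.constant_columns,
            "smoothed_fwhm": list(self.smoothed_fwhm)
            if self.smoothed_fwhm is not None
            else None,
            "filter_cutoff_hz": self.filter_cutoff_hz,
            "steps": list(self.steps),
        }


def preprocess_subject(
    m: VoxelTimeSeriesMatrix,
    motion: np.ndarray | None = None,
    n_discard: int = 24,
    smooth_fwhm: float | tuple[float, float, float] | None = None,
    filter_spec: FilterSpec | None = FilterSpec(),
) -> tuple[VoxelTimeSeriesMatrix, PreprocessRecord]:
    """Run the full temporal preprocessing chain in its fixed order.

    Pass ``filter_spec=None`` to disable the high-pass filter (the
    unfiltered reference analysis); ``motion=None`` skips motion
    regression; ``smooth_fwhm=None`` skips smoothing.
    """
    steps = []
    if n_discard:
        m = discard_initial_volumes(m, n_discard)
        steps.append(f"discard:{n_discard}")
    if motion is not None:
        motion = np.asarray(motion, dtype=np.float64)
        if n_discard:
            motion = motion[n_discard:]
        m = regress_motion(m, motion)
        steps.append("motion_glm")
    sd = m.data.std(axis=0)
    n_constant = int(np.sum(sd <= np.maximum(np.abs(m.data.mean(axis=0)), 1.0) * 1e-12))
    m = standardize_voxels(m)
    steps.append("standardize")
    if smooth_fwhm is not None:
        m = smooth_gaussian(m, smooth_fwhm)
        steps.append("smooth")
    if filter_spec is not None:
        m = highpass_fourier(m, filter_spec)
        steps.append(f"highpass:{filter_spec.cutoff_hz}")
    logger.info("subject %s preprocessed: %s", m.subject_id, " -> ".join(steps))
    record = PreprocessRecord(
        subject_id=m.subject_id,
        n_discarded=n_discard,
        motion_regressed=motion is not None,
        constant_columns=n_constant,
        smoothed_fwhm=tuple(np.broadcast_to(np.asarray(smooth_fwhm, float), (3,)))
        if smooth_fwhm is not None
        else None,
        filter_cutoff_hz=filter_spec.cutoff_hz if filter_spec is not None else None,
        steps=steps,
    )
    return m, record
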