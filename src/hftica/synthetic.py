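"""Multi-subject synthetic fMRI generator with known ground truth.

Emulates a fast-TR (sub-second) multiband-EPI resting-state acquisition
at desk scale: each subject's in-mask data is a sum of temporally
independent sources with overlapping spatial maps, plus white noise and
a small motion-correlated drift.  Four source families are modeled:

``rsn``
    Resting-state-network-like fluctuations: spectrally shaped noise
    whose amplitude is highest just above the analysis cutoff and decays
    monotonically with frequency (power envelope ~ f^-2e).
``cardiac``
    A heart-beat oscillator at a subject-specific base frequency near
    1-1.3 Hz, with slow sinusoidal frequency modulation standing in for
    heart-rate variability; each subject gets their own source.  The
    waveform is pulsatile (a narrow positive pulse per cycle,
    exp(kappa*cos(phase)) demeaned) rather than a pure cosine: real
    cardiac-linked fMRI signal is spiky, and the resulting peaked
    unimodal marginal is what lets ICA isolate it (a pure sinusoid's
    bimodal marginal creates spurious FastICA optima when several
    subjects' oscillators occupy disjoint stretches of the group time
    course).
``technical``
    A narrowband scanner artifact (default 0.8 Hz) whose spatial map is
    banded in planes parallel to the acquisition slices.
``pulsation``
    Broadband CSF/vessel pulsation across 0.6-1.4 Hz with a gentle
    downward tilt so peak power sits at the low end of the band, as seen
    in ventricular pulsation.

Spectral shaping is done by multiplying the rFFT of white noise with a
kind-specific magnitude envelope and inverse-transforming, which gives
exact, seedable control of band placement.  Because spectrally shaped
Gaussian noise keeps a Gaussian marginal distribution — and mutually
Gaussian sources are not separable by ICA — the shaped kinds are
additionally amplitude-modulated by a slow (< ~0.03 Hz) envelope.  This
mirrors the waxing-and-waning amplitude of real physiological and
network fluctuations, gives the sources the super-Gaussian marginals
that temporal ICA exploits, and leaves band placement essentially
intact (the modulation only smears band edges by the envelope
bandwidth).  All time courses are standardized to zero mean, unit
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import VoxelTimeSeriesMatrix, nyquist_frequency

SOURCE_KINDS = ("rsn", "cardiac", "technical", "pulsation")


@dataclass(frozen=True)
class SourceSpec:
    """Description of one simulated signal source.

    Spectral parameters are interpreted per ``kind``:

    - rsn: ``decay_exponent`` (amplitude ~ f^-decay above ``cutoff_hz``)
    - cardiac: ``base_freq_hz`` +- ``base_freq_sd`` (per-subject draw),
      ``freq_jitter_sd`` (slow FM depth, Hz)
    - technical: ``center_hz`` +- ``bandwidth_hz``/2 boxcar
    - pulsation: ``band_hz`` edges with a linear amplitude taper
      ``taper`` (ratio of amplitude at the upper to the lower edge)

    Spatial parameters: ``blob_centers``/``blob_radius`` give smooth
    Gaussian blobs (radius = sigma in voxels, truncated at 3 sigma;
    radius 0 is a single voxel); ``slice_period`` gives the banded
    technical map (sign alternates every ``slice_period`` slices along
    the third axis).  ``subject_scope`` is ``"shared"`` (same map, a
    fresh independent time course per subject), ``"per-subject"`` (one
    separate source per subject, e.g. cardiac), or an integer subject
    index (present in that subject only).
    """

    kind: str
    subject_scope: str | int = "shared"
    amplitude: float = 1.0
    # rsn
    decay_exponent: float = 1.5
    cutoff_hz: float = 0.25
    # cardiac
    base_freq_hz: float = 1.15
    base_freq_sd: float = 0.07
    freq_jitter_sd: float = 0.015
    fm_rate_hz: float = 0.05
    pulse_shape: float = 1.5  # waveform peakedness kappa; 0 = pure cosine
    # technical
    center_hz: float = 0.8
    bandwidth_hz: float = 0.05
    # pulsation
    band_hz: tuple[float, float] = (0.6, 1.4)
    taper: float = 0.375
    # slow amplitude modulation of the shaped-noise kinds
    envelope_depth: float = 0.6
    envelope_cutoff_hz: float = 0.03
    # spatial
    blob_centers: tuple[tuple[float, float, float], ...] = ()
    blob_radius: float = 2.0
    center_jitter: float = 0.0
    slice_period: int = 2
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")

    def check_frequencies(self, tr_seconds: float) -> None:
        nyq = nyquist_frequency(tr_seconds)
        if self.kind == "cardiac" and not (0 < self.base_freq_hz < nyq):
            raise ValueError(
                f"cardiac base frequency {self.base_freq_hz} Hz outside "
                f"(0, Nyquist={nyq:.4f} Hz) at TR={tr_seconds} s"
            )
        if self.kind == "technical" and not (0 < self.center_hz < nyq):
            raise ValueError(
                f"technical center frequency {self.center_hz} Hz outside "
                f"(0, Nyquist={nyq:.4f} Hz) at TR={tr_seconds} s"
            )
        if self.kind == "pulsation" and not (
            0 <= self.band_hz[0] < self.band_hz[1] <= nyq
        ):
            raise ValueError(
                f"pulsation band {self.band_hz} invalid for Nyquist "
                f"{nyq:.4f} Hz"
            )


def default_source_specs() -> list[SourceSpec]:
    """The standard simulated study: 4 shared sources + per-subject
    cardiac oscillators, with deliberately overlapping spatial maps.

    Amplitudes (peak per-voxel signal SD for a unit-variance time
    course) reflect the relative strength of the source families in
    real fast-TR data: vessel/cardiac pulsation is the strongest
    in-brain fluctuation, network fluctuations are of order the local
    signal SD, and the slice-banded scanner artifact is weak per voxel
    but covers the whole volume.
    """
    return [
        SourceSpec(
            kind="rsn",
            name="rsn_a",
            amplitude=1.0,
            blob_centers=((3.5, 4.0, 3.0), (8.0, 8.0, 4.5)),
            blob_radius=1.8,
        ),
        SourceSpec(
            kind="rsn",
            name="rsn_b",
            amplitude=1.0,
            blob_centers=((4.0, 8.0, 4.5), (8.0, 4.0, 3.0)),
            blob_radius=1.8,
        ),
        SourceSpec(
            kind="technical", name="slice_band", amplitude=0.5, slice_period=2
        ),
        SourceSpec(
            kind="pulsation",
            name="ventricle",
            amplitude=1.5,
            blob_centers=((5.5, 5.5, 3.0), (6.0, 6.0, 5.0)),
            blob_radius=1.6,
        ),
        # Per-subject heart-beat sources sit at distinct vessel-like
        # sites (left/right lateral, anterior, posterior, inferior),
        # away from the central ventricle blob: subjects' vascular
        # anatomy emphasizes different vessels, and near-collinear
        # cardiac maps would make the group mixture ill-conditioned.
        SourceSpec(
            kind="cardiac",
            name="heartbeat",
            amplitude=3.0,
            subject_scope="per-subject",
            blob_centers=(
                (2.0, 5.5, 4.0),
                (9.0, 5.5, 4.0),
                (5.5, 2.0, 4.0),
                (5.5, 9.0, 4.0),
                (5.5, 5.5, 1.0),
            ),
            blob_radius=1.5,
            center_jitter=0.5,
        ),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation settings (desk-scale defaults)."""

    n_subjects: int = 5
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    n_volumes: int = 512
    tr_seconds: float = 0.354
    snr: float = 5.0
    seed: int = 0
    motion_variance_fraction: float = 0.2
    source_specs: tuple[SourceSpec, ...] = field(
        default_factory=lambda: tuple(default_source_specs())
    )

    def __post_init__(self) -> None:
        if self.n_volumes < 64:
            raise ValueError("n_volumes must be >= 64")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 4")
        for spec in self.source_specs:
            spec.check_frequencies(self.tr_seconds)


@dataclass
class GroundTruth:
    """True sources behind a simulated dataset.

    source_timecourses[s] is the (n_volumes, n_sources) matrix of
    subject ``s``; a source absent from that subject has an all-zero
    column.  spatial_maps is (n_sources, n_voxels) over in-mask voxels,
    each row scaled to peak weight = the source's amplitude, so a unit-
    variance time course produces that signal amplitude at the map
    peak.  Labels align one-to-one with sources.
    """

    source_timecourses: list[np.ndarray]
    spatial_maps: np.ndarray
    labels: list[str]
    names: list[str]
    subject_of: list[int | None]
    cardiac_rates: dict[str, float]

    @property
    def n_sources(self) -> int:
        return self.spatial_maps.shape[0]

    def group_timecourses(self, n_discard: int = 0) -> np.ndarray:
        """Concatenate per-subject time courses (optionally dropping the
        first ``n_discard`` volumes of each subject) into the group
        (total_time, n_sources) matrix that group tICA sees."""
        return np.vstack([tc[n_discard:] for tc in self.source_timecourses])


def _shape_noise(envelope: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """White noise spectrally shaped by an rFFT magnitude envelope."""
    white = rng.standard_normal(n)
    coeffs = np.fft.rfft(white) * envelope
    return np.fft.irfft(coeffs, n=n)


def _slow_envelope(
    spec: SourceSpec, n: int, tr: float, rng: np.random.Generator
) -> np.ndarray:
    """1 + depth * (unit-variance lowpass noise): the slow amplitude
    modulation that makes shaped-noise sources super-Gaussian."""
    if spec.envelope_depth <= 0:
        return np.ones(n)
    freqs = np.fft.rfftfreq(n, d=tr)
    env = ((freqs > 0) & (freqs <= spec.envelope_cutoff_hz)).astype(float)
    if env.sum() == 0:
        env[1] = 1.0  # series too short: use the slowest nonzero bin
    slow = _shape_noise(env, n, rng)
    sd = slow.std()
    if sd > 0:
        slow /= sd
    return 1.0 + spec.envelope_depth * slow


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate source time course (zero variance)")
    return x / sd


def generate_source_timecourse(
    spec: SourceSpec,
    n_volumes: int,
    tr_seconds: float,
    rng: np.random.Generator,
    base_freq_hz: float | None = None,
) -> np.ndarray:
    """Generate one unit-variance source time course.

    ``base_freq_hz`` overrides the cardiac base frequency (used for
    per-subject draws); other kinds ignore it.
    """
    spec.check_frequencies(tr_seconds)
    freqs = np.fft.rfftfreq(n_volumes, d=tr_seconds)

    if spec.kind == "rsn":
        env = np.zeros_like(freqs)
        above = freqs >= spec.cutoff_hz
        env[above] = (freqs[above] / spec.cutoff_hz) ** (-spec.decay_exponent)
        x = _shape_noise(env, n_volumes, rng)
    elif spec.kind == "technical":
        lo = spec.center_hz - spec.bandwidth_hz / 2.0
        hi = spec.center_hz + spec.bandwidth_hz / 2.0
        env = ((freqs >= lo) & (freqs <= hi)).astype(float)
        if env.sum() == 0:
            raise ValueError(
                "technical band contains no frequency bins; increase "
                "bandwidth or series length"
            )
        x = _shape_noise(env, n_volumes, rng)
    elif spec.kind == "pulsation":
        lo, hi = spec.band_hz
        env = np.zeros_like(freqs)
        inside = (freqs >= lo) & (freqs <= hi)
        # linear amplitude taper from 1 at the lower edge down to
        # ``taper`` at the upper edge: peak power near the low end
        env[inside] = 1.0 + (spec.taper - 1.0) * (freqs[inside] - lo) / (hi - lo)
        x = _shape_noise(env, n_volumes, rng)
    elif spec.kind == "cardiac":
        base = spec.base_freq_hz if base_freq_hz is None else base_freq_hz
        nyq = nyquist_frequency(tr_seconds)
        if not (0 < base < nyq):
            raise ValueError(
                f"cardiac frequency {base} Hz outside (0, Nyquist={nyq:.4f})"
            )
        t = np.arange(n_volumes) * tr_seconds
        if spec.freq_jitter_sd > 0:
            phase0 = rng.uniform(0, 2 * np.pi)
            fm_phase = rng.uniform(0, 2 * np.pi)
            inst_freq = base + spec.freq_jitter_sd * np.sin(
                2 * np.pi * spec.fm_rate_hz * t + fm_phase
            )
        else:
            phase0 = rng.uniform(0, 2 * np.pi)
            inst_freq = np.full(n_volumes, base)
        phase = phase0 + 2 * np.pi * np.cumsum(inst_freq) * tr_seconds
        if spec.pulse_shape > 0:
            x = np.exp(spec.pulse_shape * np.cos(phase))
        else:
            x = np.cos(phase)
    else:  # pragma: no cover - guarded in SourceSpec
        raise ValueError(spec.kind)
    if spec.kind in ("rsn", "technical", "pulsation"):
        x = x * _slow_envelope(spec, n_volumes, tr_seconds, rng)
    return _standardize(x)


def generate_spatial_map(
    spec: SourceSpec,
    grid_shape: tuple[int, int, int],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Build the full-grid spatial weight volume for one source.

    Technical sources get slice-parallel bands of alternating sign along
    the third (slice) axis; blob kinds get smooth localized Gaussian
    bumps (truncated at 3 sigma) that may overlap across sources.
    ``center_jitter`` > 0 randomly shifts blob centers (needs ``rng``).
    """
    if any(s < 1 for s in grid_shape):
        raise ValueError("grid_shape axes must be positive")
    if spec.kind == "technical":
        weights = np.zeros(grid_shape)
        z = np.arange(grid_shape[2])
        band_sign = np.where((z // max(spec.slice_period, 1)) % 2 == 0, 1.0, -1.0)
        weights[:, :, :] = band_sign[np.newaxis, np.newaxis, :]
        return weights

    centers = spec.blob_centers or ((np.array(grid_shape) - 1) / 2.0,)
    weights = np.zeros(grid_shape)
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij"), axis=-1
    ).astype(float)
    for c in centers:
        c = np.asarray(c, dtype=float)
        if spec.center_jitter > 0:
            if rng is None:
                raise ValueError("center_jitter requires an rng")
            c = c + rng.uniform(-spec.center_jitter, spec.center_jitter, size=3)
            c = np.clip(c, 0, np.asarray(grid_shape) - 1)
        d2 = np.sum((coords - c) ** 2, axis=-1)
        if spec.blob_radius == 0:
            nearest = tuple(int(round(v)) for v in c)
            weights[nearest] += 1.0
        else:
            blob = np.exp(-d2 / (2.0 * spec.blob_radius**2))
            blob[d2 > (3.0 * spec.blob_radius) ** 2] = 0.0
            weights += blob
    if not np.any(weights):
        raise ValueError("spatial map has no nonzero voxel")
    return weights


def ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Brain-like ellipsoidal mask inscribed in the grid (boolean)."""
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = shape * np.array([7.0 / 12.0, 7.0 / 12.0, 4.8 / 8.0])
    grids = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _mask_scan_order(mask: np.ndarray) -> np.ndarray:
    """(n_voxels, 3) coordinates in scan order, first axis fastest."""
    flat = mask.reshape(-1, order="F")
    lin = np.flatnonzero(flat)
    nx, ny, _ = mask.shape
    i = lin % nx
    j = (lin // nx) % ny
    k = lin // (nx * ny)
    return np.column_stack([i, j, k])


def _expand_sources(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[SourceSpec, int | None, float | None]]:
    """Expand specs into concrete sources: (spec, subject_or_None, base_freq).

    Per-subject cardiac specs become one source per subject with a base
    frequency drawn once from N(base, base_sd), clipped to the
    physiological 1.05-1.28 Hz window so the heart-beat peak stays
    inside the 1-1.3 Hz range seen across subjects.
    """
    expanded: list[tuple[SourceSpec, int | None, float | None]] = []
    for spec in config.source_specs:
        if spec.subject_scope == "shared":
            expanded.append((spec, None, None))
        elif spec.subject_scope == "per-subject":
            for s in range(config.n_subjects):
                if spec.kind == "cardiac":
                    base = float(
                        np.clip(
                            rng.normal(spec.base_freq_hz, spec.base_freq_sd),
                            1.05,
                            1.28,
                        )
                    )
                else:
                    base = None
                sub_spec = spec
                if len(spec.blob_centers) > 1:
                    # round-robin: subject s takes the s-th listed site
                    sub_spec = replace(
                        spec,
                        blob_centers=(
                            spec.blob_centers[s % len(spec.blob_centers)],
                        ),
                    )
                expanded.append((sub_spec, s, base))
        else:
            s = int(spec.subject_scope)
            if not 0 <= s < config.n_subjects:
                raise ValueError(
                    f"subject_scope {spec.subject_scope} out of range"
                )
            base = spec.base_freq_hz if spec.kind == "cardiac" else None
            expanded.append((spec, s, base))
    return expanded


def _motion_table(
    n_volumes: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth 6-column random-walk motion parameters (3 trans, 3 rot)."""
    steps = rng.standard_normal((n_volumes, 6)) * 0.01
    walk = np.cumsum(steps, axis=0)
    # mild smoothing for realism
    kernel = np.ones(5) / 5.0
    return np.column_stack(
        [np.convolve(walk[:, c], kernel, mode="same") for c in range(6)]
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[VoxelTimeSeriesMatrix], GroundTruth, list[np.ndarray]]:
    """Simulate the full multi-subject dataset.

    Returns per-subject masked time-by-voxel matrices, the ground truth
    bundle, and per-subject motion tables.  Identical config (including
    seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    mask = ellipsoid_mask(config.grid_shape)
    voxel_index = _mask_scan_order(mask)
    idx = tuple(voxel_index.T)
    n_vox = voxel_index.shape[0]

    sources = _expand_sources(config, rng)
    n_src = len(sources)

    maps = np.empty((n_src, n_vox))
    labels: list[str] = []
    names: list[str] = []
    subject_of: list[int | None] = []
    cardiac_rates: dict[str, float] = {}
    for s_i, (spec, subj, base) in enumerate(sources):
        vol = generate_spatial_map(spec, config.grid_shape, rng)
        w = vol[idx]
        peak = np.abs(w).max()
        if peak == 0:
            raise ValueError(f"source {spec.name or spec.kind}: map empty in mask")
        maps[s_i] = w / peak * spec.amplitude
        labels.append(spec.kind)
        name = spec.name or spec.kind
        if subj is not None:
            name = f"{name}_sub{subj:02d}"
        names.append(name)
        subject_of.append(subj)
        if spec.kind == "cardiac" and base is not None:
            cardiac_rates[name] = base

    timecourses: list[np.ndarray] = []
    for subj in range(config.n_subjects):
        tc = np.zeros((config.n_volumes, n_src))
        for s_i, (spec, owner, base) in enumerate(sources):
            if owner is not None and owner != subj:
                continue
            tc[:, s_i] = generate_source_timecourse(
                spec, config.n_volumes, config.tr_seconds, rng, base_freq_hz=base
            )
        timecourses.append(tc)

    truth = GroundTruth(
        source_timecourses=timecourses,
        spatial_maps=maps,
        labels=labels,
        names=names,
        subject_of=subject_of,
        cardiac_rates=cardiac_rates,
    )

    # Per-voxel noise variance: spatially heterogeneous, chosen so the
    # per-voxel TOTAL variance is identical across subjects.  The floor
    # is set by snr against the mean in-mask signal variance; on top of
    # it, a subject missing a strong local source (e.g. another
    # subject's cardiac blob) receives compensating noise there.  With
    # a subject-invariant total variance the voxelwise standardization
    # applies the same scaling to every subject, so the concatenated
    # group mixture remains exactly low-rank — the regime in which
    # group temporal ICA is well-posed.
    sig_var = np.empty((config.n_subjects, n_vox))
    for subj in range(config.n_subjects):
        active = timecourses[subj].std(axis=0) > 0
        sig_var[subj] = np.sum(maps[active] ** 2, axis=0)
    mean_signal_var = float(sig_var.mean())
    base_var = mean_signal_var / config.snr if np.isfinite(config.snr) else 0.0
    target_var = sig_var.max(axis=0) + base_var
    noise_var = target_var[None, :] - sig_var  # >= base_var everywhere

    matrices: list[VoxelTimeSeriesMatrix] = []
    motion_tables: list[np.ndarray] = []
    for subj in range(config.n_subjects):
        data = timecourses[subj] @ maps
        sd = np.sqrt(noise_var[subj])
        if np.any(sd > 0):
            data = data + rng.standard_normal(data.shape) * sd
        motion = _motion_table(config.n_volumes, rng)
        if config.motion_variance_fraction > 0:
            motion_std = motion.std(axis=0)
            motion_std[motion_std == 0] = 1.0
            m_unit = (motion - motion.mean(axis=0)) / motion_std
            w_m = rng.standard_normal((6, n_vox)) * np.sqrt(
                config.motion_variance_fraction * mean_signal_var / 6.0
            )
            data = data + m_unit @ w_m
        matrices.append(
            VoxelTimeSeriesMatrix(
                data=data,
                tr_seconds=config.tr_seconds,
                voxel_index=voxel_index,
                subject_id=f"sub-{subj + 1:02d}",
                grid_shape=tuple(config.grid_shape),
            )
        )
        motion_tables.append(motion)
    return matrices, truth, motion_tables


def resample_long_tr(
    series: np.ndarray, tr_in: float, tr_out: float
) -> np.ndarray:
    """Decimate a fast-TR series to a slower TR by keeping every k-th
    sample (k = tr_out / tr_in, which must be an integer ratio).

    Used to demonstrate aliasing: an oscillation above the new Nyquist
    folds to |f - round(f * tr_out) / tr_out|.
    """
    if tr_in <= 0 or tr_out <= 0:
        raise ValueError("sampling intervals must be positive")
    ratio = tr_out / tr_in
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"tr_out ({tr_out}) must be an integer multiple of tr_in ({tr_in})"
        )
    return np.asarray(series)[::k]


def alias_frequency(freq_hz: float, tr_out: float) -> float:
    """Apparent frequency after sampling ``freq_hz`` at interval tr_out."""
    return abs(freq_hz - round(freq_hz * tr_out) / tr_out)
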