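# Methods

## The analysis model

The pipeline treats a multi-subject resting-state acquisition as a
blind source separation problem in time. Each subject's masked 4D run
is a time-by-voxel matrix; after temporal preprocessing the subjects
are stacked in time and the concatenated matrix X (ΣTᵢ × V) is modeled
as

    X ≈ S M,    S: ΣTᵢ × n temporally independent time courses,
                M: n × V spatial maps (free to overlap),

which is the temporal-ICA convention: independence is imposed on the
time courses, not the maps, so sources with overlapping spatial
support (vessels threading through networks, global scanner artifacts)
can still be separated — the case where spatial ICA fails by
construction.

Estimation is classical: truncated SVD X ≈ U S Vᵀ for PCA prewhitening
(Z = √(T−1)·U has identity sample covariance), then symmetric FastICA
on Z. When n_ics < n_pcs the ICA rotation is estimated in the subspace
of the top n_ics whitened dimensions; the extra component(s) only
stabilize the prewhitening. This is the behavior one gets from the
standard fastICA implementations when handed k principal components
and asked for k−1 independent components (their internal re-whitening
keeps the top k−1 directions), and it is also a numerical necessity: a
rectangular symmetric unmixing (n rows in a k-dim space, n < k) has no
stable fixed point on noisy data and cycles instead of converging.
With n_ics = n_pcs the reconstruction identity
`ic_timecourses @ spatial_maps = rank-k approximation` holds to 1e-6
relative Frobenius error; with n_ics < n_pcs it holds at rank n_ics.

FastICA details: contrasts logcosh (a = 1, default), exp, cube;
symmetric decorrelation W ← (WWᵀ)^(−1/2) W each step; convergence when
max |⟨wᵢ_new, wᵢ_old⟩| deviates from 1 by less than tol = 1e-6
(max_iter 1000); on non-convergence up to 5 restarts with seeds derived
from the user seed, then an error. Components are canonicalized: sign
chosen so each spatial map has positive skewness (fallback: strongest
voxel positive), order by variance explained (descending). All
randomness — ARPACK starting vector included — derives from the seed,
so identical configuration implies bit-identical output.

### Spatial map units

The analysis operates on voxelwise-standardized data, so raw
back-projected maps are in "standardized voxel" units. The
standardization step records each voxel's removed SD, and
`Decomposition.maps_in_data_units()` multiplies the maps by it,
restoring loadings in the data's own units. This matters for
localized sources: standardization flattens a blob's profile (its
high-variance center is divided by a larger SD than its flanks), and
comparisons against ground-truth maps are only meaningful after the
units are restored.

## Preprocessing

Fixed order: discard initial volumes (default 24) → motion GLM
(intercept + 3 translations + 3 rotations, least squares; SVD
pseudo-inverse with a logged warning if rank-deficient) → voxelwise
standardization (constant columns set to zero and counted) → optional
Gaussian smoothing (separable kernel, σ = FWHM/2.3548, renormalized at
mask edges so signal is not diluted into out-of-mask zeros; off by
default) → Fourier high-pass.

The high-pass filter zeroes every rFFT coefficient at frequencies
strictly below the cutoff (default 0.25 Hz), DC included; the bin
exactly at the cutoff is retained (a strict "below" reading,
configurable via `FilterSpec`). Operating on the real FFT keeps the
output exactly real for odd and even lengths. The filter is a
projection (idempotent) and satisfies the Parseval split
‖x‖² = ‖highpass(x)‖² + ‖complement(x)‖².

## Component characterization

*Consistency.* For each component, per-subject sums of squares SSᵢ of
its time course segment; discard iff maxᵢ SSᵢ/Σⱼ≠ᵢ SSⱼ > 1 (one
subject outweighs all others combined; ratio = ∞ when a single subject
carries everything; undefined and kept-with-note for single-subject
runs). The statistic is scale-invariant.

*Spectra.* Periodograms are computed per subject segment and averaged,
not on the raw concatenation — segment boundaries would otherwise
inject spurious broadband energy. Band fractions are normalized by the
total power inside the analyzed range only (0.25–1.4 Hz for filtered
runs; 0.01–1.4 Hz for the unfiltered reference analysis). The top edge
follows the conventional 1.4 Hz label rather than the exact Nyquist
1.412 Hz; both are configurable.

*Classification.* A deterministic cascade over the five-band
fingerprint, with thresholds engineered from the qualitative
signatures of the component families and exposed in
`ClassificationRules`:

1. technical if fraction(0.75–1.0) ≥ 0.5 and peak sharpness
   (max/median power) ≥ 10 — a narrow ~0.8 Hz peak;
2. else cardiac if the peak frequency lies in [1.0, 1.35] Hz and
   fraction(1.0–1.4) ≥ 0.4;
3. else rsn if the five band fractions decrease with frequency
   (one tie within 5% relative tolerated — sampling noise on five
   coarse bands) and fraction(0.25–0.5) ≥ 0.35;
4. else pulsation if the fraction above 0.6 Hz is ≥ 0.5;
5. else other.

Heart rate is the spectral peak restricted to [0.8 Hz, Nyquist] (must
be a local maximum), reported in Hz and bpm.

## The synthetic study

The generator emulates a fast-TR multi-subject acquisition at desk
scale. Defaults (chosen once as the study conditions): 5 subjects,
12×12×8 grid with an ellipsoidal mask (904 in-mask voxels), 512
volumes at TR = 0.354 s, SNR 5, four shared sources plus one cardiac
source per subject:

- **rsn ×2** — spectrally shaped noise, amplitude envelope ∝ f^(−1.5)
  above 0.25 Hz (power ∝ f^(−3): highest just above the cutoff,
  decaying monotonically); two Gaussian-blob pairs whose blobs overlap
  across the two sources. Peak amplitude 1.
- **technical** — boxcar band 0.8 ± 0.025 Hz; spatial map banded in
  planes parallel to the slice axis, sign alternating every 2 slices,
  covering the whole volume at peak amplitude 0.5 (weak per voxel,
  global in extent).
- **pulsation** — band-limited noise on 0.6–1.4 Hz with a linear
  amplitude taper (1 → 0.375 across the band), so peak power sits at
  the ventricular 0.6–0.8 Hz end and the fraction above 1.0 Hz stays
  below the cardiac rule's threshold; two central blobs, peak
  amplitude 1.5.
- **cardiac ×5** — per-subject oscillator with base rate drawn once
  from N(1.15, 0.07) Hz clipped to [1.05, 1.28], slow sinusoidal
  frequency modulation (depth 0.015 Hz at 0.05 Hz) standing in for
  heart-rate variability, and a pulsatile waveform
  exp(1.5·cos φ(t)) − mean: real cardiac-linked signal is spiky, and
  the peaked unimodal marginal is what makes the source identifiable
  (a pure cosine has a bimodal arcsine marginal, and several
  disjointly-supported bimodal sources create stable spurious FastICA
  optima — verified empirically with all three contrasts). Each
  subject's source sits at one of five distinct vessel-like sites
  (±0.5 voxel jitter), peak amplitude 3: vascular pulsatility is the
  strongest high-frequency signal in fast-TR data, and near-collinear
  cardiac maps would make the group mixture ill-conditioned.

Two generator-level choices are essential for the mixture to be a
well-posed group-tICA problem and are deliberate model features:

1. **Amplitude modulation.** Spectrally shaped Gaussian noise keeps a
   Gaussian marginal, and mutually Gaussian sources are not separable
   by any ICA. The shaped kinds are therefore multiplied by a slow
   (< 0.03 Hz) envelope, 1 + 0.6·lowpass-noise — the
   waxing-and-waning amplitude real physiological and network
   fluctuations show — giving them the super-Gaussian marginals
   temporal ICA exploits while smearing band edges only by the
   envelope bandwidth.
2. **Variance-equalized heterogeneous noise.** Per-voxel noise
   variance has a floor of (mean in-mask signal variance)/SNR and is
   raised per subject so that each voxel's *total* variance is the
   same for every subject. Without this, per-subject voxelwise
   standardization applies a different diagonal scaling to each
   subject (their cardiac blobs sit at different sites), which
   inflates the rank of the concatenated mixture beyond the source
   count and pushes the weakest source directions into the noise
   bulk — a structural failure unrelated to the estimation method.
   Physically this reads as spatially structured noise (higher where a
   given subject lacks a strong local source), a stand-in for the
   tissue-dependent physiological noise floor of real data.

Motion is simulated as smoothed 6-column random walks whose
standardized regressors are injected at 20% of the mean signal
variance; the motion GLM removes the injected part exactly, making the
stage testable.

What the simulator does **not** model: hemodynamic-response
convolution, realistic anatomy or registration error, scanner drift
and spike artifacts, respiration, non-stationary heart rate beyond
sinusoidal FM, and aliased harmonics of the cardiac waveform are only
partly representative (the second harmonic of the pulse train folds
back into the sampled band). Passing the synthetic tests therefore
demonstrates correctness of the pipeline's computations and the
self-consistency of the model, not performance on real scans.

*Aliasing demonstrator.* `resample_long_tr` keeps every k-th sample
(integer TR ratio) and `alias_frequency(f, tr) = |f − round(f·tr)/tr|`
gives the analytic fold; a 1.1 Hz source decimated to TR = 2 s peaks
at 0.1 Hz — the mechanism by which high-frequency physiology
masquerades as low-frequency "noise" in conventional acquisitions.

## Evaluation protocol

`hftica.evaluate` matches estimated components to ground-truth sources
by Hungarian assignment on absolute time-course correlations (truth
time courses trimmed by the discarded volumes), then scores: matched
|r| per source (time courses, and maps in data units), consistency
disposition correctness (kept ⇔ shared), and label correctness. The
decomposition runs at n_ics = number of simulated sources (the
noiseless mixing rank, 9 by default) with one extra principal
component retained, mirroring the k/k−1 convention. The default study
at SNR 5 recovers all four shared sources with time-course |r| ≥ 0.95
and map |r| ≥ 0.90 in 20 of 20 seeds, and disposes/labels ≥ 95% of
matched components correctly.

## Numerical choices and degenerate inputs

- Truncated SVD: scipy's ARPACK Lanczos with a seeded starting vector;
  singular values returned descending; whitening refuses directions
  with singular value ≤ 1e-12 of the largest.
- On-grid cutoff comparison uses a 1e-12 relative guard so the bin at
  the cutoff frequency is retained regardless of floating rounding.
- Constant voxel columns: zeroed and counted (they carry no signal and
  would otherwise produce NaNs).
- Consistency ratio with zero "others" energy returns ∞ (discard).
- Problem sizes in tests and the acceptance script (512-volume,
  5-subject default; 100-seed white-noise calibration; 20-seed
  recovery studies) were chosen so the whole suite runs in well under
  a minute while keeping every statistical margin wide.

## Known limitations

- The consistency criterion assumes equal-length subject segments
  (guaranteed by the pipeline); `component_spectrum` rejects unequal
  segments rather than resampling them.
- Classification thresholds are heuristics tuned to the four synthetic
  families; real data will need threshold adjustment via
  `ClassificationRules` and may populate the `other` class heavily.
- The one-extra-PC convention (n_pcs = n_ics + 1) is reproduced as a
  default without a theoretical justification.
- No out-of-core or GPU path: the group matrix must fit in memory
  (desk-scale; a 10,000 × 240,000 full-study matrix at float64 is
  ~19 GB and would need a thinner dtype or chunked SVD).
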