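"""Component characterization: consistency, spectra, classification.

Three stages turn raw independent components into an interpretable
report:

1. **Subject-consistency filter** — a component is discarded when a
   single subject contributes more variance (sum of squares of its time
   course segment) than all other subjects combined, i.e. when the
   ratio SS_subject / SS_others exceeds 1.  This removes components
   driven by one individual, such as heart-beat oscillations whose
   frequency differs from subject to subject.
2. **Spectral fingerprinting** — per-subject periodograms of the
   component time course are averaged, and the fraction of power in the
   bands 0.25-0.5, 0.5-0.75, 0.75-1.0, 1.0-1.25 and 1.25-1.4 Hz is
   computed (normalized by total power within the analyzed range).
3. **Rule-based labeling** — a deterministic cascade assigns one of
   {technical, cardiac, rsn, pulsation, other} from the band fractions,
   peak frequency, and peak sharpness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

HIGHFREQ_BAND_EDGES = (0.25, 0.5, 0.75, 1.0, 1.25, 1.4)
LOWFREQ_BAND_EDGES = (0.01, 0.10, 0.25, 1.4)


@dataclass
class ConsistencyResult:
    """Per-component subject-consistency summary."""

    component: int
    per_subject_ss: dict[str, float]
    max_ratio: float
    dominant_subject: str
    keep: bool


def consistency_filter(
    ic_timecourses: np.ndarray,
    boundaries: list[tuple[str, int, int]],
) -> list[ConsistencyResult]:
    """Flag components driven by a single subject.

    For each component, computes the sum of squares of its time course
    within every subject's segment; the component is kept iff the
    largest ratio of one subject's SS to the summed SS of all others is
    <= 1.  With a single subject the ratio is undefined and the
    component is kept with a logged note.
    """
    tcs = np.asarray(ic_timecourses)
    ends = sorted(end for _, _, end in boundaries)
    starts = sorted(start for _, start, _ in boundaries)
    if starts[0] != 0 or ends[-1] != tcs.shape[0]:
        raise ValueError("boundaries do not cover all time-course rows")
    results = []
    single = len(boundaries) == 1
    if single:
        logger.info(
            "single-subject input: consistency ratio undefined, keeping all"
        )
    for c in range(tcs.shape[1]):
        ss = {
            sid: float(np.sum(tcs[start:end, c] ** 2))
            for sid, start, end in boundaries
        }
        total = sum(ss.values())
        if single:
            sid = boundaries[0][0]
            results.append(
                ConsistencyResult(c, ss, float("nan"), sid, keep=True)
            )
            continue
        ratios = {
            sid: (s / (total - s) if total - s > 0 else float("inf"))
            for sid, s in ss.items()
        }
        dominant = max(ratios, key=ratios.get)
        max_ratio = ratios[dominant]
        results.append(
            ConsistencyResult(
                component=c,
                per_subject_ss=ss,
                max_ratio=max_ratio,
                dominant_subject=dominant,
                keep=max_ratio <= 1.0,
            )
        )
    n_kept = sum(r.keep for r in results)
    logger.info(
        "consistency filter: %d of %d components kept", n_kept, len(results)
    )
    return results


@dataclass
class ComponentSpectrum:
    """Subject-averaged power spectrum of one component time course.

    ``band_fractions[i]`` is the power between band_edges[i] and
    band_edges[i+1] divided by the total power within
    [band_edges[0], band_edges[-1]]; fractions sum to 1.
    """

    freqs: np.ndarray
    power: np.ndarray
    band_edges: tuple[float, ...]
    band_fractions: np.ndarray
    peak_freq: float

    def fraction_between(self, lo: float, hi: float) -> float:
        """Power in [lo, hi] relative to the analyzed range."""
        analyzed = (self.freqs >= self.band_edges[0]) & (
            self.freqs <= self.band_edges[-1]
        )
        total = self.power[analyzed].sum()
        if total == 0:
            return 0.0
        sel = analyzed & (self.freqs >= lo) & (self.freqs <= hi)
        return float(self.power[sel].sum() / total)

    @property
    def peak_sharpness(self) -> float:
        """Max power over median power within the analyzed range."""
        analyzed = (self.freqs >= self.band_edges[0]) & (
            self.freqs <= self.band_edges[-1]
        )
        p = self.power[analyzed]
        if p.size == 0:
            return 0.0
        med = np.median(p)
        return float(p.max() / med) if med > 0 else float("inf")


def component_spectrum(
    timecourse: np.ndarray,
    boundaries: list[tuple[str, int, int]],
    tr_seconds: float,
    band_edges: tuple[float, ...] = HIGHFREQ_BAND_EDGES,
) -> ComponentSpectrum:
    """Average per-subject periodograms and compute band fractions.

    The periodogram is computed per subject segment (equal lengths
    required) and averaged: computing it on the raw concatenation would
    introduce spurious broadband energy at segment boundaries.
    """
    tc = np.asarray(timecourse, dtype=float)
    lengths = {end - start for _, start, end in boundaries}
    if len(lengths) != 1:
        raise ValueError(f"unequal subject segment lengths: {sorted(lengths)}")
    seg_len = lengths.pop()
    if seg_len < 2 * (len(band_edges) - 1):
        raise ValueError("segments too short for the requested band count")
    edges = tuple(band_edges)
    if list(edges) != sorted(edges) or len(edges) < 2:
        raise ValueError("band_edges must be ordered with >= 2 entries")

    freqs = np.fft.rfftfreq(seg_len, d=tr_seconds)[1:]  # drop DC
    power = np.zeros_like(freqs)
    for _, start, end in boundaries:
        seg = tc[start:end]
        power += np.abs(np.fft.rfft(seg))[1:] ** 2
    power /= len(boundaries)

    analyzed = (freqs >= edges[0]) & (freqs <= edges[-1])
    total = power[analyzed].sum()
    fractions = np.zeros(len(edges) - 1)
    if total > 0:
        for i in range(len(edges) - 1):
            if i < len(edges) - 2:
                sel = (freqs >= edges[i]) & (freqs < edges[i + 1])
            else:  # last band closed at the top edge
                sel = (freqs >= edges[i]) & (freqs <= edges[i + 1])
            fractions[i] = power[sel].sum() / total
    peak_freq = float(freqs[np.argmax(power)])
    return ComponentSpectrum(
        freqs=freqs,
        power=power,
        band_edges=edges,
        band_fractions=fractions,
        peak_freq=peak_freq,
    )


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds of the rule cascade (engineered defaults, all
    configurable; the qualitative signatures they encode are: technical
    = narrow 0.75-1.0 Hz peak, cardiac = 1-1.3 Hz peak, rsn = band power
    decreasing with frequency, pulsation = broadband above 0.6 Hz)."""

    technical_band: tuple[float, float] = (0.75, 1.0)
    technical_fraction: float = 0.5
    technical_sharpness: float = 10.0
    cardiac_peak_range: tuple[float, float] = (1.0, 1.35)
    cardiac_band: tuple[float, float] = (1.0, 1.4)
    cardiac_fraction: float = 0.4
    rsn_first_fraction: float = 0.35
    rsn_tie_rel_tol: float = 0.05
    pulsation_cut_hz: float = 0.6
    pulsation_fraction: float = 0.5


@dataclass
class ComponentLabel:
    """Assigned label plus the rule evidence that produced it."""

    label: str
    evidence: dict = field(default_factory=dict)


def _decreasing_with_one_tie(fractions: np.ndarray, rel_tol: float) -> bool:
    """Strictly decreasing, tolerating at most one tie within rel_tol."""
    ties = 0
    for a, b in zip(fractions[:-1], fractions[1:]):
        if b < a:
            continue
        if a > 0 and (b - a) / a <= rel_tol:
            ties += 1
            if ties > 1:
                return False
        else:
            return False
    return True


def classify_component(
    spectrum: ComponentSpectrum,
    spatial_map: np.ndarray | None = None,
    rules: ClassificationRules | None = None,
) -> ComponentLabel:
    """Deterministic rule cascade over the spectral fingerprint.

    Order: technical -> cardiac -> rsn -> pulsation -> other.  The
    spatial map is accepted for interface symmetry and future
    map-based rules; the default cascade is purely spectral.
    """
    rules = rules or ClassificationRules()
    f = spectrum.band_fractions
    evidence = {
        "band_fractions": [float(v) for v in f],
        "peak_freq": spectrum.peak_freq,
        "peak_sharpness": spectrum.peak_sharpness,
    }

    tech_frac = spectrum.fraction_between(*rules.technical_band)
    evidence["technical_fraction"] = tech_frac
    if (
        tech_frac >= rules.technical_fraction
        and spectrum.peak_sharpness >= rules.technical_sharpness
    ):
        return ComponentLabel("technical", evidence)

    card_frac = spectrum.fraction_between(*rules.cardiac_band)
    evidence["cardiac_fraction"] = card_frac
    lo, hi = rules.cardiac_peak_range
    if lo <= spectrum.peak_freq <= hi and card_frac >= rules.cardiac_fraction:
        return ComponentLabel("cardiac", evidence)

    if (
        _decreasing_with_one_tie(f, rules.rsn_tie_rel_tol)
        and f[0] >= rules.rsn_first_fraction
    ):
        return ComponentLabel("rsn", evidence)

    high_frac = spectrum.fraction_between(
        rules.pulsation_cut_hz, spectrum.band_edges[-1]
    )
    evidence["high_fraction"] = high_frac
    if high_frac >= rules.pulsation_fraction:
        return ComponentLabel("pulsation", evidence)

    return ComponentLabel("other", evidence)


def heart_rate_estimate(
    spectrum: ComponentSpectrum, min_hz: float = 0.8
) -> tuple[float, float]:
    """Peak frequency of a cardiac component, in Hz and beats/minute.

    The search is restricted to [min_hz, Nyquist]; the peak must be a
    local maximum of the spectrum, otherwise an error is raised.
    """
    sel = spectrum.freqs >= min_hz
    if not np.any(sel):
        raise ValueError(f"no frequency bins at or above {min_hz} Hz")
    p = spectrum.power[sel]
    f = spectrum.freqs[sel]
    i = int(np.argmax(p))
    if p[i] <= 0:
        raise ValueError("no spectral peak: all power zero in range")
    left = p[i - 1] if i > 0 else -np.inf
    right = p[i + 1] if i < p.size - 1 else -np.inf
    if not (p[i] > left or p[i] > right):
        raise ValueError("no local maximum in the cardiac range")
    peak = float(f[i])
    return peak, 60.0 * peak


def lowfreq_band_table(spectrum: ComponentSpectrum) -> dict[str, float]:
    """Band-fraction row for an unfiltered-run component, in percent.

    Reports power fractions in 0.01-0.25, 0.01-0.10, 0.10-0.25 and
    0.25-top Hz; the 0.01-0.25 entry is the sum of its two sub-bands.
    The spectrum must have been computed with the low-frequency band
    edges (analysis range 0.01 Hz to the top edge).
    """
    lo = spectrum.band_edges[0]
    top = spectrum.band_edges[-1]
    f_low = spectrum.fraction_between(lo, _just_below(spectrum, 0.10))
    f_mid = spectrum.fraction_between(0.10, _just_below(spectrum, 0.25))
    f_high = spectrum.fraction_between(0.25, top)
    return {
        "0.01-0.25 Hz (%)": 100.0 * (f_low + f_mid),
        "0.01-0.10 Hz (%)": 100.0 * f_low,
        "0.10-0.25 Hz (%)": 100.0 * f_mid,
        f"0.25-{top:g} Hz (%)": 100.0 * f_high,
    }


def _just_below(spectrum: ComponentSpectrum, edge: float) -> float:
    """Largest frequency strictly below ``edge`` on the grid (keeps the
    half-open band convention of band_fractions)."""
    below = spectrum.freqs[spectrum.freqs < edge]
    return float(below[-1]) if below.size else spectrum.band_edges[0]


@dataclass
class ComponentReport:
    """Everything known about one component after characterization."""

    component: int
    consistency: ConsistencyResult
    spectrum: ComponentSpectrum
    label: ComponentLabel
    heart_rate_bpm: float | None = None


def characterize_components(
    ic_timecourses: np.ndarray,
    boundaries: list[tuple[str, int, int]],
    tr_seconds: float,
    spatial_maps: np.ndarray | None = None,
    band_edges: tuple[float, ...] = HIGHFREQ_BAND_EDGES,
    rules: ClassificationRules | None = None,
) -> list[ComponentReport]:
    """Run consistency, spectra and classification for every component."""
    consistency = consistency_filter(ic_timecourses, boundaries)
    reports = []
    for c, cons in enumerate(consistency):
        spec = component_spectrum(
            ic_timecourses[:, c], boundaries, tr_seconds, band_edges
        )
        smap = spatial_maps[c] if spatial_maps is not None else None
        label = classify_component(spec, smap, rules)
        bpm = None
        if label.label == "cardiac":
            try:
                _, bpm = heart_rate_estimate(spec)
            except ValueError:
                logger.warning("component %d: cardiac label but no peak", c)
        reports.append(
            ComponentReport(
                component=c,
                consistency=cons,
                spectrum=spec,
                label=label,
                heart_rate_bpm=bpm,
            )
        )
    return reports


def plot_spectra(reports: list[ComponentReport], path: str) -> None:
    """Optional diagnostic plot of all component spectra (one panel per
    component), written to ``path``.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(reports)
    ncol = min(5, max(n, 1))
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False
    )
    for r, ax in zip(reports, axes.ravel()):
        ax.plot(r.spectrum.freqs, r.spectrum.power, lw=0.8)
        ax.set_title(
            f"IC{r.component} {r.label.label}"
            + ("" if r.consistency.keep else " (discarded)"),
            fontsize=8,
        )
        ax.set_xlabel("Hz", fontsize=7)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
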