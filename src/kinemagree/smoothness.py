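"""Movement smoothness via the modified spectral arc length (SPARC).

SPARC quantifies smoothness of a movement's speed profile v(t) from its
magnitude spectrum: smooth movements concentrate power at low frequencies, so
the normalized spectrum V(omega) = |FFT(v)| / |FFT(v)|_0 of a smooth movement
is a short, rapidly decaying curve. The metric is the negative arc length of
V over [0, omega_c],

    SPARC = - int_0^{omega_c} sqrt( (1/omega_c)^2 + (dV/domega)^2 ) domega,

with the frequency axis normalized by an adaptive cutoff omega_c: the end of
the band in which V stays above an amplitude threshold, capped at a maximum
admissible cutoff. SPARC is always negative; values closer to zero mean
smoother movement. The adaptive cutoff makes the measure robust to the noise
floor and approximately invariant to movement duration and amplitude.

Defaults (zero-padding level 4, amplitude threshold 0.05, cutoff cap 10 Hz)
follow the metric's reference definition and are configurable because
published analyses do not always state their settings.

For rhythmic movements, smoothness is computed per repetition and averaged
(:func:`segment_and_average`), which avoids the spectral mixing of repeated
sub-movements.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .parameters import ScalarSeries

__all__ = ["SparcParams", "SmoothnessResult", "sparc", "segment_and_average"]

#: Minimum number of uniformly spaced samples for a meaningful spectrum.
MIN_SAMPLES = 8


@dataclass(frozen=True)
class SparcParams:
    """SPARC settings: FFT zero-padding exponent, cutoff cap (Hz) and
    normalized amplitude threshold for cutoff selection."""

    pad_level: int = 4
    max_cutoff_hz: float = 10.0
    amp_threshold: float = 0.05

    def __post_init__(self):
        if self.pad_level < 0:
            raise ValueError("pad_level must be >= 0")
        if self.max_cutoff_hz <= 0:
            raise ValueError("max_cutoff_hz must be positive")
        if not (0.0 < self.amp_threshold < 1.0):
            raise ValueError("amp_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class SmoothnessResult:
    """SPARC value (<= 0; closer to 0 = smoother), the selected cutoff, and
    optional per-repetition values with their arithmetic mean."""

    sparc: float
    cutoff_hz: float
    per_repetition: tuple[float, ...] | None = None
    mean_of_repetitions: float | None = None

    def __post_init__(self):
        if self.sparc > 1e-12:
            raise ValueError("SPARC must be non-positive")
        if self.per_repetition is not None:
            object.__setattr__(self, "per_repetition", tuple(self.per_repetition))
            mean = float(np.mean(self.per_repetition))
            if self.mean_of_repetitions is None:
                object.__setattr__(self, "mean_of_repetitions", mean)
            elif abs(self.mean_of_repetitions - mean) > 1e-12:
                raise ValueError("mean_of_repetitions inconsistent with per_repetition")


def _uniform_rate(timestamps: np.ndarray) -> float:
    dt = np.diff(timestamps)
    if dt.size == 0 or not np.allclose(dt, dt.mean(), rtol=1e-6, atol=1e-9):
        raise ValueError("SPARC requires uniformly spaced samples")
    return 1.0 / float(dt.mean())


def _sparc_values(v: np.ndarray, fs: float, params: SparcParams) -> tuple[float, float]:
    nfft = 2 ** int(np.ceil(np.log2(len(v))) + params.pad_level)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mag = np.abs(np.fft.rfft(v, nfft))
    if mag[0] <= 0:
        raise ValueError("all-zero speed profile: SPARC normalization undefined")
    mag = mag / mag[0]
    # restrict to the admissible band, then to the adaptive cutoff: the last
    # frequency at which the normalized magnitude still reaches the threshold
    band = freqs <= params.max_cutoff_hz + 1e-12
    f_b, m_b = freqs[band], mag[band]
    above = np.flatnonzero(m_b >= params.amp_threshold)
    last = above[-1]
    if last < len(f_b) - 1:     # include the first sub-threshold sample
        last += 1
    f_sel, m_sel = f_b[: last + 1], m_b[: last + 1]
    cutoff = float(f_sel[-1])
    span = f_sel[-1] - f_sel[0]
    arc = -float(np.sum(np.sqrt((np.diff(f_sel) / span) ** 2 + np.diff(m_sel) ** 2)))
    return arc, cutoff


def sparc(speed: ScalarSeries, params: SparcParams = SparcParams()) -> SmoothnessResult:
    """Modified spectral arc length of a speed profile.

    Requires at least :data:`MIN_SAMPLES` valid, uniformly spaced samples and
    non-negative speeds; an all-zero profile (no movement) is an error since
    the spectrum cannot be normalized.
    """
    if speed.kind != "speed":
        raise ValueError("sparc expects a speed series")
    if not speed.valid.all():
        raise ValueError("SPARC window contains invalid frames")
    v = speed.values
    if len(v) < MIN_SAMPLES:
        raise ValueError(f"SPARC requires at least {MIN_SAMPLES} samples")
    fs = _uniform_rate(speed.timestamps)
    arc, cutoff = _sparc_values(v, fs, params)
    return SmoothnessResult(arc, cutoff)


def segment_and_average(speed: ScalarSeries, boundaries,
                        params: SparcParams = SparcParams()) -> SmoothnessResult:
    """Per-repetition SPARC, averaged.

    ``boundaries`` are interior repetition times; segments run between
    consecutive boundary times (the series' first/last timestamps close the
    outer segments). Segments too short for a spectrum are skipped with a
    warning; if every segment is skipped an error is raised.
    """
    edges = [float(speed.timestamps[0]), *sorted(float(b) for b in boundaries),
             float(speed.timestamps[-1])]
    per_rep, cutoffs = [], []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        mask = speed.window_mask(t0, t1)
        seg = ScalarSeries(speed.values[mask], speed.timestamps[mask],
                           "speed", speed.valid[mask])
        try:
            res = sparc(seg, params)
        except ValueError as exc:
            warnings.warn(f"repetition [{t0:.2f}, {t1:.2f}] skipped: {exc}", stacklevel=2)
            continue
        per_rep.append(res.sparc)
        cutoffs.append(res.cutoff_hz)
    if not per_rep:
        raise ValueError("no repetition segment was long enough for SPARC")
    mean = float(np.mean(per_rep))
    return SmoothnessResult(mean, float(np.mean(cutoffs)),
                            per_repetition=tuple(per_rep), mean_of_repetitions=mean)
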