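"""Signal-processing toolbox for polysomnographic time series.

Filtering (Butterworth / Bessel, four designs, applied forward-backward so
event timing is never phase-shifted), demeaning and detrending, complex
Morlet decomposition for time-resolved amplitude/power/phase, the
Teager-Kaiser energy operator, per-sample normalized band powers in the
four classical EEG bands, spectrogram, montage re-referencing and
anti-aliased downsampling.

Every function returns new arrays and leaves its input untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import Recording

__all__ = [
    "BandSet",
    "FilterSpec",
    "apply_filter",
    "demean_detrend",
    "morlet",
    "tkeo",
    "normalized_band_powers",
    "spectrogram",
    "rereference",
    "downsample",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # gaussian FWHM in units of sigma


@dataclass(frozen=True)
class BandSet:
    """The four classical EEG frequency bands, in Hz.

    Defaults: delta 0.5-4, theta 4-8, alpha 8-12, sigma 12-16.
    """

    delta: tuple[float, float] = (0.5, 4.0)
    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 12.0)
    sigma: tuple[float, float] = (12.0, 16.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name} must satisfy 0 < low < high, got {(lo, hi)}")
        lows = [lo for _, (lo, _) in self.items()]
        if lows != sorted(lows):
            raise ValueError("bands must be ordered by their low edge")

    def items(self):
        return [
            ("delta", tuple(self.delta)),
            ("theta", tuple(self.theta)),
            ("alpha", tuple(self.alpha)),
            ("sigma", tuple(self.sigma)),
        ]

    @property
    def names(self) -> tuple[str, ...]:
        return ("delta", "theta", "alpha", "sigma")


@dataclass(frozen=True)
class FilterSpec:
    """IIR filter specification: family, design, cutoff(s) and order."""

    family: str = "butterworth"
    design: str = "bandpass"
    cutoffs: tuple[float, ...] = (12.0, 14.0)
    order: int = 3

    def __post_init__(self) -> None:
        if self.family not in ("butterworth", "bessel"):
            raise ValueError(f"filter family must be butterworth or bessel, got {self.family!r}")
        if self.design not in ("lowpass", "highpass", "bandpass", "bandstop"):
            raise ValueError(f"unknown filter design {self.design!r}")
        cut = tuple(float(c) for c in np.atleast_1d(self.cutoffs))
        object.__setattr__(self, "cutoffs", cut)
        n_needed = 2 if self.design in ("bandpass", "bandstop") else 1
        if len(cut) != n_needed:
            raise ValueError(f"{self.design} needs {n_needed} cutoff(s), got {len(cut)}")
        if n_needed == 2 and not cut[0] < cut[1]:
            raise ValueError("band filters need low < high cutoff")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def sos(self, rate: float) -> np.ndarray:
        nyq = rate / 2.0
        for c in self.cutoffs:
            if not 0 < c < nyq:
                raise ValueError(
                    f"cutoff {c} Hz outside (0, {nyq}) for rate {rate} Hz"
                )
        design_fn = sps.butter if self.family == "butterworth" else sps.bessel
        wn = self.cutoffs[0] if len(self.cutoffs) == 1 else list(self.cutoffs)
        return design_fn(self.order, wn, btype=self.design, fs=rate, output="sos")


def _as_1d(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    return x


def apply_filter(series, rate: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase (forward-backward) IIR filter.

    The two-pass application doubles the effective order but cancels the
    phase response, so detected event boundaries stay aligned with the raw
    signal.
    """
    x = _as_1d(series)
    sos = spec.sos(rate)
    if x.size <= 3 * spec.order:
        raise ValueError(
            f"series of {x.size} samples too short for order-{spec.order} filter"
        )
    return sps.sosfiltfilt(sos, x)


def demean_detrend(series, mode: str = "demean") -> np.ndarray:
    """Remove the mean (``mode='demean'``) or the least-squares line
    (``mode='linear-detrend'``) from a series."""
    x = _as_1d(series)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if mode == "demean":
        return sps.detrend(x, type="constant")
    if mode in ("linear-detrend", "detrend", "linear"):
        return sps.detrend(x, type="linear")
    raise ValueError(f"unknown mode {mode!r}")


def _morlet_kernel(rate: float, center_freq: float, cycles: float) -> np.ndarray:
    """Complex Morlet kernel normalized so a unit-amplitude sinusoid at the
    center frequency yields a unit-amplitude envelope."""
    sigma_t = cycles / (2.0 * np.pi * center_freq)
    half = max(1, int(np.ceil(4.0 * sigma_t * rate)))
    t = np.arange(-half, half + 1) / rate
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = envelope * np.exp(2j * np.pi * center_freq * t)
    return kernel / (envelope.sum() / 2.0)


def _convolve_same_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    pad = min(len(kernel) // 2, x.size - 1)
    if pad > 0:
        xp = np.pad(x, pad, mode="reflect")
    else:
        xp = x
    out = sps.fftconvolve(xp, kernel, mode="same")
    return out[pad : pad + x.size] if pad > 0 else out


def morlet(series, rate: float, center_freq: float, cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet decomposition at one center frequency.

    Returns a complex series of the same length; ``np.abs`` is the
    band-limited amplitude, ``np.abs(.)**2`` the power and ``np.angle`` the
    instantaneous phase.  Edges use reflective padding.
    """
    x = _as_1d(series)
    if not 0 < center_freq < rate / 2.0:
        raise ValueError(
            f"center frequency {center_freq} Hz outside (0, {rate / 2.0}) Hz"
        )
    if cycles < 3:
        raise ValueError("morlet needs at least 3 cycles for a well-formed wavelet")
    return _convolve_same_reflect(x, _morlet_kernel(rate, center_freq, cycles))


def tkeo(series) -> np.ndarray:
    """Teager-Kaiser energy operator.

    ``psi[n] = x[n]^2 - x[n-1] * x[n+1]`` for interior samples; the two
    endpoints replicate their nearest interior value.  Accentuates
    transient high-energy bursts such as K-complex deflections.
    """
    x = _as_1d(series)
    if x.size < 3:
        raise ValueError("TKEO needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def normalized_band_powers(series, rate: float, bands: Optional[BandSet] = None) -> np.ndarray:
    """Per-sample relative power in the four EEG bands.

    Absolute power in each band is the squared amplitude of a Morlet
    decomposition at the band's center frequency, with the wavelet width
    chosen so its spectral FWHM matches the band width.  Each sample's four
    powers are divided by their sum, so every row of the returned
    ``n_samples x 4`` matrix sums to exactly 1.  Samples where all four
    powers vanish (identically zero signal) are assigned the uniform 0.25
    sentinel so downstream thresholding stays total.

    The series is demeaned first: the delta wavelet is short enough that a
    DC offset would otherwise leak into the delta estimate.
    """
    if bands is None:
        bands = BandSet()
    x = _as_1d(series)
    highest = max(hi for _, (_, hi) in bands.items())
    if rate < 2.0 * highest:
        raise ValueError(
            f"rate {rate} Hz too low for band edge {highest} Hz (need >= {2*highest})"
        )
    x = x - x.mean() if x.size else x
    powers = np.empty((x.size, 4))
    for j, (_, (lo, hi)) in enumerate(bands.items()):
        fc = 0.5 * (lo + hi)
        cycles = _FWHM * fc / (hi - lo)
        analytic = _convolve_same_reflect(x, _morlet_kernel(rate, fc, cycles))
        powers[:, j] = np.abs(analytic) ** 2
    total = powers.sum(axis=1)
    zero = total == 0.0
    total[zero] = 1.0
    out = powers / total[:, np.newaxis]
    out[zero] = 0.25
    return out


def spectrogram(
    series,
    rate: float,
    window_s: float = 30.0,
    overlap_frac: float = 0.5,
    fmin: float = 0.0,
    fmax: Optional[float] = None,
):
    """Short-time Fourier magnitude, restricted to ``[fmin, fmax]``.

    Returns ``(freqs, times, magnitude)`` with a Hamming taper.  The column
    count is ``floor((N - w) / hop) + 1`` for window length ``w`` samples
    and ``hop = w * (1 - overlap_frac)``.
    """
    x = _as_1d(series)
    if fmax is None:
        fmax = rate / 2.0
    if not 0 <= fmin < fmax <= rate / 2.0:
        raise ValueError(f"need 0 <= fmin < fmax <= Nyquist, got [{fmin}, {fmax}]")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap fraction must be in [0, 1)")
    w = int(round(window_s * rate))
    if w < 8:
        raise ValueError("window too short (need window_s * rate >= 8)")
    hop = max(1, int(round(w * (1.0 - overlap_frac))))
    freqs, times, sxx = sps.spectrogram(
        x,
        fs=rate,
        window="hamming",
        nperseg=w,
        noverlap=w - hop,
        mode="magnitude",
        detrend=False,
    )
    keep = (freqs >= fmin) & (freqs <= fmax)
    return freqs[keep], times, sxx[keep]


def rereference(
    recording: Recording, mode: str, reference: Optional[str] = None
) -> Recording:
    """Re-reference a recording.

    ``single``: subtract one named channel from every channel.
    ``common-average``: subtract the per-sample mean across channels.
    ``bipolar``: n-1 derivations, channel i minus channel i+1, labeled "A-B".
    """
    data = recording.data
    if mode == "single":
        if reference is None:
            raise ValueError("single re-referencing needs a reference channel label")
        ref = recording.channel(reference)
        return Recording(
            data - ref[np.newaxis, :],
            recording.rate,
            recording.channels,
            recording.start_time,
        )
    if mode == "common-average":
        return Recording(
            data - data.mean(axis=0, keepdims=True),
            recording.rate,
            recording.channels,
            recording.start_time,
        )
    if mode == "bipolar":
        if recording.n_channels < 2:
            raise ValueError("bipolar montage needs at least 2 channels")
        labels = tuple(
            f"{a}-{b}" for a, b in zip(recording.channels, recording.channels[1:])
        )
        return Recording(
            data[:-1] - data[1:], recording.rate, labels, recording.start_time
        )
    raise ValueError(f"unknown re-referencing mode {mode!r}")


def downsample(series, rate: float, target: float) -> tuple[np.ndarray, float]:
    """Anti-aliased downsampling to ``target`` Hz.

    For an integer decimation factor: zero-phase Butterworth lowpass at
    0.8 x target/2 followed by sample picking.  Rational non-integer
    factors go through polyphase resampling.  Returns ``(series, new_rate)``.
    """
    x = _as_1d(series)
    if target > rate:
        raise ValueError(f"target rate {target} exceeds input rate {rate}")
    if target == rate:
        return x.copy(), float(rate)
    factor = rate / target
    if abs(factor - round(factor)) < 1e-9:
        q = int(round(factor))
        spec = FilterSpec("butterworth", "lowpass", (0.8 * target / 2.0,), order=8)
        y = sps.sosfiltfilt(spec.sos(rate), x)
        return y[::q].copy(), float(target)
    from fractions import Fraction

    frac = Fraction(target / rate).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    n_out = int(round(x.size * target / rate))
    return y[:n_out], float(target)
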