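"""Wavelet front end: raw voltage -> normalized time x frequency x channel tensor.

The decoder does not see raw traces. Each channel is decomposed with a Morlet
continuous wavelet transform over a geometric frequency bank (adjacent-band
ratio sqrt(2)), the coefficient magnitude is averaged in non-overlapping
windows of ``M`` samples (dropping the effective rate from ``fs`` to
``fs / M``), and each (channel, frequency) series is robustly standardized by
its training-set median and median absolute deviation (MAD).

The CWT is evaluated in the Fourier domain with the analytic Morlet filter
(the Torrence & Compo formulation), one forward FFT per channel and one
inverse FFT per band, with reflection padding against edge wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .core import WidebandRecording

__all__ = [
    "FrequencyBank",
    "WaveletTensor",
    "NormalizationStats",
    "make_frequency_bank",
    "morlet_mother",
    "morlet_fourier_factor",
    "cwt_power",
    "downsample_mean",
    "preprocess_recording",
    "fit_mad",
    "apply_mad",
]

W0_DEFAULT = 6.0  # non-dimensional Morlet frequency constant


@dataclass(frozen=True)
class FrequencyBank:
    """Descending centre frequencies (Hz) with adjacent ratio sqrt(2)."""

    centre_frequencies: np.ndarray
    w0: float = W0_DEFAULT

    def __post_init__(self) -> None:
        f = np.asarray(self.centre_frequencies, dtype=float)
        object.__setattr__(self, "centre_frequencies", f)
        if f.ndim != 1 or len(f) == 0:
            raise ValueError("bank needs at least one frequency")
        if len(f) > 1 and not np.all(np.diff(f) < 0):
            raise ValueError("centre frequencies must be strictly decreasing")

    @property
    def n_bands(self) -> int:
        return len(self.centre_frequencies)

    def band_index(self, f: float, rtol: float = 1e-2) -> int:
        """Index of the band whose centre matches ``f`` within ``rtol``."""
        i = int(np.argmin(np.abs(self.centre_frequencies - f)))
        if abs(self.centre_frequencies[i] - f) > rtol * f:
            raise KeyError(f"{f} Hz is not a member of the frequency bank")
        return i


@dataclass
class WaveletTensor:
    """Time x frequency x channel coefficient array at rate ``fs_effective``.

    ``values`` holds nonnegative magnitudes (or powers) until MAD
    normalization, after which ``normalized`` is set and negative values are
    expected.
    """

    values: np.ndarray
    fs_effective: float
    bank: FrequencyBank
    downsample_factor: int = 1
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("values must be (time, frequency, channel)")
        if v.shape[1] != self.bank.n_bands:
            raise ValueError("frequency axis does not match bank size")
        if not np.all(np.isfinite(v)):
            raise ValueError("tensor contains non-finite values")
        if not self.normalized and v.size and v.min() < 0:
            raise ValueError("raw coefficient tensor must be nonnegative")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


@dataclass
class NormalizationStats:
    """Per (frequency, channel) median and MAD, fitted on training time only."""

    median: np.ndarray  # (freq, channel)
    mad: np.ndarray  # (freq, channel), zero deviations replaced by 1

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=float)
        self.mad = np.asarray(self.mad, dtype=float)
        if self.median.shape != self.mad.shape:
            raise ValueError("median and mad shapes differ")
        if not (np.all(np.isfinite(self.median)) and np.all(np.isfinite(self.mad))):
            raise ValueError("normalization stats must be finite")
        if np.any(self.mad < 0):
            raise ValueError("mad must be nonnegative")


def make_frequency_bank(f_max: float, f_min: float, w0: float = W0_DEFAULT) -> FrequencyBank:
    """Geometric bank ``f_k = f_max * 2**(-k/2)`` for all ``f_k >= f_min``.

    With ``(15000, 2)`` this yields the standard 26-band wide-band bank whose
    lowest centre is 2.59 Hz and which contains the spike-band centres
    468.75, 663 and 3750, 5304 Hz.
    """
    if not (f_max >= f_min > 0):
        raise ValueError("need f_max >= f_min > 0")
    freqs = []
    k = 0
    while True:
        f = f_max * 2.0 ** (-k / 2.0)
        if f < f_min * (1 - 1e-12):
            break
        freqs.append(f)
        k += 1
    return FrequencyBank(np.array(freqs), w0=w0)


def morlet_mother(eta: np.ndarray | float, w0: float = W0_DEFAULT) -> np.ndarray:
    """Morlet mother wavelet pi**(-1/4) * exp(i*w0*eta) * exp(-eta**2 / 2)."""
    eta = np.asarray(eta, dtype=float)
    return np.pi ** (-0.25) * np.exp(1j * w0 * eta) * np.exp(-(eta**2) / 2.0)


def morlet_fourier_factor(w0: float = W0_DEFAULT) -> float:
    """Fourier wavelength per unit scale: lambda = 4*pi*s / (w0 + sqrt(2 + w0^2))."""
    return 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0**2))


def _scales_for(bank: FrequencyBank) -> np.ndarray:
    # frequency f has wavelength 1/f; invert the Morlet Fourier relation
    return 1.0 / (bank.centre_frequencies * morlet_fourier_factor(bank.w0))


def _cwt_channel(
    x: np.ndarray, fs: float, bank: FrequencyBank, out: np.ndarray, magnitude: bool
) -> None:
    """Fill ``out`` (time, freq) with Morlet coefficient magnitude for one channel."""
    n = len(x)
    dt = 1.0 / fs
    scales = _scales_for(bank)
    # reflection padding: half the longest wavelet support (4 sigma each side)
    pad = min(n, int(np.ceil(4.0 * scales.max() / dt)))
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]]) if pad else x
    nfft = next_fast_len(len(xp))
    xhat = fft(np.asarray(xp, dtype=np.float64), n=nfft).astype(np.complex64)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=dt)
    for j, s in enumerate(scales):
        # analytic Morlet filter, unit-energy normalization sqrt(2*pi*s/dt);
        # the Gaussian has support only where |s*omega - w0| < 9
        lo = np.searchsorted(omega[: nfft // 2 + 1], max((bank.w0 - 9.0) / s, 0.0))
        hi = np.searchsorted(omega[: nfft // 2 + 1], (bank.w0 + 9.0) / s)
        prod = np.zeros(nfft, dtype=np.complex64)
        g = (
            np.sqrt(2.0 * np.pi * s / dt)
            * np.pi ** (-0.25)
            * np.exp(-((s * omega[lo:hi] - bank.w0) ** 2) / 2.0)
        )
        prod[lo:hi] = xhat[lo:hi] * g.astype(np.float32)
        w = ifft(prod)[pad : pad + n]
        a = np.abs(w)
        out[:, j] = a if magnitude else a**2


def cwt_power(
    rec: WidebandRecording, bank: FrequencyBank, magnitude: bool = True
) -> np.ndarray:
    """Morlet CWT coefficient array (time, frequency, channel) at full rate.

    ``magnitude=True`` (default) stores |W|; ``False`` stores |W|^2. Output
    length equals input length; edges are handled with reflection padding.
    """
    if bank.centre_frequencies.max() > rec.fs / 2.0 + 1e-9:
        raise ValueError(
            f"band {bank.centre_frequencies.max():g} Hz exceeds Nyquist {rec.fs / 2:g} Hz"
        )
    out = np.empty((rec.n_samples, bank.n_bands, rec.n_channels), dtype=np.float32)
    for c in range(rec.n_channels):
        _cwt_channel(rec.data[c], rec.fs, bank, out[:, :, c], magnitude)
    return out


def downsample_mean(values: np.ndarray, M: int) -> np.ndarray:
    """Non-overlapping window means of length ``M`` along the time (first) axis."""
    if M < 1 or int(M) != M:
        raise ValueError("M must be a positive integer")
    M = int(M)
    if M == 1:
        return np.asarray(values)
    values = np.asarray(values)
    n_out = values.shape[0] // M
    trimmed = values[: n_out * M]
    return trimmed.reshape((n_out, M) + values.shape[1:]).mean(axis=1)


def preprocess_recording(
    rec: WidebandRecording,
    bank: FrequencyBank,
    M: int,
    magnitude: bool = True,
) -> WaveletTensor:
    """CWT + downsample in one pass, one band at a time (bounded memory)."""
    if M < 1 or int(M) != M:
        raise ValueError("M must be a positive integer")
    M = int(M)
    if bank.centre_frequencies.max() > rec.fs / 2.0 + 1e-9:
        raise ValueError("bank exceeds Nyquist frequency")
    n_out = rec.n_samples // M
    out = np.empty((n_out, bank.n_bands, rec.n_channels), dtype=np.float32)
    buf = np.empty((rec.n_samples, bank.n_bands), dtype=np.float32)
    for c in range(rec.n_channels):
        _cwt_channel(rec.data[c], rec.fs, bank, buf, magnitude)
        out[:, :, c] = downsample_mean(buf, M)
    return WaveletTensor(out, fs_effective=rec.fs / M, bank=bank, downsample_factor=M)


def fit_mad(tensor: WaveletTensor, train_mask: np.ndarray) -> NormalizationStats:
    """Median/MAD per (frequency, channel) over training timepoints only."""
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape != (tensor.n_samples,):
        raise ValueError("train_mask must be one flag per timestep")
    if not train_mask.any():
        raise ValueError("train_mask selects no samples")
    x = tensor.values[train_mask].astype(float)  # (t, f, c)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med[None]), axis=0)
    mad = np.where(mad > 0, mad, 1.0)  # constant series normalize to zeros
    return NormalizationStats(median=med, mad=mad)


def apply_mad(tensor: WaveletTensor, stats: NormalizationStats) -> WaveletTensor:
    """Standardize: X <- (X - median) / MAD, per (frequency, channel)."""
    if stats.median.shape != tensor.values.shape[1:]:
        raise ValueError(
            "normalization stats fitted on a different bank/channel layout"
        )
    v = (tensor.values - stats.median[None]) / stats.mad[None]
    return replace(tensor, values=v.astype(np.float32), normalized=True)
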