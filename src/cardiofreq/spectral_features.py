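"""Power-spectrum band-ratio features from 256-sample ECG windows.

The reduction chain is: radix-2 decimation-in-time FFT of the window
(unnormalized forward transform, implemented from the even/odd recursion
rather than delegated, because the transform is part of the method under
study) -> squared-magnitude power spectrum of all 256 coefficients ->
drop the lowest 8 bins (DC/baseline drift) and the highest 8 bins
(near-empty top of the band) -> sum the remaining 240 bins in eight
contiguous sections of 30 -> divide each section sum PF_j by the total
retained power AF.  The eight ratios R_j = PF_j / AF sum to one, are
scale-invariant to sensor gain, and compress 256 raw samples to 8
network inputs — a 1:32 data reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cardiofreq.signal_io import Window

SPECTRUM_LEN = 256
TRIM_LOW = 8
TRIM_HIGH = 8
RETAINED_LEN = SPECTRUM_LEN - TRIM_LOW - TRIM_HIGH  # 240
N_SECTIONS = 8
SECTION_LEN = RETAINED_LEN // N_SECTIONS  # 30


@dataclass(frozen=True)
class PowerSpectrum:
    """Squared magnitudes |Ft(u)|^2 of the window's 256 FFT coefficients."""

    power: np.ndarray
    window_len: int = SPECTRUM_LEN

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "power", p)
        if p.size != self.window_len:
            raise ValueError(f"expected {self.window_len} power bins, got {p.size}")
        if np.any(p < 0):
            raise ValueError("power bins must be non-negative")


@dataclass(frozen=True)
class FeatureVector:
    """Eight cumulative frequency-band ratios R_j = PF_j / AF.

    ``degenerate`` flags a window whose retained spectral power AF is
    (numerically) zero — e.g. a constant stream, whose only energy sits
    in the trimmed DC bin; its ratios are all zero and it should be
    excluded from training.
    """

    ratios: np.ndarray
    section_sums: np.ndarray
    total: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        s = np.asarray(self.section_sums, dtype=float)
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "section_sums", s)
        if r.size != N_SECTIONS or s.size != N_SECTIONS:
            raise ValueError(f"expected {N_SECTIONS} sections")
        if not self.degenerate and (np.any(r < 0) or np.any(r > 1)):
            raise ValueError("ratios must lie in [0, 1]")


def _fft_recursive(a: np.ndarray) -> np.ndarray:
    """Decimation-in-time butterfly on the last axis (length a power of two)."""
    n = a.shape[-1]
    if n == 1:
        return a.astype(complex)
    even = _fft_recursive(a[..., 0::2])
    odd = _fft_recursive(a[..., 1::2])
    k = n // 2
    twiddle = np.exp(-2j * np.pi * np.arange(k) / n)
    t = twiddle * odd
    return np.concatenate([even + t, even - t], axis=-1)


def fft_radix2(samples: Window | np.ndarray) -> np.ndarray:
    """Unnormalized forward DFT, Ft(u) = sum_x G(x) exp(-i 2 pi u x / N).

    Computed by recursive even/odd (Cooley-Tukey radix-2) decomposition;
    the input length must be a power of two.  Accepts a :class:`Window`
    or a batch array whose last axis is the sample axis.
    """
    a = samples.samples if isinstance(samples, Window) else np.asarray(samples, dtype=float)
    n = a.shape[-1]
    if n < 1 or (n & (n - 1)) != 0:
        raise ValueError(f"FFT length must be a power of two, got {n}")
    return _fft_recursive(a)


def power_spectrum(coefficients: np.ndarray) -> PowerSpectrum:
    """Squared magnitude per coefficient: power[u] = Re^2 + Im^2."""
    c = np.asarray(coefficients)
    if c.size != SPECTRUM_LEN:
        raise ValueError(f"expected {SPECTRUM_LEN} coefficients, got {c.size}")
    return PowerSpectrum(power=(c.real**2 + c.imag**2))


def trim_noise_bins(spectrum: PowerSpectrum | np.ndarray) -> np.ndarray:
    """Drop the 8 lowest and 8 highest bins, keeping indices 8..247 (240 values)."""
    p = spectrum.power if isinstance(spectrum, PowerSpectrum) else np.asarray(spectrum, dtype=float)
    if p.size != SPECTRUM_LEN:
        raise ValueError(f"expected {SPECTRUM_LEN} power bins, got {p.size}")
    return p[TRIM_LOW : SPECTRUM_LEN - TRIM_HIGH]


def section_features(retained: np.ndarray) -> FeatureVector:
    """Eight section sums PF_j over consecutive 30-bin bands, normalized by AF.

    AF is the total power over the 240 retained bins, so the ratios sum
    to one exactly (up to rounding).  AF == 0 marks the window degenerate.
    """
    r = np.asarray(retained, dtype=float)
    if r.size != RETAINED_LEN:
        raise ValueError(f"expected {RETAINED_LEN} retained bins, got {r.size}")
    pf = r.reshape(N_SECTIONS, SECTION_LEN).sum(axis=1)
    af = float(pf.sum())
    if af <= 0.0:
        return FeatureVector(
            ratios=np.zeros(N_SECTIONS), section_sums=pf, total=af, degenerate=True
        )
    return FeatureVector(ratios=pf / af, section_sums=pf, total=af)


def extract_features(window: Window) -> FeatureVector:
    """Full chain for one window: FFT -> power -> trim -> section ratios."""
    if len(window) != SPECTRUM_LEN:
        raise ValueError(f"expected a {SPECTRUM_LEN}-sample window, got {len(window)}")
    coeffs = fft_radix2(window)
    spec = power_spectrum(coeffs)
    return section_features(trim_noise_bins(spec))


def extract_features_batch(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized feature extraction for an (n_windows, 256) sample matrix.

    Returns ``(ratios, degenerate)`` of shapes (n, 8) and (n,).  Matches
    :func:`extract_features` window by window bit for bit (same butterfly
    summation order).
    """
    a = np.asarray(samples, dtype=float)
    if a.ndim != 2 or a.shape[1] != SPECTRUM_LEN:
        raise ValueError(f"expected shape (n, {SPECTRUM_LEN}), got {a.shape}")
    coeffs = fft_radix2(a)
    power = coeffs.real**2 + coeffs.imag**2
    retained = power[:, TRIM_LOW : SPECTRUM_LEN - TRIM_HIGH]
    pf = retained.reshape(-1, N_SECTIONS, SECTION_LEN).sum(axis=2)
    af = pf.sum(axis=1)
    degenerate = af <= 0.0
    ratios = np.zeros_like(pf)
    ok = ~degenerate
    ratios[ok] = pf[ok] / af[ok, None]
    return ratios, degenerate
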