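"""Continuous wavelet transform and scalogram image rendering.

The CWT of a signal f(t) at scale a and translation b is the inner product
of f with a scaled, translated, conjugated mother wavelet:

    W(a, b) = n(a) * integral f(t) conj(Psi((t - b) / a)) dt

with the scale normalization n(a) = a^{-1/2} (L2, default — preserves the
L2 norm of the analyzing wavelet) or n(a) = a^{-1} (L1). The default mother
wavelet is the complex Morlet

    Psi(t) = pi^{-1/4} exp(i w0 t) exp(-t^2 / 2),   w0 = 6,

whose scale-to-frequency map is f = w0 / (2 pi a). Two implementations are
provided: an FFT-convolution fast path (:func:`cwt`) and a literal
Riemann-sum evaluation of the defining integral (:func:`cwt_reference`) kept
as a slow cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import signal as sps

from .data import ImageSet
from .preprocess import CANONICAL_BANDS, FrequencyBand, split_bands
from .recording import EEGRecording

__all__ = [
    "CWTCoefficients",
    "Scalogram",
    "morlet_center_freq",
    "scale_to_freq",
    "freq_to_scale",
    "scale_grid_for_band",
    "cwt",
    "cwt_reference",
    "render_scalogram",
    "ridge_frequencies",
    "build_image_dataset",
    "scalogram_image_set",
]

_WAVELETS = ("morlet",)
_MORLET_W0 = 6.0
_SUPPORT_SIGMAS = 6.0  # truncate the Gaussian envelope at +-6 sigma


@dataclass(frozen=True)
class CWTCoefficients:
    """Complex CWT coefficient grid with its scale -> frequency map."""

    values: np.ndarray  # complex, (n_scales, n_samples)
    scales: np.ndarray  # strictly increasing, seconds
    freqs: np.ndarray  # strictly decreasing, Hz
    wavelet_name: str = "morlet"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        scales = np.asarray(self.scales, dtype=float)
        freqs = np.asarray(self.freqs, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(scales):
            raise ValueError("values must be (n_scales, n_samples)")
        if len(scales) < 1 or np.any(scales <= 0):
            raise ValueError("scales must be positive")
        if len(scales) > 1 and not (np.all(np.diff(scales) > 0) and np.all(np.diff(freqs) < 0)):
            raise ValueError("scales must increase and freqs decrease")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "freqs", freqs)


@dataclass(frozen=True)
class Scalogram:
    """Min-max-normalized magnitude image of a CWT, in [0, 1]."""

    image: np.ndarray  # (H, W)
    band: FrequencyBand | None = None
    channel: str = ""
    source_epoch: str = ""

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("scalogram image must be 2-D")
        if not np.all(np.isfinite(img)) or img.min() < -1e-12 or img.max() > 1 + 1e-12:
            raise ValueError("scalogram values must be finite and in [0, 1]")
        object.__setattr__(self, "image", np.clip(img, 0.0, 1.0))


def morlet_center_freq(wavelet: str = "morlet") -> float:
    """Center frequency (Hz at unit scale) of the named mother wavelet."""
    if wavelet not in _WAVELETS:
        raise ValueError(f"unknown wavelet {wavelet!r}; available: {_WAVELETS}")
    return _MORLET_W0 / (2.0 * np.pi)


def scale_to_freq(scales: np.ndarray, wavelet: str = "morlet") -> np.ndarray:
    """Map scales (seconds) to pseudo-frequencies (Hz)."""
    return morlet_center_freq(wavelet) / np.asarray(scales, dtype=float)


def freq_to_scale(freqs: np.ndarray, wavelet: str = "morlet") -> np.ndarray:
    """Inverse of :func:`scale_to_freq`."""
    return morlet_center_freq(wavelet) / np.asarray(freqs, dtype=float)


def scale_grid_for_band(
    band: FrequencyBand, n_scales: int = 16, wavelet: str = "morlet", fs: float = 250.0
) -> np.ndarray:
    """Scales whose center frequencies are log-spaced over [band.low, band.high].

    The first scale maps to ``band.high`` and the last to ``band.low``
    (increasing scale = decreasing frequency).
    """
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    if not (0 < band.low < band.high < fs / 2):
        raise ValueError(f"band [{band.low}, {band.high}] outside (0, Nyquist={fs / 2})")
    freqs = np.geomspace(band.high, band.low, n_scales)
    return freq_to_scale(freqs, wavelet)


def _morlet_kernel(scale: float, fs: float, normalization: str) -> np.ndarray:
    # conj(Psi(-t/a)) sampled on the grid, times n(a) dt: convolving the
    # signal with this kernel evaluates the CWT integral at every b.
    half = int(np.ceil(_SUPPORT_SIGMAS * scale * fs))
    t = np.arange(-half, half + 1) / fs
    x = t / scale
    psi = np.pi**-0.25 * np.exp(1j * _MORLET_W0 * x) * np.exp(-0.5 * x**2)
    norm = scale**-0.5 if normalization == "L2" else 1.0 / scale
    # conj(Psi((t-b)/a)) as a convolution kernel: k(u) = conj(Psi(-u/a));
    # the dt factor of the Riemann sum is applied by the caller
    return norm * np.conj(psi[::-1])


def cwt(
    signal: np.ndarray,
    fs: float,
    scales: np.ndarray,
    wavelet: str = "morlet",
    normalization: str = "L2",
) -> CWTCoefficients:
    """FFT-convolution CWT of a 1-D signal.

    ``normalization`` selects the scale prefactor: ``"L2"`` (1/sqrt(a),
    default) or ``"L1"`` (1/a). The transform is linear in the input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or len(signal) < 2:
        raise ValueError("signal must be 1-D with length >= 2")
    if wavelet not in _WAVELETS:
        raise ValueError(f"unknown wavelet {wavelet!r}; available: {_WAVELETS}")
    if normalization not in ("L1", "L2"):
        raise ValueError("normalization must be 'L1' or 'L2'")
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    order = np.argsort(scales)
    scales_sorted = scales[order]
    dt = 1.0 / fs
    values = np.empty((len(scales_sorted), len(signal)), dtype=complex)
    for i, a in enumerate(scales_sorted):
        kernel = _morlet_kernel(a, fs, normalization) * dt
        values[i] = sps.fftconvolve(signal, kernel, mode="same")
    return CWTCoefficients(
        values=values,
        scales=scales_sorted,
        freqs=scale_to_freq(scales_sorted, wavelet),
        wavelet_name=wavelet,
    )


def cwt_reference(
    signal: np.ndarray,
    fs: float,
    scales: np.ndarray,
    wavelet: str = "morlet",
    normalization: str = "L2",
) -> CWTCoefficients:
    """Slow Riemann-sum evaluation of the CWT integral (cross-check path).

    For each (scale a, translation b = j/fs) this sums
    ``n(a) * f(t_k) conj(Psi((t_k - b)/a)) dt`` directly over all samples.
    """
    signal = np.asarray(signal, dtype=float)
    if wavelet not in _WAVELETS:
        raise ValueError(f"unknown wavelet {wavelet!r}")
    scales = np.sort(np.asarray(scales, dtype=float))
    n = len(signal)
    t = np.arange(n) / fs
    dt = 1.0 / fs
    values = np.empty((len(scales), n), dtype=complex)
    for i, a in enumerate(scales):
        norm = a**-0.5 if normalization == "L2" else 1.0 / a
        for j in range(n):
            x = (t - t[j]) / a
            psi = np.pi**-0.25 * np.exp(1j * _MORLET_W0 * x) * np.exp(-0.5 * x**2)
            values[i, j] = norm * np.sum(signal * np.conj(psi)) * dt
    return CWTCoefficients(
        values=values, scales=scales, freqs=scale_to_freq(scales, wavelet), wavelet_name=wavelet
    )


def ridge_frequencies(coeffs: CWTCoefficients) -> float:
    """Frequency of the scale row with maximal mean |coefficient|."""
    energy = np.mean(np.abs(coeffs.values), axis=1)
    return float(coeffs.freqs[int(np.argmax(energy))])


def render_scalogram(
    coeffs: CWTCoefficients,
    size: tuple[int, int] = (64, 64),
    band: FrequencyBand | None = None,
    channel: str = "",
    source_epoch: str = "",
) -> Scalogram:
    """Render |coefficients| as a fixed-size image in [0, 1].

    Magnitudes are min-max normalized per image (a constant-magnitude grid
    maps to all zeros), then resampled to ``size`` by bilinear interpolation.
    """
    mag = np.abs(coeffs.values)
    if not np.all(np.isfinite(mag)):
        raise ValueError("non-finite CWT coefficients")
    lo, hi = mag.min(), mag.max()
    norm = np.zeros_like(mag) if hi == lo else (mag - lo) / (hi - lo)
    h, w = norm.shape
    H, W = size
    # map_coordinates with an exact index grid: identity when sizes match
    rows = np.linspace(0, h - 1, H)
    cols = np.linspace(0, w - 1, W)
    grid = np.meshgrid(rows, cols, indexing="ij")
    img = ndimage.map_coordinates(norm, grid, order=1, mode="nearest")
    return Scalogram(image=img, band=band, channel=channel, source_epoch=source_epoch)


def _epochs(rec: EEGRecording, epoch_length_s: float) -> int:
    per = int(round(epoch_length_s * rec.fs))
    if per < 2:
        raise ValueError("epoch too short")
    return rec.n_samples // per


def scalogram_image_set(
    recordings: list[EEGRecording],
    bands: tuple[FrequencyBand, ...] = CANONICAL_BANDS,
    channels: tuple[str, ...] | None = None,
    epoch_length_s: float = 2.0,
    size: tuple[int, int] = (64, 64),
    n_scales: int = 32,
    wavelet: str = "morlet",
    normalization: str = "L2",
) -> ImageSet:
    """Full pipeline from recordings to an in-memory scalogram image set.

    One image per (recording, epoch, channel, band): the recording is
    band-split (zero-phase FIR), epoched into non-overlapping windows, and
    each band epoch is CWT-transformed on a per-band log-spaced scale grid
    and rendered at ``size``.
    """
    images, labels, rows = [], [], []
    for rec in recordings:
        sel = rec if channels is None else rec.pick(list(channels))
        n_ep = _epochs(sel, epoch_length_s)
        per = int(round(epoch_length_s * sel.fs))
        band_signals = split_bands(sel, bands)
        for bs in band_signals:
            scales = scale_grid_for_band(bs.band, n_scales=n_scales, wavelet=wavelet, fs=sel.fs)
            for ch_i, ch_name in enumerate(sel.channel_names):
                for ep in range(n_ep):
                    seg = bs.signal[ch_i, ep * per : (ep + 1) * per]
                    coeffs = cwt(seg, sel.fs, scales, wavelet=wavelet, normalization=normalization)
                    scal = render_scalogram(
                        coeffs, size=size, band=bs.band, channel=ch_name,
                        source_epoch=f"{rec.subject_id}_e{ep}",
                    )
                    images.append(scal.image.astype(np.float32))
                    labels.append(rec.label)
                    rows.append(
                        {
                            "subject": rec.subject_id,
                            "band": bs.band.name,
                            "channel": ch_name,
                            "epoch": ep,
                        }
                    )
    stack = np.stack(images) if images else np.zeros((0,) + tuple(size), dtype=np.float32)
    return ImageSet(stack, np.asarray(labels, dtype=np.int64), pd.DataFrame(rows) if rows else None)


def build_image_dataset(
    recordings: list[EEGRecording],
    out_dir: str | Path,
    bands: tuple[FrequencyBand, ...] = CANONICAL_BANDS,
    channels: tuple[str, ...] | None = None,
    epoch_length_s: float = 2.0,
    size: tuple[int, int] = (64, 64),
    n_scales: int = 32,
    wavelet: str = "morlet",
    normalization: str = "L2",
) -> pd.DataFrame:
    """Render scalogram PNGs to ``out_dir`` and return the CSV manifest.

    Produces ``n_recordings x n_epochs x n_channels x n_bands`` images with
    manifest columns (path, label, subject, band, channel, epoch).
    """
    from .data import save_image_set

    dataset = scalogram_image_set(
        recordings,
        bands=bands,
        channels=channels,
        epoch_length_s=epoch_length_s,
        size=size,
        n_scales=n_scales,
        wavelet=wavelet,
        normalization=normalization,
    )
    return save_image_set(dataset, out_dir)
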