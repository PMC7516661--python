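"""Signal conditioning: RMS normalization, low-pass filtering, wavelet
denoising and fixed-length epoch segmentation.

The chain runs in this order on each record: normalize by the whole-record
RMS, zero-phase 3rd-order Butterworth low-pass at 300 Hz, wavelet soft-
threshold denoising, then split into consecutive non-overlapping 1-s
epochs.  RMS normalization makes the whole chain invariant to the absolute
amplitude of the recording; the remaining stages are linear or
scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .errors import DegenerateSignalError, LengthError, ParameterError
from .synthgen import EGMRecord

__all__ = [
    "PreprocConfig",
    "rms_normalize",
    "lowpass",
    "wavelet_denoise",
    "segment",
    "preprocess_record",
    "preprocess_samples",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters.

    ``lowpass_order``/``lowpass_cutoff`` define the Butterworth low-pass
    (order 3, 300 Hz).  The wavelet denoiser uses a ``wavelet_name``
    decomposition of depth ``wavelet_levels`` with universal soft
    thresholding.  ``window_s`` is the analysis epoch length in seconds.
    """

    lowpass_order: int = 3
    lowpass_cutoff: float = 300.0
    wavelet_name: str = "db4"
    wavelet_levels: int = 4
    threshold_rule: str = "universal-soft"
    window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.lowpass_order < 1:
            raise ParameterError("lowpass_order must be >= 1")
        if self.lowpass_cutoff <= 0:
            raise ParameterError("lowpass_cutoff must be positive")
        if self.window_s <= 0:
            raise ParameterError("window_s must be positive")
        if self.threshold_rule != "universal-soft":
            raise ParameterError(f"unknown threshold_rule {self.threshold_rule!r}")


def rms_normalize(x: np.ndarray) -> np.ndarray:
    """Divide by the root-mean-square value; the output has unit RMS."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DegenerateSignalError("empty signal")
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise DegenerateSignalError("all-zero signal has no RMS scale")
    return x / rms


def lowpass(x: np.ndarray, fs: float, config: PreprocConfig = PreprocConfig()) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass; DC gain 1.

    The forward-backward pass squares the magnitude response, so the gain
    at the cutoff frequency is 1/2 in power terms rather than 1/sqrt(2).
    """
    if config.lowpass_cutoff >= fs / 2:
        raise ParameterError(
            f"cutoff {config.lowpass_cutoff} Hz must be below Nyquist ({fs / 2} Hz)"
        )
    sos = sps.butter(
        config.lowpass_order, config.lowpass_cutoff, btype="low", fs=fs, output="sos"
    )
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def wavelet_denoise(x: np.ndarray, config: PreprocConfig = PreprocConfig()) -> np.ndarray:
    """Soft-threshold wavelet denoising with the universal threshold.

    Detail coefficients at every level are soft-thresholded at
    sigma * sqrt(2 ln N), with sigma estimated as MAD(finest details)/0.6745.
    Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2**config.wavelet_levels:
        raise LengthError(
            f"signal of {n} samples too short for {config.wavelet_levels} "
            "decomposition levels"
        )
    coeffs = pywt.wavedec(x, config.wavelet_name, level=config.wavelet_levels)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    if thresh == 0:  # noise-free input: nothing to shrink
        return x.copy()
    denoised = [coeffs[0]] + [
        pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]
    ]
    return pywt.waverec(denoised, config.wavelet_name)[:n]


def segment(x: np.ndarray, fs: float, window_s: float = 1.0) -> list:
    """Split into consecutive non-overlapping windows of round(window_s*fs)
    samples; a trailing remainder shorter than one window is discarded."""
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    if win <= 0:
        raise ParameterError("window_s * fs must round to a positive sample count")
    if len(x) < win:
        raise LengthError(
            f"signal of {len(x)} samples shorter than one {win}-sample window"
        )
    n_seg = len(x) // win
    return [x[i * win : (i + 1) * win].copy() for i in range(n_seg)]


def preprocess_record(
    record: EGMRecord, config: PreprocConfig = PreprocConfig()
) -> list:
    """Full conditioning chain: normalize -> low-pass -> denoise -> segment."""
    x = rms_normalize(record.samples)
    x = lowpass(x, record.fs, config)
    x = wavelet_denoise(x, config)
    return segment(x, record.fs, config.window_s)


def preprocess_samples(
    samples: np.ndarray, fs: float, config: PreprocConfig = PreprocConfig()
) -> np.ndarray:
    """The conditioning chain without segmentation (normalize -> low-pass ->
    denoise); used where the full-length conditioned series is needed, e.g.
    to build surrogates before epoching."""
    x = rms_normalize(samples)
    x = lowpass(x, fs, config)
    return wavelet_denoise(x, config)
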