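"""Discrete-wavelet ECG denoising (Daubechies db6).

The denoiser removes the three classic ECG contaminants:

* baseline drift — by zeroing the deepest approximation band;
* powerline and EMG/white noise — by thresholding the detail coefficients
  with a per-level universal threshold, the noise scale estimated from the
  median absolute deviation of each detail band.

The dyadic DWT (scale parameter a0 = 2, position parameter b0 = 1) is
computed with PyWavelets.  The requested decomposition depth is clamped to
the maximum depth the signal length supports; an error is raised only when
the signal is shorter than the wavelet filter itself.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt

__all__ = ["WaveletConfig", "dwt_decompose", "denoise"]


@dataclasses.dataclass(frozen=True)
class WaveletConfig:
    wavelet_id: str = "db6"
    levels: int = 8
    threshold_rule: str = "universal_soft"
    drop_approximation: bool = True
    a0: int = 2
    b0: int = 1
    mode: str = "symmetric"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.a0 != 2 or self.b0 != 1:
            raise ValueError("the dyadic DWT requires a0=2 and b0=1")
        if self.threshold_rule not in ("universal_soft", "universal_hard"):
            raise ValueError(f"unknown threshold_rule: {self.threshold_rule!r}")


def _effective_levels(n: int, cfg: WaveletConfig) -> int:
    wavelet = pywt.Wavelet(cfg.wavelet_id)
    if n < wavelet.dec_len:
        raise ValueError(
            f"signal of length {n} is shorter than the {cfg.wavelet_id} filter "
            f"({wavelet.dec_len} taps)"
        )
    return max(1, min(cfg.levels, pywt.dwt_max_level(n, wavelet.dec_len)))


def dwt_decompose(signal, cfg: WaveletConfig | None = None) -> list[np.ndarray]:
    """Multi-level DWT: ``[cA_J, cD_J, ..., cD_1]`` (PyWavelets ordering)."""
    if cfg is None:
        cfg = WaveletConfig()
    signal = np.asarray(signal, dtype=float)
    levels = _effective_levels(len(signal), cfg)
    return pywt.wavedec(signal, cfg.wavelet_id, mode=cfg.mode, level=levels)


def denoise(signal, cfg: WaveletConfig | None = None) -> np.ndarray:
    """Wavelet-thresholded reconstruction, same length as the input.

    Per detail level the noise scale is estimated as MAD/0.6745 and the
    universal threshold ``sigma * sqrt(2 ln n)`` applied (soft or hard).
    With ``drop_approximation`` the deepest approximation band — the
    sub-Hz content at typical ECG rates and depths — is zeroed, which
    removes baseline wander.
    """
    if cfg is None:
        cfg = WaveletConfig()
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    coeffs = dwt_decompose(signal, cfg)
    soft = cfg.threshold_rule == "universal_soft"
    out = [np.zeros_like(coeffs[0]) if cfg.drop_approximation else coeffs[0]]
    for detail in coeffs[1:]:
        sigma = np.median(np.abs(detail)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
        if thr > 0:
            detail = pywt.threshold(detail, thr,
                                    mode="soft" if soft else "hard")
        out.append(detail)
    rec = pywt.waverec(out, cfg.wavelet_id, mode=cfg.mode)
    return rec[:n]
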