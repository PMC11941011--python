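"""Image-quality metrics used to validate the enhanced renderings:
SSIM, PSNR, Shannon entropy and the relative entropy difference.

SSIM and PSNR delegate to scikit-image; colour images are reported on the
luminance channel (Y of XYZ) by default, with per-channel values available.
The "entropy difference" is the relative difference of the two images'
histogram entropies, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from .colorimetry import ContractError, srgb_to_xyz

__all__ = ["MetricReport", "ssim", "psnr", "entropy_bits", "entropy_diff_pct", "compute_report"]

PSNR_CAP_DB = 100.0


@dataclass
class MetricReport:
    rmse: float
    ssim: float
    psnr_db: float
    entropy_bits_ref: float
    entropy_bits_test: float
    entropy_diff_pct: float
    ssim_per_channel: tuple[float, ...] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _luminance(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        return srgb_to_xyz(img)[..., 1] / 100.0
    raise ContractError("expected a 2D image or an (H, W, 3) image")


def ssim(
    img_a: np.ndarray,
    img_b: np.ndarray,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float = 1.0,
    on_luminance: bool = True,
    gaussian: bool = True,
) -> float:
    """Mean structural similarity (Gaussian 11x11 window by default)."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("images must share a shape")
    if a.ndim == 3 and on_luminance:
        a, b = _luminance(a), _luminance(b)
    kwargs = dict(
        win_size=window,
        gaussian_weights=gaussian,
        sigma=1.5,
        use_sample_covariance=False,
        K1=k1,
        K2=k2,
        data_range=dynamic_range,
    )
    if a.ndim == 3:
        return float(structural_similarity(a, b, channel_axis=2, **kwargs))
    return float(structural_similarity(a, b, **kwargs))


def ssim_per_channel(img_a: np.ndarray, img_b: np.ndarray, **kwargs) -> tuple[float, ...]:
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ContractError("expected two colour images of equal shape")
    return tuple(
        ssim(a[..., c], b[..., c], on_luminance=False, **kwargs) for c in range(a.shape[2])
    )


def psnr(img_a: np.ndarray, img_b: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, capped for identical images."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("images must share a shape")
    if np.array_equal(a, b):
        return PSNR_CAP_DB
    return float(min(peak_signal_noise_ratio(a, b, data_range=peak), PSNR_CAP_DB))


def rmse(img_a: np.ndarray, img_b: np.ndarray) -> float:
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("images must share a shape")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def entropy_bits(img: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram over [0, 1]."""
    v = np.asarray(img, dtype=float).ravel()
    if v.size == 0:
        raise ContractError("empty image")
    hist, _ = np.histogram(np.clip(v, 0.0, 1.0), bins=n_bins, range=(0.0, 1.0))
    p = hist[hist > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def entropy_diff_pct(img_a: np.ndarray, img_b: np.ndarray, n_bins: int = 256) -> float:
    """Relative entropy difference |H(A) - H(B)| / H(A) in percent."""
    ha = entropy_bits(img_a, n_bins)
    hb = entropy_bits(img_b, n_bins)
    if ha == 0:
        return 0.0 if hb == 0 else float("inf")
    return float(abs(ha - hb) / ha * 100.0)


def compute_report(reference: np.ndarray, test: np.ndarray) -> MetricReport:
    """Full metric panel between a reference image and a test image."""
    per_channel = None
    if np.asarray(reference).ndim == 3:
        per_channel = ssim_per_channel(reference, test)
    return MetricReport(
        rmse=rmse(reference, test),
        ssim=ssim(reference, test),
        psnr_db=psnr(reference, test),
        entropy_bits_ref=entropy_bits(reference),
        entropy_bits_test=entropy_bits(test),
        entropy_diff_pct=entropy_diff_pct(reference, test),
        ssim_per_channel=per_channel,
    )
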