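"""Full-reference image quality: SSIM, pixel-domain VIF, skip-factor curves.

Pulse-skip decimation throws away image rows; these metrics quantify how
much structure and information survive.  The reference is always the
image at skip factor 1; decimated images are brought back to the
reference row count by nearest-row replication (not interpolation) so
the comparison isolates the information lost to decimation rather than
mixing in an interpolator.

SSIM follows the standard luminance/contrast/structure product over
sliding Gaussian-weighted local windows.  VIF is the pixel-domain
multi-scale Gaussian-scale-mixture formulation: at each of four scales
the visual information of the distorted image relative to the reference
is the ratio of two channel mutual informations under an additive
neural-noise model (variance ``sigma_n²``); identical images give 1 by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d
from scipy.signal import convolve2d

__all__ = ["QualityCurve", "ssim", "vif", "skip_quality_curve"]


@dataclass
class QualityCurve:
    skip_factors: list[int]
    ssim: list[float]
    vif: list[float]
    reference_skip: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"skip": self.skip_factors,
                             "ssim": self.ssim, "vif": self.vif})


def _gaussian_kernel(radius: int, sigma: float) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def ssim(image: np.ndarray, reference: np.ndarray, window: int = 7,
         k1: float = 0.01, k2: float = 0.03, dynamic_range: float = 255.0,
         gaussian: bool = True, sigma: float = 1.5) -> float:
    """Mean structural similarity between ``image`` and ``reference``.

    Local means/variances/covariance are taken over a sliding window of
    ``window`` pixels (Gaussian-weighted with the given sigma by
    default; uniform if ``gaussian=False``), the SSIM map is the usual
    ``((2 mu_x mu_y + C1)(2 cov + C2)) / ((mu_x² + mu_y² + C1)
    (var_x + var_y + C2))`` with ``C_i = (k_i L)²``, and edge pixels
    without a full window are cropped before averaging.
    """
    x = np.asarray(image, dtype=np.float64)
    y = np.asarray(reference, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("image and reference shapes differ")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    radius = (window - 1) // 2
    if min(x.shape) < window:
        raise ValueError("image smaller than the local window")

    if gaussian:
        kern = _gaussian_kernel(radius, sigma)
    else:
        kern = np.full(window, 1.0 / window)

    def smooth(a: np.ndarray) -> np.ndarray:
        return correlate1d(correlate1d(a, kern, axis=0, mode="nearest"),
                           kern, axis=1, mode="nearest")

    mu_x, mu_y = smooth(x), smooth(y)
    var_x = smooth(x * x) - mu_x**2
    var_y = smooth(y * y) - mu_y**2
    cov = smooth(x * y) - mu_x * mu_y
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    core = ssim_map[radius:-radius or None, radius:-radius or None]
    return float(core.mean())


def _local_stats(x: np.ndarray, y: np.ndarray, win: int, sigma: float):
    k1d = _gaussian_kernel((win - 1) // 2, sigma)
    kern = np.outer(k1d, k1d)

    def f(a):
        return convolve2d(a, kern, mode="valid")

    mu_x, mu_y = f(x), f(y)
    var_x = f(x * x) - mu_x**2
    var_y = f(y * y) - mu_y**2
    cov = f(x * y) - mu_x * mu_y
    return mu_x, mu_y, np.maximum(var_x, 0), np.maximum(var_y, 0), cov


def vif(image: np.ndarray, reference: np.ndarray, levels: int = 4,
        sigma_n_sq: float = 2.0) -> float:
    """Pixel-domain visual information fidelity of ``image`` w.r.t.
    ``reference`` over ``levels`` dyadic scales.

    Per scale, the reference is modeled locally as a Gaussian scale
    mixture and the distorted image as a gain ``g`` times the reference
    plus independent noise ``sv²``; both channels pass through additive
    observation noise ``sigma_n²``.  VIF is the summed
    ``log10(1 + g² var_ref / (sv² + sigma_n²))`` over the summed
    ``log10(1 + var_ref / sigma_n²)``.
    """
    x = np.asarray(image, dtype=np.float64)
    y = np.asarray(reference, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("image and reference shapes differ")
    if y.std() == 0:
        raise ValueError("reference has zero variance; VIF undefined")
    eps = 1e-10
    num = den = 0.0
    for level in range(1, levels + 1):
        win = 2 ** (levels - level + 1) + 1
        sigma = win / 5.0
        if level > 1:
            k1d = _gaussian_kernel((win - 1) // 2, sigma)
            kern = np.outer(k1d, k1d)
            x = convolve2d(x, kern, mode="valid")[::2, ::2]
            y = convolve2d(y, kern, mode="valid")[::2, ::2]
        if min(x.shape) < win:
            raise ValueError("image too small for the requested scale count")
        _, _, var_x, var_y, cov = _local_stats(x, y, win, sigma)
        # channel gain and residual noise of the distortion model
        g = cov / (var_y + eps)
        sv_sq = var_x - g * cov
        g[var_y < eps] = 0.0
        sv_sq[var_y < eps] = var_x[var_y < eps]
        sv_sq = np.maximum(sv_sq, eps)
        g = np.maximum(g, 0.0)
        num += float(np.log10(1.0 + g**2 * var_y / (sv_sq + sigma_n_sq)).sum())
        den += float(np.log10(1.0 + var_y / sigma_n_sq).sum())
    return num / den


def skip_quality_curve(reference: np.ndarray, skip_factors: list[int],
                       vif_levels: int = 4) -> QualityCurve:
    """SSIM/VIF versus skip factor against the skip-1 reference image.

    For each factor ``k`` the reference rows are decimated (keep one row
    in ``k``) and restored to the original row count by nearest-row
    replication before computing both metrics.
    """
    ref = np.asarray(reference, dtype=np.float64)
    n_rows = ref.shape[0]
    ssim_vals: list[float] = []
    vif_vals: list[float] = []
    for k in skip_factors:
        if k < 1 or k > n_rows:
            raise ValueError(f"skip factor {k} out of range for {n_rows} rows")
        dec = ref[::k]
        up = np.repeat(dec, k, axis=0)[:n_rows]
        ssim_vals.append(ssim(up, ref))
        vif_vals.append(vif(up, ref, levels=vif_levels))
    return QualityCurve(list(skip_factors), ssim_vals, vif_vals, reference_skip=1)
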