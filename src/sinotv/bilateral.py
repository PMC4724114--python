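"""Bilateral-filter baseline for projection denoising.

The comparator method: each pixel is replaced by a normalized weighted
average of its w x w neighbourhood, with a spatial Gaussian weight
exp(-(k-k')^2 / 2d^2) and a range Gaussian weight exp(-(v_k-v_k')^2 /
2 sigma_eff^2).  Because the weights are nonnegative and normalized, the
output is a convex combination of window values and the maximum principle
holds exactly.

The published parameterization quotes sigma values of order 1, far below the
count-scale noise of a low-dose sinogram, so by default sigma is interpreted
in local Poisson standard-deviation units: sigma_eff = sigma * sqrt(local
mean count).  An absolute mode is provided for raw comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter


@dataclass(frozen=True)
class BilateralConfig:
    """w: odd window length (default 5); d: spatial scale (default w/6);
    sigma: range scale; sigma_mode: "noise-normalized" or "absolute"."""

    sigma: float
    w: int = 5
    d: float = None  # type: ignore[assignment]
    sigma_mode: str = "noise-normalized"

    def __post_init__(self):
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError("filter length w must be odd and >= 3")
        if self.d is None:
            object.__setattr__(self, "d", self.w / 6.0)
        if self.d <= 0 or self.sigma <= 0:
            raise ValueError("d and sigma must be positive")
        if self.sigma_mode not in ("noise-normalized", "absolute"):
            raise ValueError("sigma_mode must be 'noise-normalized' or 'absolute'")


def bilateral_denoise(v: np.ndarray, config: BilateralConfig) -> np.ndarray:
    """Bilateral filtering of a 2-D image.

    Windows are clipped at image borders (weights renormalize over the valid
    neighbours).  In "noise-normalized" mode the range scale at pixel k is
    ``sigma * sqrt(mean count in the w x w window around k)``.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise ValueError("input must be 2-D")
    if not np.all(np.isfinite(v)):
        raise ValueError("input contains non-finite values")
    r = config.w // 2
    if config.sigma_mode == "absolute":
        sigma_eff = np.full(v.shape, config.sigma)
    else:
        local_mean = uniform_filter(v, size=config.w, mode="reflect")
        sigma_eff = config.sigma * np.sqrt(np.maximum(local_mean, 1e-12))

    num = np.zeros_like(v)
    den = np.zeros_like(v)
    rows, cols = v.shape
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            gs = np.exp(-(di * di + dj * dj) / (2.0 * config.d**2))
            # overlap of the image with itself shifted by (di, dj)
            sr0, sr1 = max(di, 0), rows + min(di, 0)
            sc0, sc1 = max(dj, 0), cols + min(dj, 0)
            center = (slice(sr0, sr1), slice(sc0, sc1))
            neigh = (slice(sr0 - di, sr1 - di), slice(sc0 - dj, sc1 - dj))
            diff = v[center] - v[neigh]
            wgt = gs * np.exp(-(diff**2) / (2.0 * sigma_eff[center] ** 2))
            num[center] += wgt * v[neigh]
            den[center] += wgt
    return num / den
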