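"""Image-quality measures and a minimal 2-D reconstruction.

Provides RMSE, histogram-based normalized mutual information, the global
SSIM statistic, a mean-ROI-standard-deviation noise measure, a maximum
line-gradient resolution proxy, and a parallel-beam filtered backprojection
for image-domain checks.

Standard-deviation convention is population (denominator n) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import iradon


@dataclass
class MetricReport:
    """Quality measures for one denoised result (plus parameters used)."""

    method: str
    parameter: float
    rmse: float
    mutual_information: float | None = None
    ssim: float | None = None
    noise_level: float | None = None
    resolution_proxy: float | None = None
    optimal: bool = False

    def to_dict(self):
        return asdict(self)


def _check_shapes(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def rmse(x, reference) -> float:
    """Root-mean-square difference between two equal-shape arrays."""
    x, ref = _check_shapes(x, reference)
    return float(np.sqrt(np.mean((x - ref) ** 2)))


def mutual_information(x, reference, n_bins: int = 256, normalized: bool = True) -> float:
    """Histogram-estimated mutual information, optionally self-normalized.

    Joint and marginal densities are estimated with ``n_bins`` equal-width
    bins spanning the pooled min-max range of both inputs; the result is
    divided by MI(reference, reference) — the histogram entropy of the
    reference — so a perfect match scores exactly 1.

    Raises ``ValueError`` for a constant reference (zero self-information).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    x, ref = _check_shapes(x, reference)
    lo = min(x.min(), ref.min())
    hi = max(x.max(), ref.max())
    if hi == lo:
        hi = lo + 1.0  # both constant: degenerate but well-defined joint
    edges = np.linspace(lo, hi, n_bins + 1)
    joint, _, _ = np.histogram2d(ref.ravel(), x.ravel(), bins=(edges, edges))
    pj = joint / joint.sum()
    pr = pj.sum(axis=1)
    px = pj.sum(axis=0)
    nz = pj > 0
    mi = float((pj[nz] * np.log(pj[nz] / np.outer(pr, px)[nz])).sum())
    if not normalized:
        return mi
    nzr = pr > 0
    self_mi = float(-(pr[nzr] * np.log(pr[nzr])).sum())
    if self_mi == 0.0:
        raise ValueError("constant reference: normalized MI is undefined")
    return mi / self_mi


def ssim(x, x_hat, c1: float | None = None, c2: float | None = None) -> float:
    """Global structural-similarity statistic.

    Evaluated from whole-image means, population standard deviations and
    covariance:

        SSIM = (2 mu_x mu_x' + C1)(2 cov + C2)
               / ((mu_x^2 + mu_x'^2 + C1)(var_x + var_x' + C2))

    Defaults: C1 = (0.01 L)^2, C2 = (0.03 L)^2 with L the dynamic range of
    the first argument (the reference).
    """
    x, xh = _check_shapes(x, x_hat)
    if c1 is None or c2 is None:
        rng = float(x.max() - x.min())
        if rng == 0.0:
            rng = 1.0
        c1 = (0.01 * rng) ** 2 if c1 is None else c1
        c2 = (0.03 * rng) ** 2 if c2 is None else c2
    mx, mh = x.mean(), xh.mean()
    vx, vh = x.var(), xh.var()
    cov = ((x - mx) * (xh - mh)).mean()
    return float(
        ((2 * mx * mh + c1) * (2 * cov + c2))
        / ((mx**2 + mh**2 + c1) * (vx + vh + c2))
    )


def noise_level(image, rois) -> float:
    """Mean over ROIs of the per-ROI population standard deviation.

    ``rois`` is a list of half-open 0-based rectangles (r0, r1, c0, c1).
    """
    img = np.asarray(image, dtype=float)
    rois = list(rois)
    if not rois:
        raise ValueError("at least one ROI is required")
    stds = []
    for r0, r1, c0, c1 in rois:
        if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
            raise ValueError(f"ROI {(r0, r1, c0, c1)} outside image bounds {img.shape}")
        stds.append(img[r0:r1, c0:c1].std())
    return float(np.mean(stds))


def resolution_proxy(image, line) -> float:
    """Maximum absolute slope along a line segment, as a resolution measure.

    ``line`` is ((r0, c0), (r1, c1)) in pixel coordinates; the image is
    sampled along the segment at unit-pixel spacing with bilinear
    interpolation and the maximum absolute first difference returned.
    """
    img = np.asarray(image, dtype=float)
    (r0, c0), (r1, c1) = line
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0.0:
        raise ValueError("line must have nonzero length")
    n = int(np.floor(length)) + 1
    # unit-pixel spacing along the segment direction
    rows = r0 + (r1 - r0) / length * np.arange(n)
    cols = c0 + (c1 - c0) / length * np.arange(n)
    profile = map_coordinates(img, np.stack([rows, cols]), order=1)
    if profile.size < 2:
        raise ValueError("line too short to estimate a slope")
    return float(np.max(np.abs(np.diff(profile))))


def fbp2d(sinogram, geometry, output_size: int | None = None, pixel_pitch: float | None = None):
    """Ramp-filtered backprojection of a parallel-beam sinogram.

    Thin wrapper over ``skimage.transform.iradon``; the sinogram (one row per
    view, in dimensionless mm line-integral units) is rescaled by the pixel
    pitch so the reconstruction comes out in attenuation per mm.  Cone/fan
    sinograms are not supported here.
    """
    values = getattr(sinogram, "values", sinogram)
    values = np.asarray(values, dtype=float)
    if geometry.mode != "parallel":
        raise ValueError("fbp2d supports parallel-beam geometry only")
    if len(geometry.angles_deg) < 2:
        raise ValueError("at least two view angles are required")
    pitch = geometry.det_pitch if pixel_pitch is None else pixel_pitch
    recon = iradon(
        values.T / pitch,
        theta=np.asarray(geometry.angles_deg, dtype=float),
        output_size=output_size or geometry.n_det,
        filter_name="ramp",
        circle=False,
    )
    return recon
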