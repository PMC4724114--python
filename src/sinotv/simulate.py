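"""Projection simulation: ellipse phantoms, ray integration, Poisson counts.

Stands in for scanner data in all tests.  A phantom is a list of ellipses
with additive attenuation values (the classic Shepp-Logan head layout is
provided); its line integrals are computed by sampled ray marching, and the
detected photon counts follow the Beer-Lambert / Poisson model

    N_d ~ Poisson( N0 * exp(-integral of mu ds) )

with constant incident flux N0 across rays (no bowtie filtration) and
independent pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass(frozen=True)
class Ellipse:
    """One additive-attenuation ellipse.

    value : additive attenuation inside the ellipse (1/mm)
    center : (x, y) in mm, y pointing up, origin at the rotation axis
    semi_axes : (a, b) in mm along the ellipse's own x/y axes
    angle_deg : counter-clockwise rotation of the ellipse
    """

    value: float
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float = 0.0

    def __post_init__(self):
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class ImageGrid:
    """Square-pixel raster: ``shape`` = (rows, cols), ``pitch`` in mm."""

    shape: tuple[int, int]
    pitch: float = 1.0

    def __post_init__(self):
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    def pixel_centers(self):
        """(x, y) mm coordinates of every pixel centre (meshgrids)."""
        rows, cols = self.shape
        x = (np.arange(cols) - (cols - 1) / 2.0) * self.pitch
        y = ((rows - 1) / 2.0 - np.arange(rows)) * self.pitch
        return np.meshgrid(x, y)

    def xy_to_rowcol(self, x, y):
        """Continuous (row, col) raster coordinates of mm points."""
        rows, cols = self.shape
        col = x / self.pitch + (cols - 1) / 2.0
        row = (rows - 1) / 2.0 - y / self.pitch
        return row, col


@dataclass(frozen=True)
class PhantomImage:
    """Rasterized ellipse phantom together with its analytic description."""

    values: np.ndarray
    grid: ImageGrid
    ellipses: tuple[Ellipse, ...] = ()


@dataclass(frozen=True)
class ScanGeometry:
    """Ray layout of one scan.

    mode : "parallel" or "cone" (a 2-D cone scan is a fan geometry)
    angles_deg : strictly increasing view angles
    n_det, det_pitch : detector bin count and pitch (mm)
    sdd, sad : source-to-detector / source-to-axis distances (mm, cone only);
        defaults are the micro-CT scanner distances 449.29 / 397.04 mm.
    """

    mode: str
    angles_deg: tuple[float, ...]
    n_det: int
    det_pitch: float = 1.0
    sdd: float | None = None
    sad: float | None = None

    def __post_init__(self):
        if self.mode not in ("parallel", "cone"):
            raise ValueError("mode must be 'parallel' or 'cone'")
        ang = np.asarray(self.angles_deg, dtype=float)
        if ang.size == 0 or np.any(np.diff(ang) <= 0):
            raise ValueError("angles must be a strictly increasing, non-empty list")
        if self.n_det <= 0 or self.det_pitch <= 0:
            raise ValueError("detector parameters must be positive")
        if self.mode == "cone":
            sdd = 449.29 if self.sdd is None else self.sdd
            sad = 397.04 if self.sad is None else self.sad
            if sdd <= 0 or sad <= 0:
                raise ValueError("source distances must be positive")
            object.__setattr__(self, "sdd", sdd)
            object.__setattr__(self, "sad", sad)


@dataclass(frozen=True)
class LineIntegralSinogram:
    """Noise-free line integrals (dimensionless), one row per view."""

    values: np.ndarray
    geometry: ScanGeometry


@dataclass(frozen=True)
class CountSinogram:
    """Detected photon counts, one row per view, plus the sampling metadata."""

    values: np.ndarray
    n0: float
    seed: int
    geometry: ScanGeometry | None = None


# Modified Shepp-Logan head phantom: relative additive values and geometry in
# units of the half-field-of-view (Toft's standard table).
_SHEPP_LOGAN_RELATIVE = (
    # (value, a, b, x0, y0, phi_deg)
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6050, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def shepp_logan_ellipses(fov_mm: float = 180.0, mu_scale: float = 0.1) -> list[Ellipse]:
    """Modified Shepp-Logan head phantom scaled to physical units.

    ``fov_mm`` is the full field of view spanned by the relative coordinates
    [-1, 1]; ``mu_scale`` (1/mm) converts the relative additive values to
    attenuation coefficients.  The defaults (180 mm head, 0.1/mm per relative
    unit, i.e. soft-tissue composite ~0.02/mm, skull 0.1/mm) give peak line
    integrals of about 4.5, so the expected counts at N0 = 500 span roughly
    5-500: a genuinely low-dose regime.
    """
    half = fov_mm / 2.0
    return [
        Ellipse(
            value=v * mu_scale,
            center=(x0 * half, y0 * half),
            semi_axes=(a * half, b * half),
            angle_deg=phi,
        )
        for v, a, b, x0, y0, phi in _SHEPP_LOGAN_RELATIVE
    ]


def _ellipse_values_at(ellipses, x, y):
    """Summed additive attenuation at mm points (x, y) (vectorized)."""
    total = np.zeros(np.broadcast(x, y).shape)
    for e in ellipses:
        phi = np.deg2rad(e.angle_deg)
        dx, dy = x - e.center[0], y - e.center[1]
        xr = np.cos(phi) * dx + np.sin(phi) * dy
        yr = -np.sin(phi) * dx + np.cos(phi) * dy
        inside = (xr / e.semi_axes[0]) ** 2 + (yr / e.semi_axes[1]) ** 2 <= 1.0
        total += np.where(inside, e.value, 0.0)
    return total


def rasterize_phantom(ellipses, grid: ImageGrid) -> PhantomImage:
    """Raster of summed ellipse attenuations at pixel centres (deterministic)."""
    x, y = grid.pixel_centers()
    values = _ellipse_values_at(tuple(ellipses), x, y)
    # summation round-off can leave ~1e-17 negatives where values cancel
    values[(values < 0) & (values > -1e-9)] = 0.0
    return PhantomImage(values=values, grid=grid, ellipses=tuple(ellipses))


def project(phantom: PhantomImage, geometry: ScanGeometry) -> LineIntegralSinogram:
    """Line integrals of the rasterized phantom along the scan's rays.

    Sampled accumulation with step = half the voxel pitch and bilinear
    interpolation of the raster; rays missing the grid integrate to zero.
    Negative sums arising from interpolation round-off are clipped at 0.
    """
    values = np.asarray(phantom.values, dtype=float)
    grid = phantom.grid
    step = grid.pitch / 2.0
    half_span = 0.5 * np.hypot(*[(n - 1) * grid.pitch for n in grid.shape]) + grid.pitch
    t = (np.arange(geometry.n_det) - (geometry.n_det - 1) / 2.0) * geometry.det_pitch

    sino = np.zeros((len(geometry.angles_deg), geometry.n_det))
    for k, ang in enumerate(geometry.angles_deg):
        th = np.deg2rad(ang)
        if geometry.mode == "parallel":
            n_s = int(np.ceil(2 * half_span / step)) + 1
            s = np.linspace(-half_span, half_span, n_s)
            ds = s[1] - s[0]
            # detector axis (cos, sin); ray direction (-sin, cos)
            x = t[:, None] * np.cos(th) - s[None, :] * np.sin(th)
            y = t[:, None] * np.sin(th) + s[None, :] * np.cos(th)
        else:  # fan ("cone" in 2-D)
            src = np.array([-geometry.sad * np.sin(th), geometry.sad * np.cos(th)])
            det_c = src - (geometry.sdd / geometry.sad) * src  # centre of detector
            e_t = np.array([np.cos(th), np.sin(th)])
            det_pts = det_c[None, :] + t[:, None] * e_t[None, :]
            ray = det_pts - src[None, :]
            length = np.linalg.norm(ray, axis=1)
            n_s = int(np.ceil(length.max() / step)) + 1
            frac = np.linspace(0.0, 1.0, n_s)
            ds = length[:, None] / (n_s - 1)
            x = src[0] + frac[None, :] * ray[:, 0:1]
            y = src[1] + frac[None, :] * ray[:, 1:2]
        row, col = grid.xy_to_rowcol(x, y)
        samples = map_coordinates(
            values, np.stack([row.ravel(), col.ravel()]), order=1, cval=0.0
        ).reshape(x.shape)
        sino[k] = np.clip((samples * np.broadcast_to(ds, x.shape)).sum(axis=1), 0.0, None)
    return LineIntegralSinogram(values=sino, geometry=geometry)


def apply_poisson(line_integrals, n0: float, seed: int) -> CountSinogram:
    """Draw Poisson counts with mean N0*exp(-line integral).

    A single integer seed determines all draws; each view (row) uses a
    substream keyed by its index, so per-view results are independent of the
    order in which views are simulated.
    """
    if n0 <= 0:
        raise ValueError("N0 must be positive")
    geometry = None
    if isinstance(line_integrals, LineIntegralSinogram):
        geometry = line_integrals.geometry
        line_integrals = line_integrals.values
    li = np.asarray(line_integrals, dtype=float)
    if np.any(li < 0):
        raise ValueError("line integrals cannot be negative")
    mean = n0 * np.exp(-li)
    counts = np.empty(li.shape, dtype=np.int64)
    if li.ndim == 1:
        counts[:] = np.random.default_rng([int(seed), 0]).poisson(mean)
    else:
        for k in range(li.shape[0]):
            counts[k] = np.random.default_rng([int(seed), k]).poisson(mean[k])
    return CountSinogram(values=counts, n0=n0, seed=int(seed), geometry=geometry)
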