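"""Weighted structure-tensor orientation and coherency analysis.

The local texture orientation of a 2D image is obtained from the 2x2
structure tensor

    J = [[<fx,fx>_w, <fx,fy>_w],
         [<fx,fy>_w, <fy,fy>_w]]

where the inner products are weighted sums over a window w.  The
eigenvector of the largest eigenvalue is the *gradient-dominant* axis
(the axis maximizing the windowed directional-derivative energy
``u^T J u``); for fibrous textures the fibers run perpendicular to it,
so the reported ``theta_deg`` is that axis rotated by 90 degrees.
Coherency C = (lmax - lmin)/(lmax + lmin) is 1 for a perfectly
oriented texture and 0 for an isotropic one.

A brute-force angle sweep of ``u^T J u`` (direct weighted summation of
squared directional derivatives, no eigendecomposition) is provided as
an independent oracle for the eigen route.

Angles follow the package convention: axial degrees in [-90, 90),
counter-clockwise from +x, with images stored y-up (see
:mod:`radialign.image`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Image2D, wrap_axial_deg


@dataclass(frozen=True)
class WeightWindow:
    """Square analysis window of side ``size_L`` centered at ``center``.

    ``center`` is (x0, y0) in y-up pixel coordinates.  ``profile`` is
    ``"box"`` (uniform weights, the default) or ``"gaussian"``
    (sigma = L/4, truncated at the window edge).
    """

    center: tuple[float, float]
    size_L: int
    profile: str = "box"

    def __post_init__(self) -> None:
        if self.size_L < 1:
            raise ValueError("size_L must be >= 1")
        if self.profile not in ("box", "gaussian"):
            raise ValueError(f"unknown window profile {self.profile!r}")

    def bounds(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Clipped (row0, row1, col0, col1) of the window in an image."""
        x0, y0 = self.center
        half = self.size_L / 2.0
        r0 = int(np.ceil(y0 - half))
        r1 = int(np.floor(y0 + half)) + 1
        c0 = int(np.ceil(x0 - half))
        c1 = int(np.floor(x0 + half)) + 1
        r0c, r1c = max(r0, 0), min(r1, shape[0])
        c0c, c1c = max(c0, 0), min(c1, shape[1])
        if r0c >= r1c or c0c >= c1c:
            raise ValueError(
                f"window centered at {self.center} (L={self.size_L}) "
                f"does not intersect image of shape {shape}"
            )
        return r0c, r1c, c0c, c1c

    def weights(self, shape: tuple[int, int]) -> tuple[np.ndarray, tuple[int, int, int, int]]:
        """Nonnegative weight patch and its bounds."""
        r0, r1, c0, c1 = self.bounds(shape)
        if self.profile == "box":
            w = np.ones((r1 - r0, c1 - c0), dtype=float)
        else:
            x0, y0 = self.center
            yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
            sigma = self.size_L / 4.0
            w = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))
        return w, (r0, r1, c0, c1)


@dataclass(frozen=True)
class GradientField:
    """Gaussian-derivative gradient estimates (y-up: fy increases with y)."""

    fx: np.ndarray
    fy: np.ndarray
    derivative_scale_sigma: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.fx.shape


@dataclass(frozen=True)
class StructureTensor:
    """Weighted gradient inner products; symmetric positive semi-definite."""

    jxx: float
    jxy: float
    jyy: float

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.jxx, self.jxy], [self.jxy, self.jyy]])

    @property
    def energy(self) -> float:
        return self.jxx + self.jyy


@dataclass(frozen=True)
class OrientationResult:
    """Per-window orientation read-out.

    ``theta_deg`` is the fiber axis in [-90, 90) (NaN when invalid);
    ``gradient_axis_deg`` is the raw dominant-gradient axis.
    ``valid`` is False when the window energy falls below threshold or
    the tensor is isotropic (lmax == lmin), in which case coherency is
    reported as 0 and theta as NaN.
    """

    theta_deg: float
    coherency: float
    energy: float
    lambda_max: float
    lambda_min: float
    valid: bool
    gradient_axis_deg: float = float("nan")
    center: tuple[float, float] | None = None


def compute_gradients(image: Image2D, sigma: float = 1.5) -> GradientField:
    """Gaussian-derivative estimates of df/dx and df/dy.

    Boundaries are handled by reflection.  ``sigma`` is the derivative
    scale in pixels.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v = image.values
    support = int(4 * sigma) + 1
    if min(v.shape) < support:
        raise ValueError(
            f"image {v.shape} smaller than kernel support ({support} px) "
            f"for sigma={sigma}"
        )
    fx = ndimage.gaussian_filter(v, sigma, order=(0, 1), mode="reflect")
    fy = ndimage.gaussian_filter(v, sigma, order=(1, 0), mode="reflect")
    return GradientField(fx=fx, fy=fy, derivative_scale_sigma=sigma)


def structure_tensor(grad: GradientField, window: WeightWindow) -> StructureTensor:
    """Weighted inner products of the gradient components over a window."""
    w, (r0, r1, c0, c1) = window.weights(grad.shape)
    fx = grad.fx[r0:r1, c0:c1]
    fy = grad.fy[r0:r1, c0:c1]
    jxx = float(np.sum(w * fx * fx))
    jxy = float(np.sum(w * fx * fy))
    jyy = float(np.sum(w * fy * fy))
    return StructureTensor(jxx=jxx, jxy=jxy, jyy=jyy)


def orientation_coherency(
    J: StructureTensor,
    energy_threshold: float = 0.0,
    center: tuple[float, float] | None = None,
) -> OrientationResult:
    """Eigen-analysis of the structure tensor.

    lmax/lmin are computed in closed form for the symmetric 2x2 case.
    The gradient-dominant axis is the lmax eigenvector; the reported
    fiber axis is that axis + 90 degrees.  Below ``energy_threshold``
    (or for an isotropic tensor) the result is flagged invalid with
    coherency 0 and theta NaN — never a fabricated angle.
    """
    mean = 0.5 * (J.jxx + J.jyy)
    half_diff = 0.5 * (J.jxx - J.jyy)
    disc = float(np.hypot(half_diff, J.jxy))
    lmax = mean + disc
    lmin = mean - disc
    energy = J.energy
    if energy <= energy_threshold or energy <= 0.0 or lmax + lmin <= 0.0:
        return OrientationResult(
            theta_deg=float("nan"), coherency=0.0, energy=energy,
            lambda_max=lmax, lambda_min=lmin, valid=False, center=center,
        )
    coherency = (lmax - lmin) / (lmax + lmin)
    if disc == 0.0:
        # isotropic tensor: orientation undefined
        return OrientationResult(
            theta_deg=float("nan"), coherency=0.0, energy=energy,
            lambda_max=lmax, lambda_min=lmin, valid=False, center=center,
        )
    grad_axis = float(np.degrees(0.5 * np.arctan2(2.0 * J.jxy, J.jxx - J.jyy)))
    grad_axis = float(wrap_axial_deg(grad_axis))
    theta = float(wrap_axial_deg(grad_axis + 90.0))
    return OrientationResult(
        theta_deg=theta, coherency=float(coherency), energy=energy,
        lambda_max=lmax, lambda_min=lmin, valid=True,
        gradient_axis_deg=grad_axis, center=center,
    )


@dataclass(frozen=True)
class DirectionSweep:
    """Output of the brute-force directional-energy sweep."""

    angles_deg: np.ndarray  # probe axes in [0, 180)
    energies: np.ndarray    # ||D_u f||^2_w at each probe axis
    argmax_axis_deg: float  # gradient-dominant axis (axial, [-90, 90))
    max_energy: float


def dominant_direction_bruteforce(
    image: Image2D,
    window: WeightWindow,
    angle_step_deg: float = 0.5,
    sigma: float = 1.5,
) -> DirectionSweep:
    """Arg-max of the windowed directional-derivative energy.

    Sweeps the probe axis over [0, 180) in ``angle_step_deg`` steps and
    evaluates ``||D_u f||^2_w`` by direct weighted summation of squared
    directional derivatives (never via eigendecomposition), serving as
    an independent oracle for :func:`orientation_coherency`.  Returns
    the gradient-dominant axis; the fiber axis is 90 degrees away.
    """
    if angle_step_deg <= 0:
        raise ValueError("angle_step_deg must be positive")
    grad = compute_gradients(image, sigma=sigma)
    w, (r0, r1, c0, c1) = window.weights(grad.shape)
    fx = grad.fx[r0:r1, c0:c1]
    fy = grad.fy[r0:r1, c0:c1]
    angles = np.arange(0.0, 180.0, angle_step_deg)
    rad = np.radians(angles)
    energies = np.empty_like(angles)
    for i, a in enumerate(rad):
        du = np.cos(a) * fx + np.sin(a) * fy
        energies[i] = np.sum(w * du * du)
    best = int(np.argmax(energies))
    return DirectionSweep(
        angles_deg=angles,
        energies=energies,
        argmax_axis_deg=float(wrap_axial_deg(angles[best])),
        max_energy=float(energies[best]),
    )


def directional_energy(
    image: Image2D,
    window: WeightWindow,
    angle_deg: float,
    sigma: float = 1.5,
) -> float:
    """``||D_u f||^2_w`` at one probe axis, by direct weighted summation.

    Used to verify the Rayleigh-quotient identity: evaluated at the
    eigen axis it must equal lambda_max.
    """
    grad = compute_gradients(image, sigma=sigma)
    w, (r0, r1, c0, c1) = window.weights(grad.shape)
    a = np.radians(angle_deg)
    du = np.cos(a) * grad.fx[r0:r1, c0:c1] + np.sin(a) * grad.fy[r0:r1, c0:c1]
    return float(np.sum(w * du * du))


@dataclass(frozen=True)
class OrientationMap:
    """Tiled per-window orientation results over an image.

    ``centers_x``/``centers_y`` are the window centers (y-up pixels);
    all per-tile arrays share the tile-grid shape.
    """

    centers_x: np.ndarray
    centers_y: np.ndarray
    theta_deg: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray
    valid: np.ndarray
    window_size_L: int
    stride: int

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


def orientation_map(
    image: Image2D,
    window_size_L: int = 16,
    stride: int | None = None,
    sigma: float = 1.5,
    energy_threshold_rel: float = 1e-3,
    profile: str = "box",
) -> OrientationMap:
    """Tile the per-window analysis across an image.

    ``energy_threshold_rel`` masks tiles whose energy is below that
    fraction of the maximum tile energy.  Requires L >= 4*sigma so the
    window dominates the derivative kernel support.
    """
    if window_size_L < 4 * sigma:
        raise ValueError(
            f"window_size_L={window_size_L} must be >= 4*sigma={4 * sigma}"
        )
    if stride is None:
        stride = window_size_L
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, wdt = image.shape
    if stride > h or stride > wdt:
        raise ValueError(f"stride {stride} exceeds image size {image.shape}")
    grad = compute_gradients(image, sigma=sigma)
    row_starts = np.arange(0, h - window_size_L + 1, stride)
    col_starts = np.arange(0, wdt - window_size_L + 1, stride)
    if len(row_starts) == 0 or len(col_starts) == 0:
        raise ValueError("window larger than image: no tiles")
    shape = (len(row_starts), len(col_starts))
    cx = np.empty(shape)
    cy = np.empty(shape)
    tensors = np.empty(shape + (3,))
    for i, rs in enumerate(row_starts):
        for j, cs in enumerate(col_starts):
            x0 = cs + (window_size_L - 1) / 2.0
            y0 = rs + (window_size_L - 1) / 2.0
            win = WeightWindow(center=(x0, y0), size_L=window_size_L, profile=profile)
            J = structure_tensor(grad, win)
            cx[i, j], cy[i, j] = x0, y0
            tensors[i, j] = (J.jxx, J.jxy, J.jyy)
    energies = tensors[..., 0] + tensors[..., 2]
    threshold = energy_threshold_rel * float(energies.max()) if energies.size else 0.0
    theta = np.full(shape, np.nan)
    coher = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            J = StructureTensor(*tensors[i, j])
            res = orientation_coherency(J, energy_threshold=threshold)
            theta[i, j] = res.theta_deg
            coher[i, j] = res.coherency
            valid[i, j] = res.valid
    return OrientationMap(
        centers_x=cx, centers_y=cy, theta_deg=theta, coherency=coher,
        energy=energies, valid=valid, window_size_L=window_size_L, stride=stride,
    )
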