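"""Seeded synthetic-image and trace generators with known ground truth.

Every generator is a pure function of its spec (including the seed):
identical inputs give bit-identical outputs.  Ground truth (sampled
angles, transient parameters) is returned alongside the artifact so
recovery error is computable exactly downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import Image2D, wrap_axial_deg

DEFAULT_STROKE_WIDTH_PX = 3.0


@dataclass(frozen=True)
class FiberFieldSpec:
    """Parameters for stripe/fiber image generators.

    ``stripe_angle_deg`` drives :func:`make_grating`;
    ``orientation_mu_deg``/``orientation_kappa``/``n_fibers`` drive
    :func:`make_fiber_field`.  ``orientation_kappa`` is the
    concentration of an *axial* von Mises distribution (kappa=0 is the
    isotropic control).
    """

    height: int = 256
    width: int = 256
    stripe_angle_deg: float = 0.0
    wavelength_px: float = 16.0
    orientation_mu_deg: float = 0.0
    orientation_kappa: float = 0.0
    n_fibers: int = 100
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 3 or self.width < 3:
            raise ValueError("image must be at least 3x3")
        if self.wavelength_px <= 2:
            raise ValueError(
                f"wavelength_px must exceed 2 px (Nyquist), got {self.wavelength_px}"
            )
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be >= 0")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -90.0 <= self.stripe_angle_deg < 90.0:
            raise ValueError("stripe_angle_deg must lie in [-90, 90)")


@dataclass(frozen=True)
class NucleiFieldSpec:
    """Parameters for the elongated-nucleus image generator.

    Non-overlap of nuclei is NOT guaranteed; centers are sampled
    uniformly and ellipses may intersect.
    """

    height: int = 256
    width: int = 256
    n_nuclei: int = 60
    axis_ratio: float = 3.0
    major_axis_px: float = 18.0
    orientation_mu_deg: float = 0.0
    orientation_kappa: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_ratio < 1:
            raise ValueError(f"axis_ratio must be >= 1, got {self.axis_ratio}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.major_axis_px <= 0:
            raise ValueError("major_axis_px must be positive")


@dataclass(frozen=True)
class FiberFieldResult:
    """Image plus the exact axial angles used to draw it."""

    image: Image2D
    angles_deg: np.ndarray


@dataclass(frozen=True)
class NucleiFieldResult:
    image: Image2D
    angles_deg: np.ndarray
    # False when axis_ratio == 1: circular nuclei carry no orientation.
    orientation_defined: bool = True


@dataclass(frozen=True)
class CalciumTrace:
    """Fluorescence time series; ``dFF0`` is attached by signal_quant."""

    time_s: np.ndarray
    F: np.ndarray
    F0: float | None = None
    dFF0: np.ndarray | None = None


def sample_axial_von_mises(
    mu_deg, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample axial angles (degrees in [-90, 90)) via angle doubling.

    Draws 2*alpha from von Mises(2*mu, kappa), halves, wraps.  kappa=0
    reduces to the uniform axial distribution.  ``mu_deg`` may be a
    scalar or an array of per-sample means of length ``n``.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    mu2 = np.radians(2.0 * np.asarray(mu_deg, dtype=float))
    if mu2.ndim > 0 and mu2.shape != (n,):
        raise ValueError(f"per-sample mu must have length {n}")
    doubled = rng.vonmises(mu2, kappa, size=n)
    return wrap_axial_deg(np.degrees(doubled) / 2.0)


def _normalize01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-300:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def make_grating(spec: FiberFieldSpec) -> Image2D:
    """Sinusoidal grating whose stripe (fiber) axis lies at
    ``spec.stripe_angle_deg``; intensity varies perpendicular to it.

    Intensity is normalized to [0, 1] before optional Gaussian noise.
    """
    y, x = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    a = np.radians(spec.stripe_angle_deg)
    # coordinate along the direction perpendicular to the stripe axis
    perp = -x * np.sin(a) + y * np.cos(a)
    img = 0.5 + 0.5 * np.cos(2.0 * np.pi * perp / spec.wavelength_px)
    img = _normalize01(img)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return Image2D(img)


def _render_stroke(
    canvas: np.ndarray,
    x0: float,
    y0: float,
    angle_deg: float,
    length: float,
    width: float,
) -> None:
    """Accumulate an anti-aliased stroke (Gaussian cross-profile segment)."""
    a = np.radians(angle_deg)
    dx, dy = np.cos(a), np.sin(a)
    hx, hy = dx * length / 2.0, dy * length / 2.0
    xa, ya, xb, yb = x0 - hx, y0 - hy, x0 + hx, y0 + hy
    pad = width + 2.0
    r0 = max(int(np.floor(min(ya, yb) - pad)), 0)
    r1 = min(int(np.ceil(max(ya, yb) + pad)) + 1, canvas.shape[0])
    c0 = max(int(np.floor(min(xa, xb) - pad)), 0)
    c1 = min(int(np.ceil(max(xa, xb) + pad)) + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
    # distance from pixel centers to the segment
    px, py = xx - xa, yy - ya
    vx, vy = xb - xa, yb - ya
    vv = vx * vx + vy * vy
    t = np.clip((px * vx + py * vy) / vv, 0.0, 1.0) if vv > 0 else 0.0
    d2 = (px - t * vx) ** 2 + (py - t * vy) ** 2
    sigma = width / 2.0
    canvas[r0:r1, c0:c1] += np.exp(-d2 / (2.0 * sigma * sigma))


def make_fiber_field(
    spec: FiberFieldSpec,
    fiber_length_px: float = 40.0,
    stroke_width_px: float = DEFAULT_STROKE_WIDTH_PX,
    radial_mu_center: tuple[float, float] | None = None,
) -> FiberFieldResult:
    """Elongated strokes with axial angles from von Mises(mu, kappa).

    kappa=0 yields the isotropic control; large kappa an oriented
    control.  When ``radial_mu_center`` (x0, y0) is given, each
    fiber's von Mises mean is the radial axial angle of its own center
    about that point (radially organized field) instead of the global
    ``orientation_mu_deg``.  Returns the sampled angles as ground
    truth.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros((spec.height, spec.width), dtype=float)
    xs = rng.uniform(0, spec.width, spec.n_fibers)
    ys = rng.uniform(0, spec.height, spec.n_fibers)
    if radial_mu_center is not None:
        cx, cy = radial_mu_center
        mu = wrap_axial_deg(np.degrees(np.arctan2(ys - cy, xs - cx)))
    else:
        mu = spec.orientation_mu_deg
    angles = sample_axial_von_mises(mu, spec.orientation_kappa, spec.n_fibers, rng)
    for x0, y0, ang in zip(xs, ys, angles):
        _render_stroke(canvas, x0, y0, ang, fiber_length_px, stroke_width_px)
    img = _normalize01(canvas)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return FiberFieldResult(image=Image2D(img), angles_deg=angles)


def make_radial_pattern(
    height: int,
    width: int,
    center: tuple[float, float] | None = None,
    n_spokes: int = 30,
    seed: int = 0,
    inner_radius_px: float = 16.0,
    stroke_width_px: float = DEFAULT_STROKE_WIDTH_PX,
    noise_sd: float = 0.0,
) -> Image2D:
    """Spoke pattern: the local fiber axis equals the radial direction
    from ``center`` at every drawn pixel.

    ``center`` is (x0, y0) in y-up pixel coordinates; defaults to the
    image center.  A seeded global angular jitter decorrelates the
    spoke set across seeds without breaking radiality.
    """
    if center is None:
        center = ((width - 1) / 2.0, (height - 1) / 2.0)
    cx, cy = center
    if not (0 <= cx < width and 0 <= cy < height):
        raise ValueError(f"center {center} outside image {height}x{width}")
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 360.0 / n_spokes)
    outer = float(np.hypot(max(cx, width - 1 - cx), max(cy, height - 1 - cy)))
    canvas = np.zeros((height, width), dtype=float)
    for k in range(n_spokes):
        phi = np.radians(offset + 360.0 * k / n_spokes)
        r_mid = (inner_radius_px + outer) / 2.0
        length = outer - inner_radius_px
        x0 = cx + r_mid * np.cos(phi)
        y0 = cy + r_mid * np.sin(phi)
        _render_stroke(canvas, x0, y0, np.degrees(phi), length, stroke_width_px)
    img = _normalize01(canvas)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return Image2D(img)


def make_nuclei_image(spec: NucleiFieldSpec) -> NucleiFieldResult:
    """Filled soft-edged ellipses with major-axis angles from the axial
    von Mises sampler.

    With ``axis_ratio == 1`` the nuclei are circular and the returned
    ground truth is flagged undefined (angles set to NaN).
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros((spec.height, spec.width), dtype=float)
    angles = sample_axial_von_mises(
        spec.orientation_mu_deg, spec.orientation_kappa, spec.n_nuclei, rng
    )
    xs = rng.uniform(0, spec.width, spec.n_nuclei)
    ys = rng.uniform(0, spec.height, spec.n_nuclei)
    a_maj = spec.major_axis_px / 2.0
    a_min = a_maj / spec.axis_ratio
    for x0, y0, ang in zip(xs, ys, angles):
        rad = np.radians(ang)
        ca, sa = np.cos(rad), np.sin(rad)
        pad = a_maj + 2.0
        r0 = max(int(np.floor(y0 - pad)), 0)
        r1 = min(int(np.ceil(y0 + pad)) + 1, spec.height)
        c0 = max(int(np.floor(x0 - pad)), 0)
        c1 = min(int(np.ceil(x0 + pad)) + 1, spec.width)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
        u = (xx - x0) * ca + (yy - y0) * sa
        v = -(xx - x0) * sa + (yy - y0) * ca
        rho = np.sqrt((u / a_maj) ** 2 + (v / a_min) ** 2)
        # soft rim (~1 px) so gradient estimation sees a smooth edge
        edge = 1.0 / max(a_min, 1.0)
        canvas[r0:r1, c0:c1] += np.clip((1.0 - rho) / edge + 1.0, 0.0, 1.0)
    img = _normalize01(canvas)
    defined = spec.axis_ratio > 1.0
    if not defined:
        angles = np.full_like(angles, np.nan)
    return NucleiFieldResult(
        image=Image2D(img), angles_deg=angles, orientation_defined=defined
    )


def make_calcium_trace(
    baseline: float,
    amplitude: float,
    onset_time_s: float,
    decay_tau_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float = 30.0,
    fps: float = 16.0,
) -> CalciumTrace:
    """Exponential-decay transient on a flat pre-stimulus baseline.

    F(t) = baseline for t < onset;
    baseline + amplitude * exp(-(t - onset)/tau) for t >= onset.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive (F0 division)")
    if decay_tau_s <= 0:
        raise ValueError("decay_tau_s must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(0.0, duration_s, 1.0 / fps)
    f = np.full_like(t, float(baseline))
    post = t >= onset_time_s
    f[post] += amplitude * np.exp(-(t[post] - onset_time_s) / decay_tau_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, f.shape)
    return CalciumTrace(time_s=t, F=f)
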