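"""Radial-organization scoring of orientation fields.

Given an orientation map and a center, each tile's fiber axis is
compared to the local radial axis; the energy-weighted mean axial
deviation (0-90 degrees) summarizes how radially organized the field
is.  A sample map can then be compared against a radial control and an
isotropic control, yielding a verdict on which control it resembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import ks_2samp

from .image import Image2D, axial_difference_deg, wrap_axial_deg
from .orientation import OrientationMap


@dataclass(frozen=True)
class RadialReference:
    """Radial axial angle per position around ``center`` (x0, y0).

    At position p != center the angle is the axial angle of p - center;
    the center itself is undefined (NaN).
    """

    center: tuple[float, float]
    shape: tuple[int, int]

    def angle_at(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx = x - self.center[0]
        dy = y - self.center[1]
        ang = wrap_axial_deg(np.degrees(np.arctan2(dy, dx)))
        ang = np.where((dx == 0) & (dy == 0), np.nan, ang)
        return ang

    def angle_field(self) -> np.ndarray:
        yy, xx = np.mgrid[0 : self.shape[0], 0 : self.shape[1]].astype(float)
        return self.angle_at(xx, yy)


def radial_reference(shape: tuple[int, int], center: tuple[float, float]) -> RadialReference:
    """Build the per-position radial reference; center must be inside."""
    h, w = shape
    x0, y0 = center
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError(f"center {center} outside image shape {shape}")
    return RadialReference(center=(float(x0), float(y0)), shape=(h, w))


def estimate_center(image: Image2D) -> tuple[float, float]:
    """Centroid of the foreground (above-mean-intensity) mask, (x0, y0).

    Fallback when no physiological center is supplied.
    """
    v = image.values
    mask = v > v.mean()
    if not mask.any():
        mask = np.ones_like(v, dtype=bool)
    cy, cx = ndimage.center_of_mass(mask)
    return (float(cx), float(cy))


@dataclass(frozen=True)
class DeviationSummary:
    """Per-map radial deviation statistics (degrees, in [0, 90])."""

    mean_deviation_deg: float      # energy-weighted mean
    median_deviation_deg: float
    deviations_deg: np.ndarray     # per valid tile
    weights: np.ndarray            # tile energies
    n_tiles: int


def angular_deviation(omap: OrientationMap, ref: RadialReference) -> DeviationSummary:
    """Axial deviation of each valid tile from the local radial axis.

    d = min(|theta - theta_ref|, 180 - |theta - theta_ref|) in [0, 90];
    the mean is energy-weighted, the median unweighted.
    """
    mask = omap.valid
    if not mask.any():
        raise ValueError("orientation map has no valid tiles")
    theta = omap.theta_deg[mask]
    xs = omap.centers_x[mask]
    ys = omap.centers_y[mask]
    ref_angles = ref.angle_at(xs, ys)
    ok = np.isfinite(ref_angles)
    if not ok.any():
        raise ValueError("all valid tiles coincide with the reference center")
    dev = axial_difference_deg(theta[ok], ref_angles[ok])
    w = omap.energy[mask][ok]
    wsum = w.sum()
    mean_dev = float(np.sum(dev * w) / wsum) if wsum > 0 else float(dev.mean())
    return DeviationSummary(
        mean_deviation_deg=mean_dev,
        median_deviation_deg=float(np.median(dev)),
        deviations_deg=dev,
        weights=w,
        n_tiles=int(dev.size),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Two-axis comparison of a sample against radial/isotropic controls.

    Axis (a): Kolmogorov-Smirnov distance between tile-coherency
    distributions of sample vs each control.  Axis (b): absolute
    difference in mean radial deviation.  ``verdict`` is "radial-like"
    when both axes place the sample closer to the radial control,
    "isotropic-like" when both place it closer to the isotropic one,
    else "indeterminate".  Similarities are 1 - normalized distance, so
    higher means more alike.
    """

    mean_radial_deviation_deg: float
    coherency_summary: dict
    similarity_to_radial: float
    similarity_to_isotropic: float
    verdict: str
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_radial_deviation_deg": self.mean_radial_deviation_deg,
            "coherency_summary": self.coherency_summary,
            "similarity_to_radial": self.similarity_to_radial,
            "similarity_to_isotropic": self.similarity_to_isotropic,
            "verdict": self.verdict,
            "detail": self.detail,
        }


def _coherency_sample(omap: OrientationMap) -> np.ndarray:
    c = omap.coherency[omap.valid]
    if c.size == 0:
        raise ValueError("orientation map has no valid tiles")
    return c


def compare_to_controls(
    sample_map: OrientationMap,
    radial_map: OrientationMap,
    isotropic_map: OrientationMap,
    ref: RadialReference,
) -> ComparisonReport:
    """Compare a sample orientation map to radial and isotropic controls.

    All three maps must share the same tiling (window size and stride).
    """
    for m in (radial_map, isotropic_map):
        if (
            m.window_size_L != sample_map.window_size_L
            or m.stride != sample_map.stride
            or m.theta_deg.shape != sample_map.theta_deg.shape
        ):
            raise ValueError("maps do not share a common tiling")

    cs = _coherency_sample(sample_map)
    cr = _coherency_sample(radial_map)
    ci = _coherency_sample(isotropic_map)
    ks_radial = float(ks_2samp(cs, cr, method="asymp").statistic)
    ks_isotropic = float(ks_2samp(cs, ci, method="asymp").statistic)

    dev_sample = angular_deviation(sample_map, ref)
    dev_radial = angular_deviation(radial_map, ref)
    dev_isotropic = angular_deviation(isotropic_map, ref)
    gap_radial = abs(dev_sample.mean_deviation_deg - dev_radial.mean_deviation_deg)
    gap_isotropic = abs(dev_sample.mean_deviation_deg - dev_isotropic.mean_deviation_deg)

    closer_radial_coh = ks_radial <= ks_isotropic
    closer_radial_dev = gap_radial <= gap_isotropic
    if closer_radial_coh and closer_radial_dev:
        verdict = "radial-like"
    elif (not closer_radial_coh) and (not closer_radial_dev):
        verdict = "isotropic-like"
    else:
        verdict = "indeterminate"

    # combined distance per control: mean of KS (already in [0,1]) and
    # deviation gap normalized by its 90-degree range
    dist_radial = 0.5 * (ks_radial + gap_radial / 90.0)
    dist_isotropic = 0.5 * (ks_isotropic + gap_isotropic / 90.0)
    return ComparisonReport(
        mean_radial_deviation_deg=dev_sample.mean_deviation_deg,
        coherency_summary={
            "sample_mean": float(cs.mean()),
            "sample_median": float(np.median(cs)),
            "radial_control_mean": float(cr.mean()),
            "isotropic_control_mean": float(ci.mean()),
        },
        similarity_to_radial=float(1.0 - dist_radial),
        similarity_to_isotropic=float(1.0 - dist_isotropic),
        verdict=verdict,
        detail={
            "ks_coherency_vs_radial": ks_radial,
            "ks_coherency_vs_isotropic": ks_isotropic,
            "mean_deviation_sample_deg": dev_sample.mean_deviation_deg,
            "mean_deviation_radial_deg": dev_radial.mean_deviation_deg,
            "mean_deviation_isotropic_deg": dev_isotropic.mean_deviation_deg,
        },
    )
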