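"""Orientation-distribution histogram with Gaussian peak fit.

Emulates the nuclei-alignment read-out: axial angles are binned over
[-90, 90), a Gaussian peak (with periodic angular distance, period
180 degrees) is least-squares fitted, and the goodness of fit — in
[0, 1], 1 for a sharply aligned distribution, ~0 for a flat one — is
reported as the alignment score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .image import Image2D, wrap_axial_deg
from .orientation import OrientationMap, orientation_map

PERIOD_DEG = 180.0


@dataclass(frozen=True)
class OrientationHistogram:
    """Axial-angle histogram over [-90, 90) with equal-width bins."""

    bin_centers_deg: np.ndarray
    weights: np.ndarray
    normalized: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers_deg)

    @property
    def bin_width_deg(self) -> float:
        return PERIOD_DEG / self.n_bins


@dataclass(frozen=True)
class GaussianPeakFit:
    """Fitted peak parameters and the [0, 1] goodness score."""

    mu_deg: float
    sigma_deg: float
    amplitude: float
    baseline: float
    goodness: float


def _angular_delta(angle_deg: np.ndarray, mu_deg: float) -> np.ndarray:
    """Signed periodic distance (period 180), in [-90, 90)."""
    return (angle_deg - mu_deg + 90.0) % PERIOD_DEG - 90.0


def orientation_histogram(
    orientations,
    n_bins: int = 90,
    weighting: str = "count",
) -> OrientationHistogram:
    """Bin axial angles (degrees) into an equal-width histogram.

    ``orientations`` may be a sequence of angles or an
    :class:`~radialign.orientation.OrientationMap`, in which case only
    valid tiles contribute.  ``weighting`` is ``"count"``, ``"energy"``
    or ``"coherency_energy"`` (per-tile coherency times energy; angle
    lists only support ``"count"``).  The histogram is normalized to
    unit mass.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if weighting not in ("count", "energy", "coherency_energy"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if isinstance(orientations, OrientationMap):
        m = orientations
        mask = m.valid
        angles = np.asarray(m.theta_deg[mask], dtype=float)
        if weighting == "energy":
            w = np.asarray(m.energy[mask], dtype=float)
        elif weighting == "coherency_energy":
            w = np.asarray(m.coherency[mask] * m.energy[mask], dtype=float)
        else:
            w = np.ones_like(angles)
    else:
        angles = np.asarray(orientations, dtype=float).ravel()
        angles = angles[np.isfinite(angles)]
        if weighting != "count":
            raise ValueError("angle lists support only weighting='count'")
        w = np.ones_like(angles)
    if angles.size == 0:
        raise ValueError("no valid orientations to histogram")
    angles = wrap_axial_deg(angles)
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    hist, _ = np.histogram(angles, bins=edges, weights=w)
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram has zero total mass")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return OrientationHistogram(
        bin_centers_deg=centers, weights=hist / total, normalized=True
    )


def _peak_model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    baseline, amplitude, mu, sigma = params
    d = _angular_delta(x, mu)
    return baseline + amplitude * np.exp(-(d**2) / (2.0 * sigma**2))


def fit_gaussian_peak(hist: OrientationHistogram) -> GaussianPeakFit:
    """Least-squares Gaussian-peak fit with periodic angular distance.

    Goodness = max(0, 1 - SS_res/SS_tot), clipped to [0, 1]; a flat
    histogram (SS_tot ~ 0 with nonzero mass) scores 0.  Initialization
    is from the modal bin, with a second start at the strongest
    secondary mode; the lower-residual fit wins.
    """
    if hist.n_bins < 5:
        raise ValueError("need at least 5 bins to fit")
    x = np.asarray(hist.bin_centers_deg, dtype=float)
    y = np.asarray(hist.weights, dtype=float)
    if not np.any(y > 0):
        raise ValueError("cannot fit a flat-zero histogram")
    y_mean = float(y.mean())
    ss_tot = float(np.sum((y - y_mean) ** 2))

    def solve(mu0: float) -> tuple[np.ndarray, float]:
        amp0 = max(float(y.max()) - y_mean, 1e-12)
        p0 = np.array([min(float(y.min()), y_mean), amp0, mu0, 15.0])
        lo = [0.0, 0.0, mu0 - 90.0, hist.bin_width_deg / 4.0]
        hi = [float(y.max()) + 1e-9, 2.0 * float(y.max()) + 1e-9, mu0 + 90.0, 180.0]
        res = least_squares(
            lambda p: _peak_model(p, x) - y, p0, bounds=(lo, hi), method="trf"
        )
        return res.x, float(np.sum(res.fun**2))

    mu_modal = float(x[int(np.argmax(y))])
    params, ss_res = solve(mu_modal)
    second = _secondary_mode(x, y, mu_modal)
    if second is not None:
        params2, ss_res2 = solve(second)
        if ss_res2 < ss_res:
            params, ss_res = params2, ss_res2
    if ss_tot <= 1e-30:
        goodness = 0.0  # flat histogram: no structure to explain
    else:
        goodness = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    baseline, amplitude, mu, sigma = params
    return GaussianPeakFit(
        mu_deg=float(wrap_axial_deg(mu)),
        sigma_deg=float(sigma),
        amplitude=float(amplitude),
        baseline=float(baseline),
        goodness=goodness,
    )


def _secondary_mode(x: np.ndarray, y: np.ndarray, mu_primary: float) -> float | None:
    """Strongest bin at least 20 degrees (axially) from the primary mode."""
    d = np.abs(_angular_delta(x, mu_primary))
    far = d >= 20.0
    if not np.any(far):
        return None
    idx = int(np.argmax(np.where(far, y, -np.inf)))
    return float(x[idx])


def alignment_score(
    image: Image2D,
    window_size_L: int = 16,
    stride: int | None = None,
    sigma: float = 1.5,
    n_bins: int = 90,
    weighting: str = "coherency_energy",
    energy_threshold_rel: float = 1e-3,
) -> GaussianPeakFit:
    """Image-level alignment score.

    Composition: orientation map -> weighted axial histogram ->
    Gaussian-peak fit; the fit's goodness is the alignment score.
    Raises when the image yields no valid tiles (e.g. blank input).
    """
    m = orientation_map(
        image,
        window_size_L=window_size_L,
        stride=stride,
        sigma=sigma,
        energy_threshold_rel=energy_threshold_rel,
    )
    if m.n_valid == 0:
        raise ValueError("no valid orientation tiles (blank image?)")
    hist = orientation_histogram(m, n_bins=n_bins, weighting=weighting)
    return fit_gaussian_peak(hist)
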