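"""Core 2D image container used by every analysis stage.

Coordinate convention
---------------------
``Image2D.values`` is stored *y-up*: row index 0 is the bottom of the
image and the row index increases with the physical y coordinate.
Angles are axial, in degrees, in ``[-90, 90)``, measured
counter-clockwise from the +x axis.  File readers/writers perform the
row flip so that on-disk images keep the usual top-row-first layout
(see :mod:`radialign.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Image2D:
    """A single-channel intensity grid.

    Parameters
    ----------
    values
        2D float array (y-up row order), finite, at least 3x3.
    pixel_size
        Physical length per pixel (arbitrary unit, default 1.0).
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"Image2D requires a 2D array, got ndim={v.ndim}")
        if v.shape[0] < 3 or v.shape[1] < 3:
            raise ValueError(f"Image2D must be at least 3x3, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("Image2D values must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def wrap_axial_deg(angle_deg):
    """Wrap angles (degrees) to the axial range [-90, 90)."""
    return (np.asarray(angle_deg, dtype=float) + 90.0) % 180.0 - 90.0


def axial_difference_deg(a_deg, b_deg):
    """Axial angular distance in degrees, in [0, 90].

    Orientations are undirected, so the distance between two axes is
    ``min(|a-b|, 180-|a-b|)``.
    """
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def axial_mean_deg(angles_deg) -> float:
    """Mean of axial angles via angle doubling, in [-90, 90).

    Doubles the angles so the 180-degree-periodic orientations become
    360-degree-periodic directions, takes the circular mean, halves.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    if a.size == 0:
        raise ValueError("axial_mean_deg: empty input")
    mean = np.angle(np.exp(1j * a).mean())
    return float(wrap_axial_deg(np.degrees(mean / 2.0)))


def axial_circular_variance(angles_deg) -> float:
    """Circular variance of doubled axial angles, in [0, 1].

    0 for perfectly concentrated orientations, 1 for a balanced
    (e.g. uniform) axial distribution.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    if a.size == 0:
        raise ValueError("axial_circular_variance: empty input")
    r = np.abs(np.exp(1j * a).mean())
    return float(1.0 - r)
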