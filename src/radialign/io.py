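"""File I/O: images, CSV/JSON artifacts, run manifests.

On-disk images use the conventional top-row-first layout; loading
flips rows so in-memory arrays are y-up (see :mod:`radialign.image`).
Coordinates in all outputs are 0-based y-up pixel indices, angles in
degrees.
"""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile

from .image import Image2D
from .orientation import OrientationMap
from .synthetic import CalciumTrace


def read_image(path: str | Path, channel: int | None = None) -> Image2D:
    """Load a TIFF or PNG as a single-channel float image in [0, 1].

    8/16-bit integer data is scaled by its dtype maximum; float data is
    passed through after a finiteness check.  Multi-channel files
    require an explicit ``channel`` index.  Rows are flipped to the
    package's y-up convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name} has {arr.shape[-1]} channels; pass an explicit "
                "channel index"
            )
        arr = arr[..., channel]
    elif arr.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{path.name} contains non-finite values")
    return Image2D(np.flipud(arr))


def write_image(path: str | Path, image: Image2D) -> None:
    """Write an image as float32 TIFF or 8-bit PNG (by extension)."""
    path = Path(path)
    arr = np.flipud(image.values)  # back to top-row-first
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
    elif suffix == ".png":
        clipped = np.clip(arr, 0.0, 1.0)
        iio.imwrite(path, np.round(clipped * 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format {suffix!r}")


def write_angles_csv(path: str | Path, angles_deg) -> None:
    """One axial angle (degrees) per row."""
    pd.DataFrame({"angle_deg": np.asarray(angles_deg, dtype=float)}).to_csv(
        path, index=False
    )


def write_orientation_map_csv(path: str | Path, omap: OrientationMap) -> None:
    """Per-tile CSV: x0, y0, theta_deg, coherency, energy, valid."""
    df = pd.DataFrame(
        {
            "x0": omap.centers_x.ravel(),
            "y0": omap.centers_y.ravel(),
            "theta_deg": omap.theta_deg.ravel(),
            "coherency": omap.coherency.ravel(),
            "energy": omap.energy.ravel(),
            "valid": omap.valid.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)


def write_trace_csv(path: str | Path, trace: CalciumTrace) -> None:
    cols = {"time_s": trace.time_s, "F": trace.F}
    if trace.dFF0 is not None:
        cols["dFF0"] = trace.dFF0
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> CalciumTrace:
    """CSV with columns time (or time_s) and F."""
    df = pd.read_csv(path)
    tcol = "time_s" if "time_s" in df.columns else "time"
    if tcol not in df.columns or "F" not in df.columns:
        raise ValueError(f"{path}: expected columns time[_s] and F")
    return CalciumTrace(
        time_s=df[tcol].to_numpy(dtype=float), F=df["F"].to_numpy(dtype=float)
    )


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_manifest(out_dir: str | Path, config: dict, seeds: dict | None = None) -> Path:
    """Record config, seeds and versions next to the run outputs.

    The angle/coordinate conventions are stated once here so every
    artifact directory is self-describing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import radialign

    manifest = {
        "config": config,
        "seeds": seeds or {},
        "conventions": {
            "angles": "axial degrees in [-90, 90), CCW from +x, y-up",
            "coordinates": "0-based pixel indices, y-up after load-time row flip",
        },
        "versions": {
            "radialign": radialign.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
        },
    }
    path = out_dir / "manifest.json"
    write_json(path, manifest)
    return path
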