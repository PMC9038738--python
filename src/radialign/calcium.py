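"""Calcium-transient quantification: dF/F0 relative to a pre-stimulus
baseline.

F0 is the mean fluorescence over a user-set baseline window ending at
the stimulus (a single-sample baseline is noise-fragile);
dF/F0 = (F - F0) / F0 elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import CalciumTrace


@dataclass(frozen=True)
class TransientSummary:
    """Scalar read-outs of a normalized transient."""

    F0: float
    peak_dFF0: float
    time_to_peak_s: float  # measured from the end of the baseline window


def delta_f_over_f0(
    trace: CalciumTrace,
    baseline_window_s: tuple[float, float] | None = None,
) -> tuple[CalciumTrace, TransientSummary]:
    """Normalize a fluorescence trace by its pre-stimulus baseline.

    ``baseline_window_s`` is a (start, end) time interval; samples with
    start <= t < end define F0.  Defaults to everything before the
    trace midpoint is NOT assumed — when omitted, the first 10% of the
    trace is used and this choice is the caller's responsibility.
    Raises if the window is empty or F0 <= 0.
    """
    t = np.asarray(trace.time_s, dtype=float)
    f = np.asarray(trace.F, dtype=float)
    if t.ndim != 1 or t.shape != f.shape or t.size < 2:
        raise ValueError("trace must hold matching 1D time and F arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if baseline_window_s is None:
        baseline_window_s = (float(t[0]), float(t[0] + 0.1 * (t[-1] - t[0])))
    b0, b1 = baseline_window_s
    if b1 <= b0:
        raise ValueError("baseline window must have positive length")
    in_base = (t >= b0) & (t < b1)
    if not in_base.any():
        raise ValueError("baseline window contains no samples")
    f0 = float(f[in_base].mean())
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be positive, got {f0}")
    dff0 = (f - f0) / f0
    out = replace(trace, F0=f0, dFF0=dff0)
    post = t >= b1
    region = post if post.any() else np.ones_like(post)
    idx = int(np.argmax(np.where(region, dff0, -np.inf)))
    summary = TransientSummary(
        F0=f0,
        peak_dFF0=float(dff0[idx]),
        time_to_peak_s=float(t[idx] - b1),
    )
    return out, summary
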