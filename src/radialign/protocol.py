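"""Membrane strain model and mechanical-stimulation waveform compiler.

The strain <-> reservoir-volume map uses spherical-cap kinematics for a
clamped circular membrane of radius ``a``: injecting a fluid volume
``dV`` lifts the membrane into a spherical cap of apex height ``h``
with

    dV = pi * h * (3 a^2 + h^2) / 6,

cap sphere radius R = (a^2 + h^2) / (2 h), meridional arc
s = 2 R arcsin(a / R), and average radial strain (s - 2a) / (2a).
This is a kinematic surrogate for a full finite-element membrane
analysis: it reproduces the monotone strain-volume relationship with no
free material parameters (the elastic modulus is carried as metadata
only).

Protocols are ordered phase lists (ramp / rest / cyclic) compiled to a
strain-vs-time waveform on a uniform grid, with the reservoir volume
attached through the membrane model and every stretch event logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

HEMISPHERE_STRAIN = (np.pi - 2.0) / 2.0  # strain when the cap is a hemisphere


@dataclass(frozen=True)
class MembraneModelParams:
    """Clamped circular membrane geometry/metadata.

    ``membrane_diameter_mm`` defaults to 22 (a 24 mm variant exists for
    larger constructs).  ``initial_elastic_modulus_MPa`` and
    ``thickness_mm`` are carried for provenance; the kinematic cap
    model does not use them.
    """

    membrane_diameter_mm: float = 22.0
    initial_elastic_modulus_MPa: float = 1.0
    thickness_mm: float | None = None

    def __post_init__(self) -> None:
        if self.membrane_diameter_mm <= 0:
            raise ValueError("membrane_diameter_mm must be positive")
        if self.initial_elastic_modulus_MPa <= 0:
            raise ValueError("initial_elastic_modulus_MPa must be positive")
        if self.thickness_mm is not None and self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive when given")

    @property
    def radius_mm(self) -> float:
        return self.membrane_diameter_mm / 2.0

    @property
    def hemisphere_volume_uL(self) -> float:
        """Volume (uL = mm^3) at which the cap becomes a hemisphere."""
        a = self.radius_mm
        return (2.0 / 3.0) * np.pi * a**3


@dataclass(frozen=True)
class MembraneState:
    """One point on the strain-volume curve."""

    delta_volume_uL: float
    cap_height_mm: float
    radial_strain: float  # dimensionless; multiply by 100 for percent

    @property
    def radial_strain_percent(self) -> float:
        return 100.0 * self.radial_strain


def _cap_height_from_volume(delta_volume_uL: float, a_mm: float) -> float:
    """Invert dV = pi h (3 a^2 + h^2) / 6 for h >= 0 (real cubic root)."""
    if delta_volume_uL == 0.0:
        return 0.0
    # h^3 + 3 a^2 h - 6 dV / pi = 0; monotone in h, single real positive root
    c = 6.0 * delta_volume_uL / np.pi
    # Cardano for depressed cubic h^3 + p h + q = 0 with p = 3 a^2, q = -c
    p = 3.0 * a_mm**2
    disc = np.sqrt((c / 2.0) ** 2 + (p / 3.0) ** 3)
    h = np.cbrt(c / 2.0 + disc) + np.cbrt(c / 2.0 - disc)
    return float(h)


def cap_strain_from_volume(
    delta_volume_uL: float, params: MembraneModelParams
) -> MembraneState:
    """Average radial strain of the membrane for a reservoir volume change."""
    if delta_volume_uL < 0:
        raise ValueError("delta_volume_uL must be >= 0")
    a = params.radius_mm
    h = _cap_height_from_volume(delta_volume_uL, a)
    if h == 0.0:
        return MembraneState(delta_volume_uL=0.0, cap_height_mm=0.0, radial_strain=0.0)
    R = (a**2 + h**2) / (2.0 * h)
    s = 2.0 * R * np.arcsin(min(a / R, 1.0))
    strain = (s - 2.0 * a) / (2.0 * a)
    return MembraneState(
        delta_volume_uL=float(delta_volume_uL),
        cap_height_mm=h,
        radial_strain=float(strain),
    )


def _strain_of_height(h, a_mm: float):
    """Vectorized average radial strain as a function of cap height."""
    h = np.asarray(h, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (a_mm**2 + h**2) / (2.0 * h)
        s = 2.0 * R * np.arcsin(np.minimum(a_mm / R, 1.0))
        strain = (s - 2.0 * a_mm) / (2.0 * a_mm)
    return np.where(h == 0.0, 0.0, strain)


def volumes_for_strains(target_strains, params: MembraneModelParams) -> np.ndarray:
    """Vectorized inverse of :func:`cap_strain_from_volume`.

    Bisects the monotone strain(h) relation in cap-height space over
    (0, a], then maps h to volume in closed form.  Roundtrip error
    < 1e-8 in strain (h resolved to ~a * 2^-60).
    """
    eps = np.asarray(target_strains, dtype=float)
    if np.any(eps < 0):
        raise ValueError("target_strain must be >= 0")
    if np.any(eps >= HEMISPHERE_STRAIN):
        bad = float(eps[eps >= HEMISPHERE_STRAIN].min())
        raise ValueError(
            f"target_strain {bad:.4f} is at or above the model "
            f"range limit {HEMISPHERE_STRAIN:.4f} (hemisphere)"
        )
    a = params.radius_mm
    lo = np.zeros_like(eps)
    hi = np.full_like(eps, a)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _strain_of_height(mid, a) < eps
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    h = 0.5 * (lo + hi)
    vol = np.pi * h * (3.0 * a**2 + h**2) / 6.0
    return np.where(eps == 0.0, 0.0, vol)


def volume_for_strain(
    target_strain: float, params: MembraneModelParams
) -> float:
    """Reservoir volume change producing a target average radial strain.

    Valid for 0 <= target_strain < (pi - 2)/2 (the hemisphere limit of
    the cap model); root-finding inversion with roundtrip error < 1e-8.
    """
    return float(volumes_for_strains(np.array([target_strain]), params)[0])


# --- protocol phases -------------------------------------------------------


@dataclass(frozen=True)
class RampPhase:
    """Linear strain increase from start to end over ``duration_s``."""

    start_strain_percent: float
    end_strain_percent: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.start_strain_percent < 0 or self.end_strain_percent < 0:
            raise ValueError("strains must be >= 0")

    @property
    def peak_strain_percent(self) -> float:
        return max(self.start_strain_percent, self.end_strain_percent)


@dataclass(frozen=True)
class RestPhase:
    """Zero strain for ``duration_s``."""

    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    peak_strain_percent: float = 0.0


@dataclass(frozen=True)
class CyclicPhase:
    """Repeated stretch-event cycles.

    Each cycle lasts ``cycle_duration_s`` and contains
    ``stretches_per_cycle`` triangular stretch-release events evenly
    spaced (one per slot of cycle_duration/stretches).
    ``cycles_per_day`` cycles are evenly spaced across each 24 h day,
    for ``days`` days.  ``stretch_duration_s`` is the width of each
    triangular event (peak at its midpoint).
    """

    strain_percent: float
    stretches_per_cycle: int = 10
    cycle_duration_s: float = 600.0
    cycles_per_day: int = 3
    days: int = 1
    stretch_duration_s: float = 4.0

    def __post_init__(self) -> None:
        if self.strain_percent < 0:
            raise ValueError("strain_percent must be >= 0")
        if self.stretches_per_cycle < 1 or self.cycles_per_day < 1 or self.days < 1:
            raise ValueError("counts must be >= 1")
        if self.cycle_duration_s <= 0 or self.stretch_duration_s <= 0:
            raise ValueError("durations must be positive")
        slot = self.cycle_duration_s / self.stretches_per_cycle
        if self.stretch_duration_s > slot:
            raise ValueError(
                f"stretch_duration_s {self.stretch_duration_s} exceeds the "
                f"per-stretch slot {slot}"
            )

    @property
    def peak_strain_percent(self) -> float:
        return self.strain_percent

    @property
    def duration_s(self) -> float:
        return 86400.0 * self.days

    @property
    def stretch_frequency_per_min(self) -> float:
        return 60.0 * self.stretches_per_cycle / self.cycle_duration_s


Phase = Union[RampPhase, RestPhase, CyclicPhase]


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered list of stimulation phases."""

    phases: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        for p in self.phases:
            if not isinstance(p, (RampPhase, RestPhase, CyclicPhase)):
                raise TypeError(f"unknown phase type {type(p).__name__}")

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)


def slow_ramp_day() -> ProtocolSpec:
    """One day of the first stimulation protocol: linear ramp 0 -> 10%
    strain over 7 h, then 17 h rest."""
    return ProtocolSpec(
        phases=(
            RampPhase(start_strain_percent=0.0, end_strain_percent=10.0,
                      duration_s=7 * 3600.0),
            RestPhase(duration_s=17 * 3600.0),
        )
    )


def training_day(days: int = 1) -> ProtocolSpec:
    """Training protocol: 3 cycles/day of 10 stretches in 10 min
    (1 stretch/min) at 5% maximum strain."""
    return ProtocolSpec(
        phases=(
            CyclicPhase(strain_percent=5.0, stretches_per_cycle=10,
                        cycle_duration_s=600.0, cycles_per_day=3, days=days),
        )
    )


@dataclass(frozen=True)
class StretchEvent:
    """One logged stretch: peak time, indices and magnitude."""

    time_s: float
    phase_index: int
    cycle_index: int        # global cycle counter within the phase
    stretch_index: int      # within its cycle
    strain_percent: float


@dataclass(frozen=True)
class StimulationWaveform:
    """Compiled target-strain time series with attached volumes."""

    time_s: np.ndarray
    strain_percent: np.ndarray
    delta_volume_uL: np.ndarray
    event_log: tuple
    dt_s: float

    @property
    def peak_strain_percent(self) -> float:
        return float(self.strain_percent.max()) if self.strain_percent.size else 0.0

    @property
    def n_events(self) -> int:
        return len(self.event_log)

    @property
    def n_cycles(self) -> int:
        return len({(e.phase_index, e.cycle_index) for e in self.event_log})


def _triangle(t: np.ndarray, peak_time: float, half_width: float, height: float) -> np.ndarray:
    return height * np.clip(1.0 - np.abs(t - peak_time) / half_width, 0.0, None)


def compile_protocol(
    spec: ProtocolSpec,
    params: MembraneModelParams | None = None,
    dt_s: float = 1.0,
) -> StimulationWaveform:
    """Compile a phase list into a strain waveform and event log.

    Phases are laid end to end (they cannot overlap by construction).
    Ramp phases rise linearly and include their endpoint sample so the
    compiled peak equals the spec exactly; cyclic phases emit
    triangular stretch events whose apices fall on the time grid
    whenever ``stretch_duration_s`` is an even multiple of ``dt_s``.
    Volumes come from :func:`volume_for_strain` on the unique strain
    levels of the grid.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if params is None:
        params = MembraneModelParams()
    total = spec.total_duration_s
    n = int(round(total / dt_s)) + 1 if total > 0 else 0
    time = np.arange(n) * dt_s
    strain = np.zeros(n)
    events: list[StretchEvent] = []
    t_phase = 0.0
    for pi, phase in enumerate(spec.phases):
        t0, t1 = t_phase, t_phase + phase.duration_s
        in_phase = (time >= t0) & (time <= t1)
        if isinstance(phase, RampPhase):
            frac = (time[in_phase] - t0) / phase.duration_s
            seg = phase.start_strain_percent + frac * (
                phase.end_strain_percent - phase.start_strain_percent
            )
            strain[in_phase] = np.maximum(strain[in_phase], seg)
        elif isinstance(phase, CyclicPhase):
            slot = phase.cycle_duration_s / phase.stretches_per_cycle
            day_s = 86400.0
            cycle_spacing = day_s / phase.cycles_per_day
            half = phase.stretch_duration_s / 2.0
            for day in range(phase.days):
                for c in range(phase.cycles_per_day):
                    cycle_t0 = t0 + day * day_s + c * cycle_spacing
                    gcycle = day * phase.cycles_per_day + c
                    for s_i in range(phase.stretches_per_cycle):
                        peak_t = cycle_t0 + s_i * slot + half
                        events.append(
                            StretchEvent(
                                time_s=peak_t,
                                phase_index=pi,
                                cycle_index=gcycle,
                                stretch_index=s_i,
                                strain_percent=phase.strain_percent,
                            )
                        )
                        lo = np.searchsorted(time, peak_t - half)
                        hi = np.searchsorted(time, peak_t + half, side="right")
                        tri = _triangle(
                            time[lo:hi], peak_t, half, phase.strain_percent
                        )
                        strain[lo:hi] = np.maximum(strain[lo:hi], tri)
        # RestPhase contributes zeros
        t_phase = t1

    # strain -> volume on unique levels via the vectorized inversion
    volume = np.zeros_like(strain)
    if strain.size:
        levels, inverse = np.unique(strain, return_inverse=True)
        vol_levels = volumes_for_strains(levels / 100.0, params)
        volume = vol_levels[inverse]
    return StimulationWaveform(
        time_s=time,
        strain_percent=strain,
        delta_volume_uL=volume,
        event_log=tuple(events),
        dt_s=dt_s,
    )


def parse_protocol_dict(payload: dict) -> tuple[ProtocolSpec, MembraneModelParams, float]:
    """Build (spec, membrane params, dt_s) from a parsed YAML/JSON dict.

    Expected layout::

        phases:
          - {type: ramp, start_strain_percent: 0, end_strain_percent: 10, duration_s: 25200}
          - {type: rest, duration_s: 61200}
          - {type: cyclic, strain_percent: 5, stretches_per_cycle: 10,
             cycle_duration_s: 600, cycles_per_day: 3, days: 1}
        membrane: {membrane_diameter_mm: 22}
        dt_s: 1.0
    """
    kinds = {"ramp": RampPhase, "rest": RestPhase, "cyclic": CyclicPhase}
    phases = []
    for entry in payload.get("phases", []):
        entry = dict(entry)
        kind = entry.pop("type", None)
        if kind not in kinds:
            raise ValueError(f"unknown phase type {kind!r}")
        phases.append(kinds[kind](**entry))
    spec = ProtocolSpec(phases=tuple(phases))
    params = MembraneModelParams(**payload.get("membrane", {}))
    dt_s = float(payload.get("dt_s", 1.0))
    return spec, params, dt_s


def load_protocol_yaml(path) -> tuple[ProtocolSpec, MembraneModelParams, float]:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return parse_protocol_dict(payload)


@dataclass(frozen=True)
class CapabilityLimits:
    """Hardware envelope: maximum strain and stretch frequency."""

    max_strain_percent: float = 30.0
    max_frequency_per_min: float = 16.0


@dataclass(frozen=True)
class CapabilityReport:
    ok: bool
    violations: tuple


def capability_check(
    spec: ProtocolSpec, limits: CapabilityLimits | None = None
) -> CapabilityReport:
    """Flag phases exceeding the strain or frequency limits."""
    if limits is None:
        limits = CapabilityLimits()
    violations = []
    for i, phase in enumerate(spec.phases):
        if phase.peak_strain_percent > limits.max_strain_percent:
            violations.append(
                f"phase {i} ({type(phase).__name__}): peak strain "
                f"{phase.peak_strain_percent}% exceeds "
                f"{limits.max_strain_percent}%"
            )
        if isinstance(phase, CyclicPhase):
            freq = phase.stretch_frequency_per_min
            if freq > limits.max_frequency_per_min:
                violations.append(
                    f"phase {i} (CyclicPhase): {freq:.2f} stretches/min "
                    f"exceeds {limits.max_frequency_per_min}/min"
                )
    return CapabilityReport(ok=not violations, violations=tuple(violations))
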