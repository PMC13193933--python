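"""Simulated isometric mid-thigh-pull (IMTP) force-time curves.

A noiseless curve is a mono-exponential rise to a plateau,

    F(t) = F_peak * (1 - exp(-(RFD / F_peak) * t)),

whose analytic derivative at t = 0 is exactly the supplied RFD, so the
interference model's output maps directly onto the initial slope of the
simulated trace.  Aerobic exercise flattens the curve family by reducing
that slope only; the plateau force is shared across durations by default
(optionally scalable for exploration).  Optional additive Gaussian noise
with an explicit seed stands in for force-plate noise.

``estimate_rfd_from_curve`` recovers RFD as the least-squares slope of
force against time over an initial window, the conventional way an initial
slope is read off a sampled force-plate trace.  On the mono-exponential
form the fit is biased low by roughly ``(rfd / peak_force) * window / 2``
(the curve bends away from its tangent within the window), so the window
should be kept small relative to the curvature time constant
``peak_force / rfd`` when accuracy matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import DEFAULT_PARAMS, InterferenceParams, predict_rfd

__all__ = [
    "CurveParams",
    "ForceTimeCurve",
    "generate_curve",
    "curve_family",
    "estimate_rfd_from_curve",
    "write_curve",
    "read_curve",
]


@dataclass(frozen=True)
class CurveParams:
    """Sampling and noise settings for simulated IMTP traces.

    peak_force : plateau force, N (default 4000 — a strong athlete's IMTP).
    t_end, dt  : trial length and sampling interval, s (5 s at 1 kHz, the
                 typical force-plate configuration).
    noise_sd   : SD of additive zero-mean Gaussian force noise, N (0 = off).
    seed       : RNG seed; identical seed and parameters give bit-identical
                 curves.
    peak_scale : optional multiplier on the plateau, for exploring the case
                 where aerobic exercise also lowers peak force (default 1.0:
                 the interference model acts on the slope only).
    """

    peak_force: float = 4000.0
    t_end: float = 5.0
    dt: float = 0.001
    noise_sd: float = 0.0
    seed: int = 0
    peak_scale: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.peak_force) or self.peak_force <= 0:
            raise ValueError(f"peak_force must be strictly positive, got {self.peak_force}")
        if not 0 < self.dt < self.t_end:
            raise ValueError(f"require 0 < dt < t_end, got dt={self.dt}, t_end={self.t_end}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.peak_scale <= 0:
            raise ValueError(f"peak_scale must be strictly positive, got {self.peak_scale}")


@dataclass
class ForceTimeCurve:
    """A sampled force-time trace.

    ``rfd_used`` records the RFD that generated the curve (None for curves
    read from external files); ``label`` is a free provenance tag such as
    ``"d=10 min"``.
    """

    times: np.ndarray
    forces: np.ndarray
    rfd_used: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.forces.shape:
            raise ValueError("times and forces must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a curve needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def generate_curve(rfd: float, cp: CurveParams = CurveParams(), label: str = "") -> ForceTimeCurve:
    """Simulate one IMTP trace whose initial slope equals ``rfd`` (N·s⁻¹)."""
    if not math.isfinite(rfd) or rfd <= 0:
        raise ValueError(f"rfd must be strictly positive, got {rfd}")
    peak = cp.peak_force * cp.peak_scale
    n = int(round(cp.t_end / cp.dt)) + 1
    times = np.arange(n) * cp.dt
    forces = peak * (1.0 - np.exp(-(rfd / peak) * times))
    if cp.noise_sd > 0:
        rng = np.random.default_rng(cp.seed)
        forces = forces + rng.normal(0.0, cp.noise_sd, size=n)
    return ForceTimeCurve(times=times, forces=forces, rfd_used=float(rfd), label=label)


def curve_family(
    durations: Sequence[float],
    params: InterferenceParams = DEFAULT_PARAMS,
    cp: CurveParams = CurveParams(),
) -> list[ForceTimeCurve]:
    """One simulated IMTP trace per aerobic duration, in input order.

    Each curve's generating slope is ``predict_rfd(d, params)``; a duration
    of 0 yields the no-exercise reference curve at ``rfd0``.
    """
    durations = list(durations)
    if not durations:
        raise ValueError("durations must be non-empty")
    return [
        generate_curve(predict_rfd(d, params), cp, label=f"d={d:g} min")
        for d in durations
    ]


def estimate_rfd_from_curve(curve: ForceTimeCurve, window: float = 0.02) -> float:
    """Initial slope of a sampled trace: least-squares fit over [0, window] s.

    Requires at least two samples inside the window.  For noiseless
    mono-exponential curves the estimate is biased low by about
    ``(rfd / peak_force) * window / 2``; shrink the window for a steeper
    curve, or enlarge it to average down noise.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    mask = (curve.times >= 0) & (curve.times <= window)
    if np.count_nonzero(mask) < 2:
        raise ValueError(
            f"need at least 2 samples in [0, {window}] s, found {np.count_nonzero(mask)}"
        )
    slope, _ = np.polyfit(curve.times[mask], curve.forces[mask], 1)
    return float(slope)


_HEADER = "time_s,force_N"


def write_curve(curve: ForceTimeCurve, path: str | Path) -> None:
    """Write a curve as two-column CSV text at full double precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for t, f in zip(curve.times.tolist(), curve.forces.tolist()):
            fh.write(f"{t!r},{f!r}\n")


def read_curve(path: str | Path, label: str | None = None) -> ForceTimeCurve:
    """Read a two-column (time_s, force_N) text file written by write_curve.

    Round-trips bit-exactly; ``rfd_used`` is not stored in the file and is
    left unset.
    """
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"expected two columns (time_s, force_N), got {data.shape[1]}")
    return ForceTimeCurve(
        times=data[:, 0],
        forces=data[:, 1],
        rfd_used=None,
        label=label if label is not None else str(path),
    )
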