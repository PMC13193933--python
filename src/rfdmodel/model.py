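"""Nonlinear interference model for rate of force development (RFD).

The model predicts the acute loss of peak RFD — the initial slope of an
isometric mid-thigh-pull force-time curve, in N·s⁻¹ — following a single
bout of aerobic exercise of duration ``d`` minutes:

    RFD_aerobic(d) = RFD0 * [1 - kappa * (1 - exp(-alpha * (d - d0)+))]

where ``(x)+ = max(x, 0)`` is the positive-part operator.  ``kappa`` caps
the maximal fractional loss (kappa = 0.8 → at most 80 % of baseline RFD can
be lost), ``alpha`` sets how quickly the loss saturates with duration, and
``d0`` is an onset delay below which no decline is predicted.  A linear
comparison variant anchored at the same endpoints is provided for model
comparison.

The model is a theoretical dose-response projection: it describes the state
shortly after the aerobic bout and says nothing about recovery kinetics,
chronic adaptation, or aerobic modalities other than running.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InterferenceParams",
    "PredictionResult",
    "AthleteProfile",
    "DurationError",
    "ParameterError",
    "ExtrapolationWarning",
    "predict_rfd",
    "percent_loss",
    "predict_linear",
    "predict_table",
    "results_to_frame",
]


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class DurationError(ValueError):
    """An aerobic-exercise duration is outside the model's domain (d >= 0)."""


class ExtrapolationWarning(UserWarning):
    """Duration exceeds the supported domain; the closed form is extrapolated."""


@dataclass(frozen=True)
class InterferenceParams:
    """Tunable parameters of the interference model.

    Parameters
    ----------
    rfd0 : float
        Baseline peak rate of force development, N·s⁻¹; strictly positive.
        Default 15000 represents a highly trained weightlifter.
    kappa : float
        Scaling factor in [0, 1]: the maximal fractional RFD reduction the
        model permits.  Default 0.8 (at most 80 % loss).
    alpha : float
        Rate constant, per minute, >= 0: steepness of interference onset.
        Default 0.3.
    d0 : float
        Onset delay, minutes, >= 0: durations at or below ``d0`` produce no
        predicted decline.  Default 2.
    d_max : float
        Upper end of the supported duration domain, minutes.  Default 60.
        Longer durations are accepted with an :class:`ExtrapolationWarning`.
    """

    rfd0: float = 15000.0
    kappa: float = 0.8
    alpha: float = 0.3
    d0: float = 2.0
    d_max: float = 60.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.rfd0) or self.rfd0 <= 0:
            raise ParameterError(f"rfd0 must be strictly positive, got {self.rfd0}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ParameterError(f"kappa must lie in [0, 1], got {self.kappa}")
        if not math.isfinite(self.alpha) or self.alpha < 0:
            raise ParameterError(f"alpha must be non-negative, got {self.alpha}")
        if not math.isfinite(self.d0) or self.d0 < 0:
            raise ParameterError(f"d0 must be non-negative, got {self.d0}")
        if not self.d0 <= self.d_max:
            raise ParameterError(
                f"d0 must not exceed d_max, got d0={self.d0}, d_max={self.d_max}"
            )

    def replace(self, **changes: float) -> "InterferenceParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def rfd_floor(self) -> float:
        """Large-duration asymptote of the predicted RFD, rfd0 * (1 - kappa)."""
        return self.rfd0 * (1.0 - self.kappa)


#: Default parameter set for a highly trained weightlifter.
DEFAULT_PARAMS = InterferenceParams()


@dataclass(frozen=True)
class AthleteProfile:
    """A labelled baseline RFD to use as ``rfd0``."""

    label: str
    baseline_rfd: float
    description: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.baseline_rfd) or self.baseline_rfd <= 0:
            raise ParameterError(
                f"baseline_rfd must be strictly positive, got {self.baseline_rfd}"
            )

    def params(self, base: InterferenceParams = DEFAULT_PARAMS) -> InterferenceParams:
        """Parameter set with this athlete's baseline substituted for rfd0."""
        return base.replace(rfd0=self.baseline_rfd)


@dataclass(frozen=True)
class PredictionResult:
    """Prediction for a single aerobic-exercise duration.

    Full floating-point precision is retained in the fields; display-rounded
    values (nearest integer N·s⁻¹ and nearest integer percent, matching the
    conventional reporting precision) are exposed as properties.
    """

    duration: float
    predicted_rfd: float
    absolute_loss: float
    percent_loss: float

    @property
    def predicted_rfd_rounded(self) -> int:
        return round(self.predicted_rfd)

    @property
    def absolute_loss_rounded(self) -> int:
        return round(self.absolute_loss)

    @property
    def percent_loss_rounded(self) -> int:
        return round(self.percent_loss)


def _check_durations(d: np.ndarray, params: InterferenceParams) -> None:
    if d.size == 0:
        raise DurationError("durations must be non-empty")
    if not np.all(np.isfinite(d)):
        raise DurationError("durations must be finite")
    if np.any(d < 0):
        bad = float(d[d < 0].flat[0])
        raise DurationError(f"duration must be non-negative, got {bad}")
    if np.any(d > params.d_max):
        warnings.warn(
            f"duration exceeds d_max={params.d_max} min; "
            "extrapolating beyond the supported domain",
            ExtrapolationWarning,
            stacklevel=3,
        )


def _fractional_retention(d: np.ndarray, params: InterferenceParams) -> np.ndarray:
    """RFD_aerobic(d) / RFD0 — the bracketed factor of the closed form."""
    excess = np.maximum(d - params.d0, 0.0)
    return 1.0 - params.kappa * (1.0 - np.exp(-params.alpha * excess))


def predict_rfd(d, params: InterferenceParams = DEFAULT_PARAMS):
    """Predicted RFD (N·s⁻¹) after ``d`` minutes of acute aerobic exercise.

    Accepts a scalar or array-like duration; returns a float or ndarray
    accordingly.  Equals ``rfd0`` exactly for ``d <= d0``, decreases
    monotonically toward the floor ``rfd0 * (1 - kappa)``, and is continuous
    at the onset delay.  Negative durations raise :class:`DurationError`;
    durations above ``d_max`` warn and extrapolate.
    """
    arr = np.atleast_1d(np.asarray(d, dtype=float))
    _check_durations(arr, params)
    out = params.rfd0 * _fractional_retention(arr, params)
    return float(out[0]) if np.isscalar(d) or np.ndim(d) == 0 else out


def percent_loss(d, params: InterferenceParams = DEFAULT_PARAMS):
    """Percent loss of RFD after ``d`` minutes, 100 * (1 - RFD(d)/RFD0).

    Equals ``100 * kappa * (1 - exp(-alpha * (d - d0)+))`` and is therefore
    independent of ``rfd0``.
    """
    arr = np.atleast_1d(np.asarray(d, dtype=float))
    _check_durations(arr, params)
    out = 100.0 * (1.0 - _fractional_retention(arr, params))
    return float(out[0]) if np.isscalar(d) or np.ndim(d) == 0 else out


def predict_linear(d, params: InterferenceParams = DEFAULT_PARAMS):
    """Linear comparison variant of the interference model.

    Anchored at the nonlinear model's endpoints: ``rfd0`` at ``d <= d0``,
    declining along the chord to ``rfd0 * (1 - kappa)`` at ``d = d_max`` and
    clamped there for longer durations.  Because the exponential lies below
    its chord, the nonlinear prediction stays below this variant on
    (d0, d_max) except within the terminal gap
    ``rfd0 * kappa * exp(-alpha * (d_max - d0))`` left where the exponential
    has not fully reached the floor (0.33 N·s⁻¹ for the defaults).
    """
    arr = np.atleast_1d(np.asarray(d, dtype=float))
    _check_durations(arr, params)
    floor = params.rfd_floor
    if params.d_max > params.d0:
        frac = np.clip((arr - params.d0) / (params.d_max - params.d0), 0.0, 1.0)
    else:  # degenerate domain: step at d0
        frac = (arr > params.d0).astype(float)
    out = params.rfd0 - (params.rfd0 - floor) * frac
    return float(out[0]) if np.isscalar(d) or np.ndim(d) == 0 else out


def predict_table(
    durations: Sequence[float], params: InterferenceParams = DEFAULT_PARAMS
) -> list[PredictionResult]:
    """Per-duration predictions, in input order, as :class:`PredictionResult`.

    Element-wise identical to calling :func:`predict_rfd` and
    :func:`percent_loss` at each duration.  Raises :class:`DurationError`
    on an empty list, identifying the offending duration for negatives.
    """
    durations = list(durations)
    if not durations:
        raise DurationError("durations must be non-empty")
    results = []
    for d in durations:
        try:
            rfd = predict_rfd(d, params)
            pct = percent_loss(d, params)
        except DurationError as err:
            raise DurationError(f"invalid duration {d!r}: {err}") from err
        results.append(
            PredictionResult(
                duration=float(d),
                predicted_rfd=rfd,
                absolute_loss=params.rfd0 - rfd,
                percent_loss=pct,
            )
        )
    return results


def results_to_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    """Tabulate prediction results (full precision plus display rounding)."""
    if not results:
        raise ValueError("results must be non-empty")
    return pd.DataFrame(
        {
            "duration_min": [r.duration for r in results],
            "predicted_rfd": [r.predicted_rfd for r in results],
            "absolute_loss": [r.absolute_loss for r in results],
            "percent_loss": [r.percent_loss for r in results],
            "predicted_rfd_rounded": [r.predicted_rfd_rounded for r in results],
            "percent_loss_rounded": [r.percent_loss_rounded for r in results],
        }
    )
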