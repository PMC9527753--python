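"""Closed-form 1:1 interaction model for fluorescence sensorgrams.

A switchSense (or SPR/BLI-style) sensorgram records the percent change in
fluorescence of a reporter dye on a surface-tethered DNA nanolever while an
analyte solution flows over the chip (association phase) and is then
replaced by plain buffer (dissociation phase).  Under pseudo-first-order
conditions a 1:1 analyte:ligand interaction gives a mono-exponential rise

    F(t) = y0 + A * (1 - exp(-(k_a*c + k_d) * (t - t_a))),   t_a <= t <= t_d

followed by a mono-exponential decay.  Some analytes do not dissociate
completely under buffer flow; this is captured by a residual bound
fraction ``f_res`` that leaves a plateau above baseline:

    F(t) = y0 + A_d * (f_res + (1 - f_res) * exp(-k_d * (t - t_d))),  t >= t_d

``f_res = 0`` recovers the ordinary complete-dissociation decay.  At
equilibrium the association constant is K_A = k_a / k_d and the
dissociation constant K_D = k_d / k_a = 1 / K_A.

Units are fixed throughout the package: seconds, molar, percent
fluorescence change.  Any conversion happens at I/O.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, OutOfWindowError

__all__ = [
    "Mode",
    "PhaseMarkers",
    "SensorgramTrace",
    "RateParameters",
    "EquilibriumConstants",
    "ObservedRate",
    "observed_rate",
    "association_signal",
    "dissociation_signal",
    "equilibrium_constants",
    "model_trace",
]


class Mode(str, enum.Enum):
    """Static measurement modes (nanolevers at rest).

    ``static_standard`` is the standard kinetics method (60 s association /
    300 s dissociation); ``static_weak_binder`` is the shortened weak-binder
    method (30 s / 60 s).  Dynamic (actuated) mode is out of scope.
    """

    STATIC_STANDARD = "static_standard"
    STATIC_WEAK_BINDER = "static_weak_binder"


@dataclass(frozen=True)
class PhaseMarkers:
    """Start times of the association and dissociation phases.

    Parameters
    ----------
    t_a : float
        Association start (s); signal before ``t_a`` is baseline.
    t_d : float
        Dissociation start (s), i.e. the switch from analyte to buffer flow.
    t_end : float
        End of the recorded trace (s).
    """

    t_a: float
    t_d: float
    t_end: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_a < self.t_d < self.t_end):
            raise InvalidParameterError(
                f"phase markers must satisfy 0 <= t_a < t_d < t_end, "
                f"got t_a={self.t_a}, t_d={self.t_d}, t_end={self.t_end}"
            )


@dataclass
class SensorgramTrace:
    """One time-resolved fluorescence record at a single analyte concentration.

    ``concentration == 0`` marks a blank (buffer-only) run.  ``meta`` is
    free-form; the simulator stores the ground-truth parameters there so
    recovery tests can compare against them.
    """

    time: np.ndarray
    signal: np.ndarray
    concentration: float
    phases: PhaseMarkers | None = None
    temperature: float = 25.0
    mode: Mode = Mode.STATIC_STANDARD
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise InvalidParameterError("time and signal must be 1-D")
        if self.time.shape != self.signal.shape:
            raise InvalidParameterError(
                f"time ({self.time.size}) and signal ({self.signal.size}) "
                "must have equal length"
            )
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            row = int(np.argmin(np.diff(self.time) > 0)) + 1
            raise InvalidParameterError(
                f"time must be strictly increasing (violated at index {row})"
            )
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise InvalidParameterError(
                f"concentration must be finite and >= 0, got {self.concentration}"
            )
        if isinstance(self.mode, str):
            self.mode = Mode(self.mode)

    @property
    def is_blank(self) -> bool:
        return self.concentration == 0.0

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class RateParameters:
    """Kinetic and per-trace signal parameters of the 1:1 model.

    Parameters
    ----------
    k_a : float
        Association rate constant (M^-1 s^-1), > 0.
    k_d : float
        Dissociation rate constant (s^-1), > 0.
    A : float
        Signal amplitude (% fluorescence change); may be negative for
        analytes that quench the reporter.
    y0 : float
        Baseline (%).
    f_res : float
        Residual bound fraction in [0, 1]; 0 means complete dissociation.
    """

    k_a: float
    k_d: float
    A: float = 1.0
    y0: float = 0.0
    f_res: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_a", "k_d", "A", "y0", "f_res"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v}")
        if self.k_a <= 0:
            raise InvalidParameterError(f"k_a must be > 0, got {self.k_a}")
        if self.k_d <= 0:
            raise InvalidParameterError(f"k_d must be > 0, got {self.k_d}")
        if not 0 <= self.f_res <= 1:
            raise InvalidParameterError(
                f"f_res must lie in [0, 1], got {self.f_res}"
            )


@dataclass(frozen=True)
class EquilibriumConstants:
    """Equilibrium association constant K_A (M^-1) and dissociation
    constant K_D (M); reciprocal of each other by construction."""

    K_A: float
    K_D: float

    def __post_init__(self) -> None:
        if self.K_A <= 0 or self.K_D <= 0:
            raise InvalidParameterError(
                f"constants must be > 0, got K_A={self.K_A}, K_D={self.K_D}"
            )


@dataclass(frozen=True)
class ObservedRate:
    """Pseudo-first-order observed association rate k_obs = k_a*c + k_d."""

    k_obs: float


def _check_rates(k_a: float, k_d: float) -> None:
    if not (math.isfinite(k_a) and math.isfinite(k_d)):
        raise InvalidParameterError(f"rates must be finite, got k_a={k_a}, k_d={k_d}")
    if k_a <= 0 or k_d <= 0:
        raise InvalidParameterError(f"rates must be > 0, got k_a={k_a}, k_d={k_d}")


def observed_rate(k_a: float, c: float, k_d: float) -> ObservedRate:
    """Observed association-phase rate ``k_obs = k_a * c + k_d`` (s^-1).

    At zero concentration k_obs reduces to k_d: during the association
    window the approach to equilibrium is governed by the sum of the
    forward pseudo-first-order rate and the back reaction.
    """
    _check_rates(k_a, k_d)
    if not math.isfinite(c) or c < 0:
        raise InvalidParameterError(f"concentration must be finite and >= 0, got {c}")
    return ObservedRate(k_obs=k_a * c + k_d)


def association_signal(
    t: float | np.ndarray,
    params: RateParameters,
    c: float,
    phases: PhaseMarkers,
) -> float | np.ndarray:
    """Association-phase signal F(t) = y0 + A*(1 - exp(-k_obs*(t - t_a))).

    Defined on ``t_a <= t <= t_d``.  Starts at the baseline ``y0`` and rises
    (or falls, for negative A) toward the plateau ``y0 + A``.
    """
    k_obs = observed_rate(params.k_a, c, params.k_d).k_obs
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < phases.t_a) or np.any(t_arr > phases.t_d):
        raise OutOfWindowError(
            f"association_signal defined on [{phases.t_a}, {phases.t_d}] s"
        )
    out = params.y0 + params.A * -np.expm1(-k_obs * (t_arr - phases.t_a))
    return float(out) if np.isscalar(t) else out


def dissociation_signal(
    t: float | np.ndarray,
    params: RateParameters,
    phases: PhaseMarkers,
    A_d: float,
) -> float | np.ndarray:
    """Dissociation-phase signal with an optional non-dissociating plateau.

    F(t) = y0 + A_d * (f_res + (1 - f_res) * exp(-k_d * (t - t_d))) for
    ``t >= t_d``: a decay from ``y0 + A_d`` toward ``y0 + A_d * f_res``.
    ``A_d`` is the signal height above baseline at the start of dissociation.
    """
    _check_rates(params.k_a, params.k_d)
    if not 0 <= params.f_res <= 1:
        raise InvalidParameterError(f"f_res must lie in [0, 1], got {params.f_res}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < phases.t_d):
        raise OutOfWindowError(f"dissociation_signal defined for t >= {phases.t_d} s")
    decay = np.exp(-params.k_d * (t_arr - phases.t_d))
    out = params.y0 + A_d * (params.f_res + (1.0 - params.f_res) * decay)
    return float(out) if np.isscalar(t) else out


def equilibrium_constants(k_a: float, k_d: float) -> EquilibriumConstants:
    """Equilibrium constants from the kinetic rates: K_A = k_a/k_d, K_D = k_d/k_a."""
    _check_rates(k_a, k_d)
    return EquilibriumConstants(K_A=k_a / k_d, K_D=k_d / k_a)


def model_trace(
    params: RateParameters,
    c: float,
    phases: PhaseMarkers,
    sampling_rate: float,
    *,
    time: Sequence[float] | np.ndarray | None = None,
    temperature: float = 25.0,
    mode: Mode = Mode.STATIC_STANDARD,
    label: str = "",
) -> SensorgramTrace:
    """Noise-free piecewise sensorgram over [0, t_end].

    Baseline ``y0`` before ``t_a``, the association rise on ``[t_a, t_d)``
    and the dissociation decay on ``[t_d, t_end]``.  The dissociation
    amplitude is pinned to the association value at ``t_d`` so the curve is
    continuous (one continuous response curve is what the instrument
    records).  Pass ``time`` to evaluate on an explicit grid instead of a
    uniform one.
    """
    if time is None:
        if not (math.isfinite(sampling_rate) and sampling_rate > 0):
            raise InvalidParameterError(
                f"sampling_rate must be > 0, got {sampling_rate}"
            )
        n = int(round(phases.t_end * sampling_rate)) + 1
        t = np.linspace(0.0, phases.t_end, n)
    else:
        t = np.asarray(time, dtype=float)
    signal = evaluate_piecewise(t, params, c, phases)
    return SensorgramTrace(
        time=t,
        signal=signal,
        concentration=c,
        phases=phases,
        temperature=temperature,
        mode=mode,
        label=label,
    )


def evaluate_piecewise(
    t: np.ndarray,
    params: RateParameters,
    c: float,
    phases: PhaseMarkers,
    *,
    A_d: float | None = None,
) -> np.ndarray:
    """Vectorized piecewise model evaluation on an arbitrary time grid.

    ``A_d=None`` pins the dissociation amplitude to the association value at
    ``t_d`` (continuity); an explicit ``A_d`` overrides it, which is what a
    fit with untied dissociation amplitudes uses.
    """
    t = np.asarray(t, dtype=float)
    k_obs = observed_rate(params.k_a, c, params.k_d).k_obs
    out = np.full(t.shape, params.y0, dtype=float)
    if c == 0.0:
        # no analyte, no complex: a blank stays at baseline
        return out
    assoc = (t >= phases.t_a) & (t < phases.t_d)
    dissoc = t >= phases.t_d
    out[assoc] = params.y0 + params.A * -np.expm1(-k_obs * (t[assoc] - phases.t_a))
    if A_d is None:
        A_d = params.A * -np.expm1(-k_obs * (phases.t_d - phases.t_a))
    decay = np.exp(-params.k_d * (t[dissoc] - phases.t_d))
    out[dissoc] = params.y0 + A_d * (params.f_res + (1.0 - params.f_res) * decay)
    return out
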