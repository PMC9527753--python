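"""Synthetic sensorgram series and docking-pose sets.

The generator emulates the statistical structure the downstream analysis
assumes: mono-exponential association at rate k_a*c + k_d, exponential
dissociation at rate k_d with an optional non-dissociating residual
fraction, per-trace amplitude and baseline, additive homoscedastic
Gaussian noise, and blank (zero-concentration) runs recorded before and
after the concentration series.

Per-trace amplitudes follow the 1:1 equilibrium saturation law
``A(c) = A_max * c / (c + K_D)`` by default, which reproduces the
concentration-signal correlation seen on real chips while the fit still
treats the amplitude as a free per-trace parameter.

Every stochastic function takes an explicit integer seed; there is no
hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidDesignError
from .models import (
    Mode,
    PhaseMarkers,
    RateParameters,
    SensorgramTrace,
    equilibrium_constants,
    model_trace,
)

__all__ = [
    "SeriesDesign",
    "NoiseSpec",
    "SiteSpec",
    "PoseSet",
    "dilution_ladder",
    "simulate_trace",
    "simulate_series",
    "simulate_pose_set",
]


def dilution_ladder(top: float, factor: float, n: int) -> tuple[float, ...]:
    """Descending concentration ladder: top, top/factor, ..., n values."""
    if top <= 0 or factor <= 1 or n < 1:
        raise InvalidDesignError(
            f"need top > 0, factor > 1, n >= 1; got {top}, {factor}, {n}"
        )
    return tuple(top / factor**i for i in range(n))


@dataclass(frozen=True)
class SeriesDesign:
    """Experimental design of one concentration series.

    ``baseline_duration`` seconds of buffer-only signal are recorded before
    the association phase starts so that every trace carries its own
    baseline window; the phase markers are derived from the three
    durations.  Blanks are measured before and after the analyte ladder.
    """

    concentrations: tuple[float, ...]
    association_duration: float
    dissociation_duration: float
    sampling_rate: float = 10.0
    baseline_duration: float = 10.0
    n_blanks_before: int = 1
    n_blanks_after: int = 1
    temperature: float = 25.0
    mode: Mode = Mode.STATIC_STANDARD
    dilution_factor: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", tuple(self.concentrations))
        if len(self.concentrations) == 0:
            raise InvalidDesignError("concentration list must not be empty")
        if any(c <= 0 for c in self.concentrations):
            raise InvalidDesignError("all series concentrations must be > 0")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise InvalidDesignError("series concentrations must be distinct")
        for name in ("association_duration", "dissociation_duration", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise InvalidDesignError(f"{name} must be > 0")
        if self.baseline_duration < 0:
            raise InvalidDesignError("baseline_duration must be >= 0")
        if self.n_blanks_before < 0 or self.n_blanks_after < 0:
            raise InvalidDesignError("blank counts must be >= 0")

    @property
    def phases(self) -> PhaseMarkers:
        t_a = self.baseline_duration
        t_d = t_a + self.association_duration
        return PhaseMarkers(t_a=t_a, t_d=t_d, t_end=t_d + self.dissociation_duration)

    @classmethod
    def eb_standard(cls, temperature: float = 25.0) -> "SeriesDesign":
        """Intercalator (ethidium bromide) design, static standard method:
        five concentrations 1e-6 ... 6.25e-8 M (factor 2), 60 s association,
        300 s dissociation."""
        return cls(
            concentrations=dilution_ladder(1e-6, 2.0, 5),
            association_duration=60.0,
            dissociation_duration=300.0,
            temperature=temperature,
            mode=Mode.STATIC_STANDARD,
            dilution_factor=2.0,
        )

    @classmethod
    def eb_weak_binder(cls, temperature: float = 25.0) -> "SeriesDesign":
        """Weak-binder method for fast kinetics: 30 s association, 60 s
        dissociation, same ethidium ladder."""
        return cls(
            concentrations=dilution_ladder(1e-6, 2.0, 5),
            association_duration=30.0,
            dissociation_duration=60.0,
            temperature=temperature,
            mode=Mode.STATIC_WEAK_BINDER,
            dilution_factor=2.0,
        )

    @classmethod
    def slow_binder(cls, temperature: float = 25.0) -> "SeriesDesign":
        """Slow, incompletely dissociating binders (alkylamino sulfonamides):
        2e-4 ... 2.5e-5 M (factor 2), 240 s association, 480 s dissociation."""
        return cls(
            concentrations=dilution_ladder(2e-4, 2.0, 4),
            association_duration=240.0,
            dissociation_duration=480.0,
            temperature=temperature,
            mode=Mode.STATIC_WEAK_BINDER,
            dilution_factor=2.0,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise, expressed relative to the series full scale.

    ``sigma_pct_fullscale`` is the noise standard deviation as a percentage
    of the maximum noise-free amplitude of the series (so 0.5 means the
    noise SD is 0.5% of the largest response).  ``drift_per_s`` adds an
    optional linear baseline drift in %/s.
    """

    sigma_pct_fullscale: float = 0.5
    drift_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_pct_fullscale < 0:
            raise InvalidDesignError("sigma_pct_fullscale must be >= 0")


def _amplitude_at(truth: RateParameters, c: float) -> float:
    """Saturation law A(c) = A_max * c / (c + K_D); truth.A is A_max."""
    K_D = equilibrium_constants(truth.k_a, truth.k_d).K_D
    return truth.A * c / (c + K_D)


def simulate_trace(
    truth: RateParameters,
    c: float,
    design: SeriesDesign,
    noise: NoiseSpec,
    *,
    rng: np.random.Generator | None = None,
    full_scale: float | None = None,
    label: str = "",
) -> SensorgramTrace:
    """One noisy sensorgram at concentration ``c`` (0 for a blank).

    ``truth.A`` is interpreted as the saturating amplitude A_max; the trace
    amplitude follows the saturation law.  ``full_scale`` sets the signal
    scale the noise percentage refers to (defaults to this trace's own
    amplitude; :func:`simulate_series` passes the series-wide scale so the
    noise is homoscedastic across traces).  The ground truth is recorded in
    ``trace.meta['truth']``.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    A_c = _amplitude_at(truth, c) if c > 0 else 0.0
    params_c = replace(truth, A=A_c if c > 0 else truth.A)
    trace = model_trace(
        params_c,
        c,
        design.phases,
        design.sampling_rate,
        temperature=design.temperature,
        mode=design.mode,
        label=label,
    )
    scale = abs(full_scale) if full_scale is not None else abs(A_c)
    if scale == 0.0:
        scale = abs(truth.A)
    sigma = noise.sigma_pct_fullscale / 100.0 * scale
    if sigma > 0:
        trace.signal = trace.signal + rng.normal(0.0, sigma, size=trace.signal.shape)
    if noise.drift_per_s != 0.0:
        trace.signal = trace.signal + noise.drift_per_s * trace.time
    trace.meta["truth"] = {
        "k_a": truth.k_a,
        "k_d": truth.k_d,
        "f_res": truth.f_res,
        "A": params_c.A,
        "y0": truth.y0,
        "sigma": sigma,
    }
    return trace


def simulate_series(
    truth: RateParameters,
    design: SeriesDesign,
    noise: NoiseSpec,
    *,
    free_amplitudes: bool = False,
) -> list[SensorgramTrace]:
    """Blanks-before, descending ladder, blanks-after series of noisy traces.

    With ``free_amplitudes=True`` per-trace amplitudes are drawn uniformly
    in [0.3, 1] * A_max instead of following the saturation law.
    """
    rng = np.random.default_rng(noise.seed)
    top = max(design.concentrations)
    full_scale = abs(_amplitude_at(truth, top))
    traces: list[SensorgramTrace] = []

    def blank(i: int, when: str) -> SensorgramTrace:
        return simulate_trace(
            truth, 0.0, design, noise, rng=rng, full_scale=full_scale,
            label=f"blank_{when}_{i}",
        )

    for i in range(design.n_blanks_before):
        traces.append(blank(i, "pre"))
    for j, c in enumerate(design.concentrations):
        t = truth
        if free_amplitudes:
            t = replace(truth, A=truth.A * rng.uniform(0.3, 1.0))
            # free amplitude: bypass the saturation law by scaling so that
            # _amplitude_at returns the drawn value at this concentration
            K_D = equilibrium_constants(truth.k_a, truth.k_d).K_D
            t = replace(t, A=t.A * (c + K_D) / c)
        traces.append(
            simulate_trace(
                t, c, design, noise, rng=rng, full_scale=full_scale,
                label=f"conc_{j}",
            )
        )
    for i in range(design.n_blanks_after):
        traces.append(blank(i, "post"))
    return traces


# ---------------------------------------------------------------------------
# docking pose sets


@dataclass(frozen=True)
class SiteSpec:
    """Generator spec for one synthetic binding site.

    ``centroid`` (Å), isotropic positional ``spread`` (Å, SD), relative
    ``weight`` (abundance), and Gaussian binding-energy magnitude
    (kcal/mol; more positive = stronger binding)."""

    centroid: tuple[float, float, float]
    spread: float
    weight: float
    energy_mean: float
    energy_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise InvalidDesignError(f"spread must be > 0, got {self.spread}")
        if self.weight < 0 or self.energy_sd < 0:
            raise InvalidDesignError("weight and energy_sd must be >= 0")


@dataclass
class PoseSet:
    """Docked pose centroids (N x 3, Å) with binding-energy magnitudes.

    ``true_site`` records the generating site index for synthetic sets
    (hidden truth used by clustering recovery tests); it is -1 for poses
    read from a file.
    """

    ids: list[str]
    coords: np.ndarray
    energies: np.ndarray
    true_site: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.ids) != self.coords.shape[0] or len(self.ids) != self.energies.size:
            raise InvalidDesignError("ids, coords and energies lengths differ")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidDesignError("pose coordinates must be finite")
        if np.any(self.energies < 0) or not np.all(np.isfinite(self.energies)):
            raise InvalidDesignError(
                "energies are magnitudes and must be finite and >= 0"
            )

    def __len__(self) -> int:
        return len(self.ids)


def simulate_pose_set(
    site_specs: Sequence[SiteSpec],
    n_poses: int,
    seed: int,
) -> PoseSet:
    """Draw ``n_poses`` docked poses from a mixture of binding sites.

    Site assignment is multinomial in the normalized weights; positions get
    isotropic Gaussian scatter around the site centroid and energies are
    Gaussian, floored at zero (energies are magnitudes).
    """
    if n_poses <= 0:
        raise InvalidDesignError(f"n_poses must be > 0, got {n_poses}")
    specs = list(site_specs)
    if not specs:
        raise InvalidDesignError("need at least one site spec")
    weights = np.array([s.weight for s in specs], dtype=float)
    if weights.sum() <= 0:
        raise InvalidDesignError("site weights must sum to a positive value")
    rng = np.random.default_rng(seed)
    assign = rng.choice(len(specs), size=n_poses, p=weights / weights.sum())
    coords = np.empty((n_poses, 3))
    energies = np.empty(n_poses)
    for i, s in enumerate(assign):
        spec = specs[s]
        coords[i] = rng.normal(spec.centroid, spec.spread)
        energies[i] = max(0.0, rng.normal(spec.energy_mean, spec.energy_sd))
    ids = [f"pose_{i:04d}" for i in range(n_poses)]
    return PoseSet(ids=ids, coords=coords, energies=energies, true_site=assign)
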