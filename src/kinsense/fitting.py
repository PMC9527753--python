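"""Global weighted least-squares estimation of 1:1 binding kinetics.

All traces of a concentration series are fitted simultaneously ("global
analysis"): the rate constants k_a and k_d (and, for incompletely
dissociating analytes, the residual bound fraction f_res) are shared
across traces while the amplitude A and baseline y0 are free per trace.
Sharing the rates across concentrations is what makes k_a and k_d
separately identifiable — a single trace only pins down the composite
observed rate k_obs = k_a*c + k_d.

The optimizer is bounded trust-region least squares (via lmfit); initial
values come from classical linearizations (log-linear dissociation tail,
linearized association, k_obs-vs-c regression).  Uncertainties are
available either from the local curvature at the optimum or from seeded
residual-resampling bootstrap; replicate experiments are aggregated as
mean +/- sample SD per parameter, with K_A/K_D summarized from the
per-replicate values rather than from ratios of means.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np

from .errors import (
    AggregationMismatchError,
    ConvergenceError,
    GuessFailureError,
    IdentifiabilityError,
    InvalidDesignError,
)
from .models import (
    EquilibriumConstants,
    RateParameters,
    SensorgramTrace,
    equilibrium_constants,
    evaluate_piecewise,
)

__all__ = [
    "DissociationModel",
    "Weighting",
    "ModelSpec",
    "TraceSignal",
    "FitResult",
    "ReplicateSummary",
    "initial_guess",
    "fit_global",
    "select_dissociation_model",
    "estimate_uncertainty",
    "aggregate_replicates",
]

# relative tolerance on cost change at which the optimizer stops
_FTOL = 1e-14
_XTOL = 1e-14


class DissociationModel(str, enum.Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"


class Weighting(str, enum.Enum):
    UNIFORM = "uniform"
    INVERSE_VARIANCE = "inverse_variance"


@dataclass(frozen=True)
class ModelSpec:
    """What to fit and how to weight it.

    ``incomplete`` adds the shared residual bound fraction f_res in [0, 1].
    ``tie_dissociation_amplitude`` pins the dissociation amplitude of each
    trace to the association value at t_d (continuity); untying it adds one
    free amplitude per trace, useful for truncated traces.
    """

    dissociation_model: DissociationModel = DissociationModel.COMPLETE
    share_amplitudes: bool = False
    weighting: Weighting = Weighting.UNIFORM
    tie_dissociation_amplitude: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.dissociation_model, str):
            object.__setattr__(
                self, "dissociation_model", DissociationModel(self.dissociation_model)
            )
        if isinstance(self.weighting, str):
            object.__setattr__(self, "weighting", Weighting(self.weighting))

    @property
    def n_shared(self) -> int:
        return 3 if self.dissociation_model is DissociationModel.INCOMPLETE else 2


@dataclass(frozen=True)
class TraceSignal:
    """Per-trace signal parameters of a fitted series."""

    label: str
    concentration: float
    A: float
    y0: float
    A_d: float | None = None  # only when the dissociation amplitude is untied


@dataclass
class FitResult:
    """Outcome of a global fit.

    ``params`` carries the shared rates (with the amplitude/baseline of the
    highest-concentration trace as representative values); ``per_trace``
    has every trace's A and y0.  ``constants`` always equals
    ``equilibrium_constants(k_a, k_d)`` of the fitted rates.
    ``standard_errors``/``covariance`` cover the shared parameters only and
    are ``None`` when unavailable (singular curvature).
    """

    params: RateParameters
    per_trace: list[TraceSignal]
    constants: EquilibriumConstants
    standard_errors: dict[str, float] | None
    covariance: np.ndarray | None
    shared_names: tuple[str, ...]
    residual_sum_squares: float
    n_points: int
    information_criterion: float
    model: ModelSpec
    converged: bool
    message: str = ""
    uncertainty_method: str = "curvature"
    meta: dict = field(default_factory=dict)

    @property
    def k_a(self) -> float:
        return self.params.k_a

    @property
    def k_d(self) -> float:
        return self.params.k_d

    @property
    def f_res(self) -> float:
        return self.params.f_res


# ---------------------------------------------------------------------------
# initial guesses


def _usable(series: Sequence[SensorgramTrace]) -> list[SensorgramTrace]:
    """Non-blank traces that carry phase markers; blanks are excluded."""
    return [tr for tr in series if not tr.is_blank and tr.phases is not None]


def _trace_windows(tr: SensorgramTrace):
    p = tr.phases
    pre = tr.time < p.t_a
    assoc = (tr.time >= p.t_a) & (tr.time < p.t_d)
    dissoc = tr.time >= p.t_d
    return pre, assoc, dissoc


def _guess_one(tr: SensorgramTrace) -> dict:
    """Linearized guesses for a single trace; raises on unusable data."""
    pre, assoc, dissoc = _trace_windows(tr)
    if assoc.sum() < 3 or dissoc.sum() < 3:
        raise GuessFailureError(
            f"trace {tr.label!r}: need >= 3 points in each phase",
            {"label": tr.label, "assoc_points": int(assoc.sum()),
             "dissoc_points": int(dissoc.sum())},
        )
    y0 = float(np.mean(tr.signal[pre])) if pre.any() else float(tr.signal[0])

    # association: amplitude from the late-association plateau, k_obs from
    # the log-linear form ln(1 - (F - y0)/A) = -k_obs (t - t_a)
    s_a = tr.signal[assoc]
    t_a_grid = tr.time[assoc] - tr.phases.t_a
    n_tail = max(3, assoc.sum() // 20)
    A = float(np.mean(s_a[-n_tail:])) - y0
    if A == 0.0:
        raise GuessFailureError(
            f"trace {tr.label!r}: flat association window",
            {"label": tr.label, "step": "association"},
        )
    z = 1.0 - (s_a - y0) / A
    mask = z > 1e-2
    if mask.sum() < 2:
        raise GuessFailureError(
            f"trace {tr.label!r}: association rise too fast to linearize",
            {"label": tr.label, "step": "association"},
        )
    slope = np.polyfit(t_a_grid[mask], np.log(z[mask]), 1)[0]
    k_obs = -float(slope)
    if not np.isfinite(k_obs) or k_obs <= 0:
        raise GuessFailureError(
            f"trace {tr.label!r}: non-positive observed rate",
            {"label": tr.label, "step": "association", "k_obs": k_obs},
        )

    # dissociation: plateau from the tail, k_d from the log-linear decay
    s_d = tr.signal[dissoc]
    t_d_grid = tr.time[dissoc] - tr.phases.t_d
    n_tail = max(3, dissoc.sum() // 20)
    plateau = float(np.mean(s_d[-n_tail:]))
    A_d0 = float(s_d[0]) - plateau
    k_d = np.nan
    if A_d0 != 0.0:
        zd = (s_d - plateau) / A_d0
        maskd = zd > 2e-2
        if maskd.sum() >= 3:
            slope_d = np.polyfit(t_d_grid[maskd], np.log(zd[maskd]), 1)[0]
            k_d = -float(slope_d)
    A_start = float(s_d[0]) - y0
    f_res = 0.0
    if A_start != 0.0:
        f_res = float(np.clip((plateau - y0) / A_start, 0.0, 1.0))
    return {
        "y0": y0, "A": A, "k_obs": k_obs, "k_d": k_d, "f_res": f_res,
        "c": tr.concentration, "weight": abs(A),
    }


def initial_guess(series: Sequence[SensorgramTrace]) -> RateParameters:
    """Starting values for the global fit from classical linearizations.

    k_d comes from log-linear regression of the dissociation tails
    (amplitude-weighted across traces), per-trace observed rates from the
    linearized association, and k_a from the least-squares slope of k_obs
    versus concentration (floored at a small positive value).  A and y0 are
    taken from the highest-concentration trace.  Blank traces are ignored.
    """
    usable = _usable(series)
    if not usable:
        raise GuessFailureError(
            "no non-blank trace with phase markers", {"n_traces": len(series)}
        )
    guesses = [_guess_one(tr) for tr in usable]

    k_ds = np.array([g["k_d"] for g in guesses])
    wts = np.array([g["weight"] for g in guesses])
    ok = np.isfinite(k_ds) & (k_ds > 0)
    if ok.any():
        k_d = float(np.average(k_ds[ok], weights=wts[ok]))
    else:
        raise GuessFailureError(
            "could not extract a dissociation rate from any trace",
            {"per_trace_k_d": k_ds.tolist()},
        )

    cs = np.array([g["c"] for g in guesses])
    k_obs = np.array([g["k_obs"] for g in guesses])
    if len(guesses) >= 2 and len(set(cs.tolist())) >= 2:
        slope = np.polyfit(cs, k_obs, 1)[0]
    else:
        slope = (k_obs[0] - k_d) / cs[0]
    floor = 1e-3 * max(k_obs.max(), k_d) / cs.max()
    k_a = float(max(slope, floor))

    top = guesses[int(np.argmax(cs))]
    f_res = float(np.average([g["f_res"] for g in guesses], weights=wts))
    return RateParameters(k_a=k_a, k_d=k_d, A=top["A"], y0=top["y0"], f_res=f_res)


# ---------------------------------------------------------------------------
# global fit


def _series_for_fit(series: Sequence[SensorgramTrace]) -> list[SensorgramTrace]:
    usable = _usable(series)
    concs = {tr.concentration for tr in usable}
    if len(concs) < 2:
        raise IdentifiabilityError(
            "global fitting needs >= 2 distinct non-blank concentrations; a "
            "single trace determines only the composite rate k_obs = k_a*c + k_d"
        )
    t_as = {tr.phases.t_a for tr in usable}
    t_ds = {tr.phases.t_d for tr in usable}
    if len(t_as) != 1 or len(t_ds) != 1:
        raise InvalidDesignError(
            "all traces in a series must share association/dissociation start times"
        )
    return usable


def _trace_weight(tr: SensorgramTrace, weighting: Weighting) -> float:
    if weighting is Weighting.UNIFORM:
        return 1.0
    pre, _, _ = _trace_windows(tr)
    sd = float(np.std(tr.signal[pre], ddof=1)) if pre.sum() >= 3 else 0.0
    return 1.0 / sd if sd > 0 else 1.0


def _build_parameters(
    usable: list[SensorgramTrace], guess: RateParameters, model: ModelSpec
) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    pars.add("k_a", value=guess.k_a, min=1e-15)
    pars.add("k_d", value=guess.k_d, min=1e-15)
    incomplete = model.dissociation_model is DissociationModel.INCOMPLETE
    pars.add(
        "f_res",
        value=min(max(guess.f_res, 1e-4), 1 - 1e-4) if incomplete else 0.0,
        min=0.0, max=1.0, vary=incomplete,
    )
    for i, tr in enumerate(usable):
        try:
            g = _guess_one(tr)
        except GuessFailureError:
            g = {"A": guess.A, "y0": guess.y0}
        pars.add(f"A_{i}", value=g["A"] if g["A"] != 0 else guess.A)
        pars.add(f"y0_{i}", value=g["y0"])
        if not model.tie_dissociation_amplitude:
            pars.add(f"Ad_{i}", value=g["A"] if g["A"] != 0 else guess.A)
    return pars


def _residuals(
    pars: lmfit.Parameters,
    usable: list[SensorgramTrace],
    model: ModelSpec,
    weights: np.ndarray,
) -> np.ndarray:
    v = pars.valuesdict()
    out = []
    for i, tr in enumerate(usable):
        p = RateParameters(
            k_a=max(v["k_a"], 1e-300), k_d=max(v["k_d"], 1e-300),
            A=v[f"A_{i}"], y0=v[f"y0_{i}"],
            f_res=min(max(v["f_res"], 0.0), 1.0),
        )
        A_d = None if model.tie_dissociation_amplitude else v[f"Ad_{i}"]
        pred = evaluate_piecewise(tr.time, p, tr.concentration, tr.phases, A_d=A_d)
        out.append((pred - tr.signal) * weights[i])
    return np.concatenate(out)


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected Akaike criterion for Gaussian residuals."""
    rss = max(rss, np.finfo(float).tiny)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def fit_global(
    series: Sequence[SensorgramTrace],
    model: ModelSpec | None = None,
    seed: int = 0,
    *,
    n_starts: int = 1,
    require_convergence: bool = False,
) -> FitResult:
    """Fit all non-blank traces of a series simultaneously.

    Shared parameters: k_a, k_d (and f_res for the incomplete model);
    per-trace parameters: amplitude A and baseline y0.  Blanks are excluded
    (they belong in blank correction, not in the fit).  ``n_starts > 1``
    restarts the optimizer from seeded perturbations of the initial guess
    and keeps the lowest-cost solution, guarding against local minima.
    Non-convergence is flagged on the result, never silent;
    ``require_convergence=True`` raises instead.
    """
    model = model or ModelSpec()
    usable = _series_for_fit(series)
    guess = initial_guess(usable)

    weights = np.array([_trace_weight(tr, model.weighting) for tr in usable])
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        g = guess
        if start > 0:
            g = replace(
                guess,
                k_a=guess.k_a * rng.lognormal(0, 0.5),
                k_d=guess.k_d * rng.lognormal(0, 0.5),
            )
        pars = _build_parameters(usable, g, model)
        res = lmfit.minimize(
            _residuals, pars, args=(usable, model, weights),
            method="least_squares", ftol=_FTOL, xtol=_XTOL, gtol=1e-14,
            x_scale="jac",
        )
        if best is None or res.chisqr < best.chisqr:
            best = res
    res = best

    v = res.params.valuesdict()
    incomplete = model.dissociation_model is DissociationModel.INCOMPLETE
    shared = ("k_a", "k_d") + (("f_res",) if incomplete else ())
    i_top = int(np.argmax([tr.concentration for tr in usable]))
    params = RateParameters(
        k_a=v["k_a"], k_d=v["k_d"], A=v[f"A_{i_top}"], y0=v[f"y0_{i_top}"],
        f_res=v["f_res"] if incomplete else 0.0,
    )
    per_trace = [
        TraceSignal(
            label=tr.label, concentration=tr.concentration,
            A=v[f"A_{i}"], y0=v[f"y0_{i}"],
            A_d=None if model.tie_dissociation_amplitude else v[f"Ad_{i}"],
        )
        for i, tr in enumerate(usable)
    ]

    se, cov = _shared_uncertainty(res, shared)
    n = int(res.ndata)
    rss = float(np.sum(res.residual**2))
    result = FitResult(
        params=params,
        per_trace=per_trace,
        constants=equilibrium_constants(params.k_a, params.k_d),
        standard_errors=se,
        covariance=cov,
        shared_names=shared,
        residual_sum_squares=rss,
        n_points=n,
        information_criterion=_aicc(rss, n, int(res.nvarys)),
        model=model,
        converged=bool(res.success),
        message=str(res.message),
    )
    if require_convergence and not result.converged:
        raise ConvergenceError(f"global fit did not converge: {result.message}")
    k_obs_max = params.k_a * max(tr.concentration for tr in usable) + params.k_d
    t_assoc = usable[0].phases.t_d - usable[0].phases.t_a
    if k_obs_max * t_assoc < 1:
        warnings.warn(
            "association window shorter than 1/k_obs: the plateau is not "
            "reached and rate estimates may be poorly determined",
            stacklevel=2,
        )
    return result


def _shared_uncertainty(res, shared: tuple[str, ...]):
    """Curvature SEs/covariance restricted to the shared parameters."""
    if res.covar is None:
        return None, None
    names = [p for p in res.params if res.params[p].vary]
    try:
        idx = [names.index(s) for s in shared]
    except ValueError:
        return None, None
    cov = res.covar[np.ix_(idx, idx)]
    diag = np.diag(cov)
    if np.any(~np.isfinite(diag)) or np.any(diag < 0):
        return None, None
    se = {s: float(np.sqrt(d)) for s, d in zip(shared, diag)}
    return se, cov


def select_dissociation_model(
    series: Sequence[SensorgramTrace], seed: int = 0
) -> tuple[ModelSpec, FitResult]:
    """Choose between complete and incomplete dissociation by AICc.

    Both models are fitted; the one with the lower small-sample-corrected
    information criterion wins and ties favor the simpler (complete) model.
    """
    complete = ModelSpec(dissociation_model=DissociationModel.COMPLETE)
    incomplete = ModelSpec(dissociation_model=DissociationModel.INCOMPLETE)
    fit_c = fit_global(series, complete, seed=seed)
    fit_i = fit_global(series, incomplete, seed=seed)
    if fit_i.information_criterion < fit_c.information_criterion:
        return incomplete, fit_i
    return complete, fit_c


# ---------------------------------------------------------------------------
# uncertainty and replicate aggregation


def estimate_uncertainty(
    fit: FitResult,
    series: Sequence[SensorgramTrace],
    method: str = "curvature",
    n_boot: int = 200,
    seed: int = 0,
) -> FitResult:
    """Standard errors of the shared parameters.

    ``curvature`` uses the local quadratic approximation at the optimum
    (already computed during fitting); ``bootstrap`` resamples residuals
    within each trace, refits ``n_boot`` times with the given seed, and
    reports the SD of the refitted shared parameters.
    """
    if not fit.converged:
        raise ConvergenceError("uncertainty estimation requires a converged fit")
    if method == "curvature":
        if fit.standard_errors is None:
            return replace_result(
                fit, uncertainty_method="curvature",
                message=fit.message + " [curvature singular: SEs unavailable]",
            )
        return replace_result(fit, uncertainty_method="curvature")
    if method != "bootstrap":
        raise ValueError(f"unknown uncertainty method {method!r}")

    usable = _series_for_fit(series)
    rng = np.random.default_rng(seed)
    # model prediction at the optimum, per trace
    preds, resids = [], []
    for i, tr in enumerate(usable):
        ts = fit.per_trace[i]
        p = RateParameters(
            k_a=fit.k_a, k_d=fit.k_d, A=ts.A, y0=ts.y0, f_res=fit.f_res
        )
        pred = evaluate_piecewise(tr.time, p, tr.concentration, tr.phases, A_d=ts.A_d)
        preds.append(pred)
        resids.append(tr.signal - pred)
    samples = {name: [] for name in fit.shared_names}
    for _ in range(n_boot):
        boot = []
        for tr, pred, r in zip(usable, preds, resids):
            idx = rng.integers(0, r.size, size=r.size)
            boot.append(
                SensorgramTrace(
                    time=tr.time, signal=pred + r[idx],
                    concentration=tr.concentration, phases=tr.phases,
                    temperature=tr.temperature, mode=tr.mode, label=tr.label,
                )
            )
        bfit = fit_global(boot, fit.model, seed=0)
        for name in fit.shared_names:
            samples[name].append(getattr(bfit.params, name))
    se = {name: float(np.std(vals, ddof=1)) for name, vals in samples.items()}
    return replace_result(fit, standard_errors=se, uncertainty_method="bootstrap")


def replace_result(fit: FitResult, **kw) -> FitResult:
    d = {f: getattr(fit, f) for f in (
        "params", "per_trace", "constants", "standard_errors", "covariance",
        "shared_names", "residual_sum_squares", "n_points",
        "information_criterion", "model", "converged", "message",
        "uncertainty_method", "meta",
    )}
    d.update(kw)
    return FitResult(**d)


@dataclass
class ReplicateSummary:
    """Mean +/- sample SD of each parameter over replicate experiments.

    K_A and K_D are summarized from the per-replicate values (the mean of
    ratios, not the ratio of means)."""

    system: str
    temperature: float
    mode: str
    n_replicates: int
    stats: dict[str, tuple[float, float]]  # name -> (mean, sd)


_META_KEYS = ("system", "temperature", "mode")


def aggregate_replicates(results: Sequence[FitResult]) -> ReplicateSummary:
    """Combine >= 2 converged replicate fits of the same system."""
    results = list(results)
    if len(results) < 2:
        raise AggregationMismatchError("need >= 2 replicate results")
    if not all(r.converged for r in results):
        raise AggregationMismatchError("all replicate fits must have converged")
    keys = [tuple(r.meta.get(k) for k in _META_KEYS) for r in results]
    if len(set(keys)) != 1:
        raise AggregationMismatchError(
            f"replicates describe different systems: {sorted(set(keys))}"
        )
    names = list(results[0].shared_names) + ["K_A", "K_D"]

    def values(name: str) -> np.ndarray:
        if name in ("K_A", "K_D"):
            return np.array([getattr(r.constants, name) for r in results])
        return np.array([getattr(r.params, name) for r in results])

    stats = {
        name: (float(np.mean(v)), float(np.std(v, ddof=1)))
        for name, v in ((n, values(n)) for n in names)
    }
    system, temperature, mode = keys[0]
    return ReplicateSummary(
        system=str(system or ""),
        temperature=float(temperature) if temperature is not None else float("nan"),
        mode=str(mode or ""),
        n_replicates=len(results),
        stats=stats,
    )
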