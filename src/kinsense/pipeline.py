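"""High-level orchestration: blank-correct, QC, fit, report.

This is the function stack behind the ``kinsense fit`` command; library
users can call :func:`analyze_series` directly on in-memory traces.
"""

from __future__ import annotations

import warnings
from typing import Sequence

from .fitting import (
    DissociationModel,
    FitResult,
    ModelSpec,
    Weighting,
    fit_global,
    select_dissociation_model,
)
from .models import SensorgramTrace
from .qc import blank_correct, linearity_check, percent_change

__all__ = ["analyze_series"]


def analyze_series(
    series: Sequence[SensorgramTrace],
    model: str = "auto",
    weighting: str = "uniform",
    seed: int = 0,
    *,
    meta: dict | None = None,
) -> tuple[FitResult, dict]:
    """Full single-series analysis.

    Blank traces are averaged and subtracted, every analyte trace gets a
    percent-change reliability flag, the concentration-response linearity
    is summarized, and the series is fitted globally.  ``model`` is
    ``complete``, ``incomplete`` or ``auto`` (AICc selection between the
    two).  Returns ``(fit, qc_record)``.
    """
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        corrected = blank_correct(series)
    qc: dict = {
        "warnings": [str(w.message) for w in caught],
        "n_blanks": sum(tr.is_blank for tr in series),
        "traces": [],
    }
    amplitudes = []
    for tr in corrected:
        peak, reliable = percent_change(tr)
        qc["traces"].append(
            {
                "label": tr.label,
                "concentration": tr.concentration,
                "max_percent_change": peak,
                "reliable": reliable,
            }
        )
        amplitudes.append((tr.concentration, peak))
    if len(amplitudes) >= 3 and len({c for c, _ in amplitudes}) >= 2:
        lin = linearity_check(amplitudes)
        qc["linearity"] = {
            "slope": lin.slope,
            "intercept": lin.intercept,
            "r_squared": lin.r_squared,
            "n_points": lin.n_points,
            "degenerate": lin.degenerate,
        }

    if model == "auto":
        spec, fit = select_dissociation_model(corrected, seed=seed)
    else:
        spec = ModelSpec(
            dissociation_model=DissociationModel(model),
            weighting=Weighting(weighting),
        )
        fit = fit_global(corrected, spec, seed=seed)
    if meta:
        fit.meta.update(meta)
    return fit, qc
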