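"""Quality checks and reporting for sensorgram series.

Covers blank correction (mean of the zero-concentration runs recorded
before and after a series), the percent-fluorescence-change reliability
flag (responses below about 1% give rate constants with high scatter),
concentration-response linearity, and rendering of kinetic summary tables
in the conventional "(value +/- SD) x 10^n" style at three significant
figures.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidDesignError
from .models import SensorgramTrace

__all__ = [
    "RELIABILITY_THRESHOLD_PCT",
    "LinearityResult",
    "blank_correct",
    "percent_change",
    "linearity_check",
    "format_quantity",
    "parse_quantity",
    "kinetic_table",
]

# responses below ~1 % fluorescence change yield poorly determined rates
RELIABILITY_THRESHOLD_PCT = 1.0


@dataclass(frozen=True)
class LinearityResult:
    """OLS line through (concentration, response) points."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not 0 <= self.r_squared <= 1:
            raise InvalidDesignError(f"r_squared out of [0, 1]: {self.r_squared}")


def blank_correct(series: Sequence[SensorgramTrace]) -> list[SensorgramTrace]:
    """Subtract the pointwise mean of the blank runs from every analyte trace.

    Blanks (concentration 0) are averaged on the union of their grids and
    linearly interpolated onto each analyte trace's time grid before
    subtraction; blanks are removed from the output.  With no blanks the
    input analyte traces are returned unchanged with a warning.
    """
    blanks = [tr for tr in series if tr.is_blank]
    analytes = [tr for tr in series if not tr.is_blank]
    if not blanks:
        warnings.warn("no blank traces found; returning data uncorrected",
                      stacklevel=2)
        return list(analytes)
    out = []
    for tr in analytes:
        correction = np.mean(
            [np.interp(tr.time, b.time, b.signal) for b in blanks], axis=0
        )
        new = SensorgramTrace(
            time=tr.time.copy(),
            signal=tr.signal - correction,
            concentration=tr.concentration,
            phases=tr.phases,
            temperature=tr.temperature,
            mode=tr.mode,
            label=tr.label,
            meta={**tr.meta, "blank_corrected": True, "n_blanks": len(blanks)},
        )
        out.append(new)
    return out


def percent_change(trace: SensorgramTrace) -> tuple[float, bool]:
    """Peak percent fluorescence change over the association window.

    The baseline is the mean signal before t_a (robust to single-sample
    noise); the peak is the largest absolute deviation from it within
    [t_a, t_d].  Returns ``(peak %dF, reliable)`` where responses below
    about 1% are flagged unreliable because the derived rate constants
    carry high standard deviations.
    """
    if trace.phases is None:
        raise InvalidDesignError("percent_change needs phase markers")
    p = trace.phases
    pre = trace.time < p.t_a
    assoc = (trace.time >= p.t_a) & (trace.time <= p.t_d)
    if not assoc.any():
        raise InvalidDesignError("trace has no association window samples")
    baseline = float(np.mean(trace.signal[pre])) if pre.any() else float(trace.signal[0])
    peak = float(np.max(np.abs(trace.signal[assoc] - baseline)))
    return peak, peak >= RELIABILITY_THRESHOLD_PCT


def linearity_check(
    points: Sequence[tuple[float, float]]
) -> LinearityResult:
    """OLS fit of response versus concentration with R².

    Requires >= 3 points over >= 2 distinct concentrations.  Constant
    responses give slope 0 and R² reported as 0 with the degenerate flag.
    """
    pts = list(points)
    if len(pts) < 3:
        raise InvalidDesignError("linearity check needs >= 3 points")
    c = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.unique(c).size < 2:
        raise InvalidDesignError("linearity check needs >= 2 distinct concentrations")
    if np.allclose(y, y[0]):
        return LinearityResult(0.0, float(y[0]), 0.0, len(pts), degenerate=True)
    res = stats.linregress(c, y)
    return LinearityResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(pts),
    )


# ---------------------------------------------------------------------------
# table rendering


def format_quantity(value: float, sd: float) -> str:
    """Render ``value +/- sd`` at 3 significant figures.

    Values whose decade lies in [-1, 2] print as plain decimals
    ("0.358 ± 0.007", "72.7 ± 3.6"); others use the shared-exponent form
    "(6.98 ± 0.63) × 10^5".  The SD is printed with the same number of
    decimal places as the value mantissa.
    """
    if value == 0:
        return f"0.00 ± {sd:.2f}"
    n = math.floor(math.log10(abs(value)))
    if -1 <= n <= 2:
        decimals = max(0, 2 - n)
        return f"{value:.{decimals}f} ± {sd:.{decimals}f}"
    mant = value / 10**n
    mant_sd = sd / 10**n
    return f"({mant:.2f} ± {mant_sd:.2f}) × 10^{n}"


_QTY_RE = re.compile(
    r"^\(?\s*(-?[\d.]+)\s*±\s*([\d.]+)\s*\)?(?:\s*×\s*10\^(-?\d+))?$"
)


def parse_quantity(text: str) -> tuple[float, float]:
    """Inverse of :func:`format_quantity` (value, sd)."""
    m = _QTY_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse quantity {text!r}")
    value, sd = float(m.group(1)), float(m.group(2))
    if m.group(3) is not None:
        scale = 10.0 ** int(m.group(3))
        value *= scale
        sd *= scale
    return value, sd


_TABLE_COLUMNS = ("k_a", "k_d", "K_D", "K_A")
_HEADERS = {
    "k_a": "k_a [M^-1 s^-1]",
    "k_d": "k_d [s^-1]",
    "K_D": "K_D [M]",
    "K_A": "K_A [M^-1]",
}


def kinetic_table(rows: Sequence[dict]) -> str:
    """Tab-separated kinetic summary table.

    Each row needs ``system``, ``temperature``, ``mode`` and, for each of
    k_a, k_d, K_D, K_A, a ``(mean, sd)`` pair (e.g. from
    :class:`~kinsense.fitting.ReplicateSummary.stats`).  Rows with missing
    fields are skipped with a warning naming the reason.  Columns follow
    the conventional order k_a, k_d, K_D, K_A.
    """
    lines = [
        "\t".join(["system", "temp [C]", "mode"] + [_HEADERS[c] for c in _TABLE_COLUMNS])
    ]
    for row in rows:
        missing = [k for k in ("system", "temperature", "mode", *_TABLE_COLUMNS)
                   if k not in row]
        if missing:
            warnings.warn(f"skipping table row (missing {missing})", stacklevel=2)
            continue
        cells = [str(row["system"]), f"{row['temperature']:g}", str(row["mode"])]
        for col in _TABLE_COLUMNS:
            mean, sd = row[col]
            cells.append(format_quantity(mean, sd))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
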