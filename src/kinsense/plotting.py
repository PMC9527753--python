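"""Diagnostic overlay of fitted curves on measured sensorgrams."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .fitting import FitResult
from .models import RateParameters, SensorgramTrace, evaluate_piecewise

__all__ = ["plot_fit"]


def plot_fit(
    series: Sequence[SensorgramTrace],
    fit: FitResult,
    path: str | Path | None = None,
):
    """Data (thin lines) with the fitted model (bold) per concentration."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = plt.cm.viridis_r([i / max(1, len(fit.per_trace) - 1)
                               for i in range(len(fit.per_trace))])
    by_label = {ts.label: ts for ts in fit.per_trace}
    i = 0
    for tr in series:
        if tr.is_blank or tr.label not in by_label:
            continue
        ts = by_label[tr.label]
        p = RateParameters(k_a=fit.k_a, k_d=fit.k_d, A=ts.A, y0=ts.y0,
                           f_res=fit.f_res)
        pred = evaluate_piecewise(tr.time, p, tr.concentration, tr.phases,
                                  A_d=ts.A_d)
        ax.plot(tr.time, tr.signal, lw=0.6, alpha=0.6, color=colors[i])
        ax.plot(tr.time, pred, lw=2.0, color=colors[i],
                label=f"{tr.concentration:.3g} M")
        i += 1
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fluorescence change (%)")
    ax.legend(fontsize=8, title="concentration")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig
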