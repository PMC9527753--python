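"""Readers and writers: trace CSVs, pose CSVs, series manifests, results.

File formats (all plain text):

* trace CSV — header ``time_s,signal_pct``; extra columns are preserved in
  ``trace.meta['extra_columns']``.
* pose CSV — header ``id,x,y,z,energy_kcal_mol``; negative energies
  (ΔG convention) are converted to positive magnitudes.
* series manifest — YAML with the phase markers, series metadata, analysis
  options and one record per trace file.
* results — JSON (machine-readable, reproducible byte-for-byte for a fixed
  manifest and seed) plus a TSV kinetic table and a run log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .fitting import FitResult, ReplicateSummary
from .models import Mode, PhaseMarkers, SensorgramTrace
from .qc import kinetic_table
from .simulate import PoseSet

__all__ = [
    "TraceEntry",
    "SeriesManifest",
    "read_trace_csv",
    "write_trace_csv",
    "read_pose_csv",
    "write_pose_csv",
    "parse_manifest",
    "write_manifest",
    "load_series",
    "write_results",
    "fit_result_to_dict",
]


def read_trace_csv(
    path: str | Path,
    *,
    concentration: float = 0.0,
    phases: PhaseMarkers | None = None,
    temperature: float = 25.0,
    mode: Mode = Mode.STATIC_STANDARD,
    label: str = "",
) -> SensorgramTrace:
    """Read one sensorgram from a ``time_s,signal_pct`` CSV.

    Metadata (concentration, phase markers, ...) comes from the caller —
    normally the series manifest.  Errors name the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "signal_pct"} - set(df.columns)
    if missing:
        raise ValidationError([f"{path.name}: missing column(s) {sorted(missing)}"])
    failures = []
    for col in ("time_s", "signal_pct"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        for row in df.index[bad]:
            failures.append(
                f"{path.name}: non-numeric {col} at data row {row + 1}: "
                f"{df[col][row]!r}"
            )
        if vals.isna().any() and not bad.any():
            row = int(df.index[vals.isna()][0])
            failures.append(f"{path.name}: empty {col} at data row {row + 1}")
        df[col] = vals
    if failures:
        raise ValidationError(failures)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size >= 2 and not np.all(dt > 0):
        row = int(np.argmin(dt > 0)) + 2
        raise ValidationError(
            [f"{path.name}: time_s not strictly increasing at data row {row}"]
        )
    extra = [c for c in df.columns if c not in ("time_s", "signal_pct")]
    trace = SensorgramTrace(
        time=t,
        signal=df["signal_pct"].to_numpy(dtype=float),
        concentration=concentration,
        phases=phases,
        temperature=temperature,
        mode=mode,
        label=label or path.stem,
    )
    if extra:
        trace.meta["extra_columns"] = {c: df[c].tolist() for c in extra}
    return trace


def write_trace_csv(trace: SensorgramTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "signal_pct": trace.signal}).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


def read_pose_csv(path: str | Path) -> PoseSet:
    """Read a docked pose table (``id,x,y,z,energy_kcal_mol``).

    Negative energies are interpreted as ΔG values and stored as positive
    magnitudes.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"id", "x", "y", "z", "energy_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError([f"{path.name}: missing column(s) {sorted(missing)}"])
    energies = df["energy_kcal_mol"].to_numpy(dtype=float)
    if np.any(energies < 0):
        energies = np.abs(energies)
    return PoseSet(
        ids=[str(i) for i in df["id"]],
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        energies=energies,
    )


def write_pose_csv(poses: PoseSet, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "id": poses.ids,
            "x": poses.coords[:, 0],
            "y": poses.coords[:, 1],
            "z": poses.coords[:, 2],
            "energy_kcal_mol": poses.energies,
        }
    ).to_csv(path, index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# series manifest


@dataclass(frozen=True)
class TraceEntry:
    file: str
    concentration: float
    is_blank: bool = False
    replicate: int = 1
    buffer: str = ""


@dataclass
class SeriesManifest:
    """Validated description of one concentration series on disk."""

    phases: PhaseMarkers
    traces: list[TraceEntry]
    temperature: float = 25.0
    mode: Mode = Mode.STATIC_STANDARD
    system: str = ""
    options: dict = field(default_factory=dict)
    base_dir: Path = field(default_factory=Path)


_DEFAULT_OPTIONS = {"model": "auto", "weighting": "uniform", "seed": 0}


def parse_manifest(path: str | Path) -> SeriesManifest:
    """Parse and validate a YAML series manifest.

    All validation failures are collected and reported together.  Defaults:
    temperature 25 °C, mode static_standard, options
    ``{model: auto, weighting: uniform, seed: 0}``; ``is_blank`` is
    inferred from a zero concentration.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    failures: list[str] = []
    if not isinstance(raw, dict):
        raise ValidationError([f"{path.name}: manifest must be a mapping"])

    phases = None
    ph = raw.get("phases")
    if not isinstance(ph, dict):
        failures.append("phases: missing mapping with t_a, t_d, t_end")
    else:
        try:
            phases = PhaseMarkers(
                t_a=float(ph.get("t_a")), t_d=float(ph.get("t_d")),
                t_end=float(ph.get("t_end")),
            )
        except Exception as exc:  # noqa: BLE001 - reported in the failure list
            failures.append(f"phases: {exc}")

    mode_raw = raw.get("mode", Mode.STATIC_STANDARD.value)
    mode = Mode.STATIC_STANDARD
    try:
        mode = Mode(mode_raw)
    except ValueError:
        failures.append(
            f"mode: unknown mode {mode_raw!r} (choose from "
            f"{[m.value for m in Mode]})"
        )

    options = dict(_DEFAULT_OPTIONS)
    options.update(raw.get("options") or {})

    entries: list[TraceEntry] = []
    items = raw.get("traces")
    if not isinstance(items, list) or not items:
        failures.append("traces: need a non-empty list of trace records")
        items = []
    for i, item in enumerate(items):
        if not isinstance(item, dict) or "file" not in item:
            failures.append(f"traces[{i}]: needs a 'file' key")
            continue
        if "concentration" not in item:
            failures.append(f"traces[{i}] ({item['file']}): missing concentration")
            continue
        try:
            conc = float(item["concentration"])
        except (TypeError, ValueError):
            failures.append(
                f"traces[{i}] ({item['file']}): non-numeric concentration "
                f"{item['concentration']!r}"
            )
            continue
        if conc < 0:
            failures.append(f"traces[{i}] ({item['file']}): concentration < 0")
            continue
        f = path.parent / item["file"]
        if not f.exists():
            failures.append(f"traces[{i}]: file not found: {item['file']}")
            continue
        entries.append(
            TraceEntry(
                file=item["file"],
                concentration=conc,
                is_blank=bool(item.get("is_blank", conc == 0.0)),
                replicate=int(item.get("replicate", 1)),
                buffer=str(item.get("buffer", "")),
            )
        )
    if failures:
        raise ValidationError([f"{path.name}: {f}" for f in failures])
    return SeriesManifest(
        phases=phases,
        traces=entries,
        temperature=float(raw.get("temperature", 25.0)),
        mode=mode,
        system=str(raw.get("system", "")),
        options=options,
        base_dir=path.parent,
    )


def write_manifest(manifest: SeriesManifest, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "phases": asdict(manifest.phases),
        "temperature": manifest.temperature,
        "mode": manifest.mode.value,
        "system": manifest.system,
        "options": manifest.options,
        "traces": [
            {
                "file": e.file,
                "concentration": e.concentration,
                "is_blank": e.is_blank,
                "replicate": e.replicate,
                **({"buffer": e.buffer} if e.buffer else {}),
            }
            for e in manifest.traces
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_series(manifest: SeriesManifest) -> list[SensorgramTrace]:
    """Read every trace referenced by a manifest, attaching its metadata."""
    return [
        read_trace_csv(
            manifest.base_dir / e.file,
            concentration=e.concentration,
            phases=manifest.phases,
            temperature=manifest.temperature,
            mode=manifest.mode,
            label=Path(e.file).stem,
        )
        for e in manifest.traces
    ]


# ---------------------------------------------------------------------------
# results


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "model": {
            "dissociation_model": fit.model.dissociation_model.value,
            "weighting": fit.model.weighting.value,
            "tie_dissociation_amplitude": fit.model.tie_dissociation_amplitude,
        },
        "converged": fit.converged,
        "message": fit.message,
        "params": {
            "k_a": fit.k_a,
            "k_d": fit.k_d,
            "f_res": fit.f_res,
        },
        "constants": {"K_A": fit.constants.K_A, "K_D": fit.constants.K_D},
        "standard_errors": fit.standard_errors,
        "uncertainty_method": fit.uncertainty_method,
        "per_trace": [asdict(ts) for ts in fit.per_trace],
        "residual_sum_squares": fit.residual_sum_squares,
        "n_points": fit.n_points,
        "information_criterion": fit.information_criterion,
        "meta": fit.meta,
    }


def write_results(
    fits: FitResult | Sequence[FitResult],
    out_dir: str | Path,
    *,
    qc: dict | None = None,
    summaries: Sequence[ReplicateSummary] = (),
    seeds: dict | None = None,
) -> dict[str, Path]:
    """Write the structured results record, TSV kinetic table and run log.

    ``results.json`` is deterministic for a fixed input (no timestamps);
    the run log records every seed and the library versions so the run can
    be reproduced.
    """
    import lmfit, scipy  # noqa: PLC0415

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(fits, FitResult):
        fits = [fits]
    record = {
        "kinsense_version": __version__,
        "seeds": seeds or {},
        "fits": [fit_result_to_dict(f) for f in fits],
        "qc": qc or {},
        "replicate_summaries": [
            {
                "system": s.system,
                "temperature": s.temperature,
                "mode": s.mode,
                "n_replicates": s.n_replicates,
                "stats": {k: list(v) for k, v in s.stats.items()},
            }
            for s in summaries
        ],
    }
    paths = {"results": out_dir / "results.json"}
    paths["results"].write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")

    rows = []
    for s in summaries:
        row = {"system": s.system, "temperature": s.temperature, "mode": s.mode}
        row.update({k: v for k, v in s.stats.items()})
        rows.append(row)
    if not rows:
        for f in fits:
            se = f.standard_errors or {}
            rows.append(
                {
                    "system": f.meta.get("system", ""),
                    "temperature": f.meta.get("temperature", float("nan")),
                    "mode": f.meta.get("mode", ""),
                    "k_a": (f.k_a, se.get("k_a", 0.0)),
                    "k_d": (f.k_d, se.get("k_d", 0.0)),
                    "K_D": (f.constants.K_D, 0.0),
                    "K_A": (f.constants.K_A, 0.0),
                }
            )
    paths["table"] = out_dir / "kinetic_table.tsv"
    paths["table"].write_text(kinetic_table(rows))

    log_lines = [f"kinsense {__version__}"]
    log_lines += [
        f"numpy {np.__version__}; scipy {scipy.__version__}; "
        f"pandas {pd.__version__}; lmfit {lmfit.__version__}"
    ]
    for name, value in (seeds or {}).items():
        log_lines.append(f"seed {name} = {value}")
    for i, f in enumerate(fits):
        log_lines.append(
            f"fit[{i}]: model={f.model.dissociation_model.value} "
            f"converged={f.converged} k_a={f.k_a:.6g} k_d={f.k_d:.6g} "
            f"f_res={f.f_res:.6g} rss={f.residual_sum_squares:.6g} "
            f"n={f.n_points}"
        )
    paths["log"] = out_dir / "run.log"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
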