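"""Published reference rate constants for DNA binders measured by switchSense.

Two summary tables of kinetic constants (mean ± SD over three independent
experiments) are bundled as plain records: an intercalator (ethidium
bromide, EB) measured by the static standard and static weak-binder
methods at 15/25/37 °C, and two slowly binding alkylamino sulfonamide
derivatives (NethylS, NpropylS) measured by the weak-binder method with
the incomplete-dissociation model.  They serve as simulation ground truth
and as inputs to arithmetic consistency checks (K_A = k_a/k_d,
K_D = k_d/k_a).

Each record holds ``(mean, sd)`` pairs exactly as printed.  The NethylS
37 °C row is flagged ``inconsistent``: its printed K_D and K_A cells do
not match k_d/k_a at the printed magnitudes (the mantissas do, so the k_d
exponent is a probable misprint) and the row is excluded from consistency
checks on the derived constants.
"""

from __future__ import annotations

__all__ = ["EB_KINETICS", "SULFONAMIDE_KINETICS", "lookup"]

# system, temperature (°C), mode, k_a (M^-1 s^-1), k_d (s^-1), K_D (M), K_A (M^-1)
EB_KINETICS: list[dict] = [
    {
        "system": "EB", "temperature": 15, "mode": "static_standard",
        "k_a": (1.50e6, 0.16e6), "k_d": (0.359, 0.005),
        "K_D": (2.39e-7, 0.25e-7), "K_A": (4.19e6, 0.44e6),
    },
    {
        "system": "EB", "temperature": 25, "mode": "static_standard",
        "k_a": (6.98e5, 0.63e5), "k_d": (0.358, 0.007),
        "K_D": (5.13e-7, 0.47e-7), "K_A": (1.95e6, 0.18e6),
    },
    {
        "system": "EB", "temperature": 37, "mode": "static_standard",
        "k_a": (8.55e5, 0.95e5), "k_d": (0.360, 0.006),
        "K_D": (4.22e-7, 0.47e-7), "K_A": (2.37e6, 0.27e6),
    },
    {
        "system": "EB", "temperature": 15, "mode": "static_weak_binder",
        "k_a": (1.69e6, 0.20e6), "k_d": (0.391, 0.007),
        "K_D": (2.32e-7, 0.27e-7), "K_A": (4.31e6, 0.51e6),
    },
    {
        "system": "EB", "temperature": 25, "mode": "static_weak_binder",
        "k_a": (6.04e5, 0.18e5), "k_d": (0.478, 0.190),
        "K_D": (7.91e-7, 0.45e-7), "K_A": (1.26e6, 0.23e6),
    },
    {
        "system": "EB", "temperature": 37, "mode": "static_weak_binder",
        "k_a": (1.03e6, 0.19e6), "k_d": (0.388, 0.008),
        "K_D": (3.75e-7, 0.69e-7), "K_A": (2.67e6, 0.49e6),
    },
]

SULFONAMIDE_KINETICS: list[dict] = [
    {
        "system": "NethylS", "temperature": 15, "mode": "static_weak_binder",
        "k_a": (72.7, 3.6), "k_d": (1.23e-2, 0.04e-2),
        "K_D": (1.68e-4, 0.10e-4), "K_A": (5.94e3, 0.35e3),
    },
    {
        "system": "NethylS", "temperature": 25, "mode": "static_weak_binder",
        "k_a": (77.7, 3.7), "k_d": (8.77e-3, 0.59e-3),
        "K_D": (1.13e-4, 0.29e-4), "K_A": (8.82e3, 0.72e3),
    },
    {
        # printed K_D and K_A disagree with k_d/k_a by whole decades while the
        # mantissas agree: the k_d exponent is a probable misprint.  Excluded
        # from derived-constant consistency checks.
        "system": "NethylS", "temperature": 37, "mode": "static_weak_binder",
        "k_a": (61.9, 2.7), "k_d": (1.57e-3, 0.04e-3),
        "K_D": (2.54e-3, 0.13e-3), "K_A": (3.93e3, 0.20e3),
        "inconsistent": True,
    },
    {
        "system": "NpropylS", "temperature": 15, "mode": "static_weak_binder",
        "k_a": (26.7, 3.4), "k_d": (1.48e-2, 0.05e-2),
        "K_D": (5.53e-4, 0.73e-4), "K_A": (1.81e3, 0.24e3),
    },
    {
        "system": "NpropylS", "temperature": 25, "mode": "static_weak_binder",
        "k_a": (16.9, 0.5), "k_d": (1.02e-2, 0.02e-2),
        "K_D": (6.02e-4, 0.24e-4), "K_A": (1.66e3, 0.07e3),
    },
    {
        "system": "NpropylS", "temperature": 37, "mode": "static_weak_binder",
        "k_a": (15.4, 0.6), "k_d": (1.19e-2, 0.02e-2),
        "K_D": (7.73e-4, 0.34e-4), "K_A": (1.29e3, 0.06e3),
    },
]


def lookup(system: str, temperature: float, mode: str | None = None) -> dict:
    """Fetch one reference record by system and temperature."""
    for row in EB_KINETICS + SULFONAMIDE_KINETICS:
        if row["system"] == system and row["temperature"] == temperature and (
            mode is None or row["mode"] == mode
        ):
            return row
    raise KeyError(f"no reference record for {system} at {temperature} C")
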