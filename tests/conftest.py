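import numpy as np
import pytest

import kinsense as ks


@pytest.fixture(scope="session")
def eb_truth() -> ks.RateParameters:
    """Intercalator-like ground truth (fast association, fast complete
    dissociation), amplitudes on the 2-30% response scale."""
    return ks.RateParameters(k_a=6.98e5, k_d=0.358, A=30.0, y0=0.0, f_res=0.0)


@pytest.fixture(scope="session")
def slow_truth() -> ks.RateParameters:
    """Slow binder with incomplete dissociation."""
    return ks.RateParameters(k_a=77.7, k_d=8.77e-3, A=20.0, y0=0.5, f_res=0.35)


@pytest.fixture(scope="session")
def eb_series_noisefree(eb_truth):
    design = ks.SeriesDesign.eb_standard()
    return ks.simulate_series(eb_truth, design, ks.NoiseSpec(0.0, seed=0))


@pytest.fixture(scope="session")
def eb_series_noisy(eb_truth):
    design = ks.SeriesDesign.eb_standard()
    return ks.simulate_series(eb_truth, design, ks.NoiseSpec(0.5, seed=11))


@pytest.fixture(scope="session")
def slow_series_noisy(slow_truth):
    design = ks.SeriesDesign.slow_binder()
    return ks.simulate_series(slow_truth, design, ks.NoiseSpec(0.5, seed=11))


@pytest.fixture
def small_design():
    """Coarsely sampled short design, for tests where fit speed matters
    more than precision."""
    return ks.SeriesDesign(
        concentrations=ks.dilution_ladder(1e-6, 2.0, 3),
        association_duration=30.0,
        dissociation_duration=60.0,
        sampling_rate=2.0,
        baseline_duration=5.0,
    )


def brute_force_single_linkage(coords: np.ndarray, cutoff: float) -> list[set]:
    """Independent O(n^2) single-linkage oracle: connected components of the
    graph joining poses at pairwise distance <= cutoff."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
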