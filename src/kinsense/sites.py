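"""Post-analysis of docked pose sets into ranked binding sites.

Docking engines emit many poses per analyte; the questions a minor-groove
binding study asks of them are (i) where do poses pile up — the "most
common" binding site, (ii) where is the single best-scoring pose — the
"most strongly bonded" site, and (iii) what fraction of poses exceed an
energy threshold.  Poses are grouped by single-linkage clustering of
their centroids at a Euclidean distance cutoff (default 3.5 Å): two poses
share a site iff they are connected by a chain of pairwise distances
within the cutoff.

Binding energies are stored as positive magnitudes (kcal/mol, larger =
stronger), matching how favorable docking energies are usually quoted;
the pose reader converts negative ΔG input by absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import InvalidDesignError
from .simulate import PoseSet

__all__ = [
    "DEFAULT_CUTOFF_ANGSTROM",
    "SiteCluster",
    "cluster_poses",
    "rank_sites",
    "energy_fraction_above",
]

DEFAULT_CUTOFF_ANGSTROM = 3.5


@dataclass(frozen=True)
class SiteCluster:
    """One spatial cluster of docked poses (a candidate binding site)."""

    members: tuple[str, ...]
    member_indices: tuple[int, ...]
    centroid: tuple[float, float, float]
    abundance: int
    best_energy: float
    representative: str

    def __post_init__(self) -> None:
        if self.abundance != len(self.members) or self.abundance < 1:
            raise InvalidDesignError("abundance must equal the member count (>= 1)")


def cluster_poses(
    poses: PoseSet, cutoff: float = DEFAULT_CUTOFF_ANGSTROM
) -> list[SiteCluster]:
    """Single-linkage partition of pose centroids at a distance cutoff.

    Deterministic; clusters are ordered by decreasing abundance, ties by
    decreasing best energy, then by first member index.  An empty pose set
    yields an empty list.
    """
    if cutoff <= 0:
        raise InvalidDesignError(f"cutoff must be > 0 Å, got {cutoff}")
    n = len(poses)
    if n == 0:
        return []
    if n == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(poses.coords), method="single")
        labels = fcluster(z, t=cutoff, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        energies = poses.energies[idx]
        best = int(idx[np.argmax(energies)])
        clusters.append(
            SiteCluster(
                members=tuple(poses.ids[i] for i in idx),
                member_indices=tuple(int(i) for i in idx),
                centroid=tuple(np.mean(poses.coords[idx], axis=0)),
                abundance=len(idx),
                best_energy=float(poses.energies[best]),
                representative=poses.ids[best],
            )
        )
    clusters.sort(
        key=lambda cl: (-cl.abundance, -cl.best_energy, cl.member_indices[0])
    )
    return clusters


def rank_sites(clusters: list[SiteCluster]) -> tuple[SiteCluster, SiteCluster]:
    """The most popular site and the most strongly bonded site.

    ``most_popular`` maximizes abundance (ties broken by higher best
    energy, then by lower cluster index); ``strongest`` maximizes the best
    member energy (ties by higher abundance, then lower index).  The two
    may be the same cluster.
    """
    if not clusters:
        raise InvalidDesignError("rank_sites needs >= 1 cluster")
    order = range(len(clusters))
    most_popular = max(
        order, key=lambda i: (clusters[i].abundance, clusters[i].best_energy, -i)
    )
    strongest = max(
        order, key=lambda i: (clusters[i].best_energy, clusters[i].abundance, -i)
    )
    return clusters[most_popular], clusters[strongest]


def energy_fraction_above(poses: PoseSet, threshold: float) -> float:
    """Fraction of poses with binding-energy magnitude above ``threshold``."""
    if len(poses) == 0:
        raise InvalidDesignError("energy fraction is undefined for an empty pose set")
    return float(np.count_nonzero(poses.energies > threshold) / len(poses))
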