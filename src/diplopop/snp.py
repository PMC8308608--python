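"""Population-based SNP-distribution distances.

Instead of comparing individuals, this method compares populations
directly through their per-site nucleotide composition. For each marker,
monomorphic alignment columns (over the pooled sample, after IUPAC
expansion) are discarded; at every remaining polymorphic position each
population is summarised by its proportion 4-vector (x_A, x_C, x_G, x_T)
over non-missing alleles, each diploid contributing two alleles. A pair
of populations is compared at one position with one of three metrics on
the 4-simplex:

    squared Euclidean     sum_i (x_i - y_i)^2
    modified squared chord  sum_i (sqrt(x_i) - sqrt(y_i))^2
    Manhattan             sum_i |x_i - y_i|

all bounded by [0, 2]. Per-site distances (which are not independent
across sites when linkage disequilibrium exists) are averaged over the
marker's polymorphic positions to give the marker-level population
distance, and markers are combined entrywise by the Euclidean rule. The
method deliberately ignores linkage — it describes compositional
differences between populations rather than evolutionary history — and
it damps rare variants: one deviant haplotype among n shifts a
population's site vector by 1/n in total variation, while it shifts the
mean pairwise individual mismatch at that site by 2/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype import combine_markers_euclidean
from .model import AlignedMarkerSet, DistanceMatrix, PopulationMap

__all__ = [
    "METRICS",
    "SiteFrequencyProfile",
    "find_polymorphic_positions",
    "population_site_frequencies",
    "site_distance",
    "snp_population_matrix",
    "snp_combined_matrix",
]

METRICS = ("sq_euclidean", "sq_chord", "manhattan")


@dataclass
class SiteFrequencyProfile:
    """Per-position nucleotide proportions of one population at one marker.

    ``positions`` are 1-based alignment coordinates; ``proportions`` has
    shape ``(len(positions), 4)`` in ACGT order, each row summing to 1
    over counted (non-missing) alleles; ``allele_counts`` holds the
    number of counted alleles per position (at most twice the population
    sample size).
    """

    population: str
    marker: str
    positions: list[int]
    proportions: np.ndarray
    allele_counts: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.positions), 4):
            raise ValueError("proportions shape does not match positions")
        if np.any(self.proportions < -1e-12):
            raise ValueError("negative proportions")
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportions must sum to 1 at every position")


def find_polymorphic_positions(marker: AlignedMarkerSet) -> list[int]:
    """1-based positions with >= 2 distinct bases in the pooled sample.

    IUPAC codes are expanded (a single heterozygote makes its column
    polymorphic); missing symbols are ignored.
    """
    w = marker.allele_weights()          # (n, L, 4)
    present = (w.sum(axis=0) > 0)        # (L, 4)
    return [int(k) + 1 for k in np.nonzero(present.sum(axis=1) >= 2)[0]]


def population_site_frequencies(
    marker: AlignedMarkerSet,
    popmap: PopulationMap,
    positions: list[int] | None = None,
) -> list[SiteFrequencyProfile]:
    """Per-population nucleotide proportion profiles at the given positions.

    Each diploid individual contributes two allele counts per position
    (IUPAC heterozygote = 1 + 1, homozygote = 2); proportions are
    normalised over non-missing alleles. ``positions`` defaults to the
    pooled polymorphic positions of the marker.
    """
    popmap.require_complete(marker)
    if positions is None:
        positions = find_polymorphic_positions(marker)
    if any(not 1 <= p <= marker.length for p in positions):
        raise ValueError(f"positions outside 1..{marker.length}")
    idx = np.array([p - 1 for p in positions], dtype=int)
    w = marker.allele_weights()
    profiles = []
    for pop in popmap.populations:
        rows = [i for i, s in enumerate(marker.sample_ids)
                if popmap.sample_to_population[s] == pop]
        counts = 2.0 * w[rows][:, idx, :].sum(axis=0)   # alleles, not samples
        totals = counts.sum(axis=1)
        if np.any(totals == 0):
            bad = positions[int(np.nonzero(totals == 0)[0][0])]
            raise ValueError(
                f"all alleles missing in population {pop!r} at position {bad}"
            )
        profiles.append(
            SiteFrequencyProfile(
                population=pop,
                marker=marker.marker_name,
                positions=list(positions),
                proportions=counts / totals[:, None],
                allele_counts=totals,
            )
        )
    return profiles


def site_distance(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """Distance between two nucleotide proportion 4-vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for v in (x, y):
        if v.shape != (4,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("proportion vectors must be non-negative and sum to 1")
    if metric == "sq_euclidean":
        return float(np.sum((x - y) ** 2))
    if metric == "sq_chord":
        return float(np.sum((np.sqrt(x) - np.sqrt(y)) ** 2))
    if metric == "manhattan":
        return float(np.sum(np.abs(x - y)))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _site_distances_vec(px: np.ndarray, py: np.ndarray, metric: str) -> np.ndarray:
    if metric == "sq_euclidean":
        return ((px - py) ** 2).sum(axis=-1)
    if metric == "sq_chord":
        return ((np.sqrt(px) - np.sqrt(py)) ** 2).sum(axis=-1)
    if metric == "manhattan":
        return np.abs(px - py).sum(axis=-1)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def snp_population_matrix(
    profiles: list[SiteFrequencyProfile],
    metric: str,
    audit: dict | None = None,
) -> DistanceMatrix:
    """Average per-site distances into one marker's population matrix.

    All profiles must share the same position list. If ``audit`` is a
    dict it is filled with ``positions`` and the per-site distance table
    (population-pair keyed), so the averaging over non-independent sites
    stays inspectable.
    """
    if not profiles:
        raise ValueError("no profiles")
    positions = profiles[0].positions
    if not positions:
        raise ValueError("empty position list (no polymorphic positions?)")
    for pr in profiles:
        if pr.positions != positions:
            raise ValueError("profiles disagree on the position list")
    pops = [pr.population for pr in profiles]
    k = len(pops)
    out = np.zeros((k, k))
    per_site: dict[tuple[str, str], np.ndarray] = {}
    for i in range(k):
        for j in range(i + 1, k):
            d = _site_distances_vec(
                profiles[i].proportions, profiles[j].proportions, metric
            )
            out[i, j] = out[j, i] = d.mean()
            per_site[(pops[i], pops[j])] = d
    if audit is not None:
        audit["positions"] = list(positions)
        audit["per_site"] = per_site
    return DistanceMatrix(pops, out, level="population")


def snp_combined_matrix(marker_matrices: list[DistanceMatrix]) -> DistanceMatrix:
    """Combine per-marker SNP matrices entrywise by the Euclidean rule."""
    return combine_markers_euclidean(marker_matrices)
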