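"""Per-population diversity statistics.

Three measures are computed per population and marker, then averaged
(unweighted) across markers:

* mean number of different alleles per position — distinct bases present
  in the population at a column (IUPAC-expanded), averaged over all L
  positions of the marker;
* expected heterozygosity — 1 - (1/N) sum_k sum_i x_{i,k}^2, with
  x_{i,k} the proportion of base i at position k and N the full marker
  length (monomorphic positions contribute 0);
* percent polymorphic positions — share of columns with >= 2 distinct
  alleles within the population.

Allele counting is haplotype-based throughout: each diploid contributes
two alleles per position, heterozygotes one of each base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AlignedMarkerSet, PopulationMap

__all__ = [
    "DiversitySummary",
    "alleles_per_position",
    "expected_heterozygosity",
    "percent_polymorphic",
    "diversity_summary",
]


def _population_counts(marker: AlignedMarkerSet, popmap: PopulationMap,
                       population: str) -> np.ndarray:
    rows = [i for i, s in enumerate(marker.sample_ids)
            if popmap.sample_to_population.get(s) == population]
    if not rows:
        raise ValueError(f"population {population!r} has no samples in "
                         f"marker {marker.marker_name!r}")
    return 2.0 * marker.allele_weights()[rows].sum(axis=0)   # (L, 4) allele counts


def _check_no_all_missing(counts: np.ndarray, population: str) -> None:
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        pos = int(np.nonzero(totals == 0)[0][0]) + 1
        raise ValueError(
            f"all alleles missing in population {population!r} at position {pos}"
        )


def alleles_per_position(counts: np.ndarray, population: str = "?") -> float:
    """Mean count of distinct bases per alignment column, from allele counts."""
    counts = np.asarray(counts, dtype=float)
    _check_no_all_missing(counts, population)
    return float((counts > 0).sum(axis=1).mean())


def expected_heterozygosity(counts: np.ndarray, population: str = "?") -> float:
    """1 - mean over positions of the sum of squared allele proportions."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] == 0:
        raise ValueError("no positions")
    _check_no_all_missing(counts, population)
    props = counts / counts.sum(axis=1, keepdims=True)
    return float(1.0 - (props ** 2).sum(axis=1).mean())


def percent_polymorphic(counts: np.ndarray, population: str = "?") -> float:
    """Percentage of columns with >= 2 distinct alleles in the population."""
    counts = np.asarray(counts, dtype=float)
    _check_no_all_missing(counts, population)
    return float(100.0 * ((counts > 0).sum(axis=1) >= 2).mean())


@dataclass
class DiversitySummary:
    """Per-population, per-marker diversity statistics with marker averages."""

    per_marker: pd.DataFrame   # index (population, marker)
    overall: pd.DataFrame      # index population; unweighted marker means

    def to_tsv(self, path) -> None:
        self.overall.to_csv(path, sep="\t", float_format="%.6g")


def diversity_summary(
    markers: list[AlignedMarkerSet], popmap: PopulationMap
) -> DiversitySummary:
    """Compute all three statistics for every population and marker.

    Every population must be present in every marker; the across-marker
    average is unweighted (markers count equally regardless of length).
    """
    for marker in markers:
        popmap.require_complete(marker)
    pops = popmap.populations
    for marker in markers:
        marker_pops = {popmap.sample_to_population[s] for s in marker.sample_ids}
        absent = [p for p in pops if p not in marker_pops]
        if absent:
            raise ValueError(
                f"population(s) {absent} absent from marker {marker.marker_name!r}"
            )
    rows = []
    for marker in markers:
        for pop in pops:
            counts = _population_counts(marker, popmap, pop)
            rows.append(
                {
                    "population": pop,
                    "marker": marker.marker_name,
                    "mean_alleles_per_position": alleles_per_position(counts, pop),
                    "expected_heterozygosity": expected_heterozygosity(counts, pop),
                    "percent_polymorphic": percent_polymorphic(counts, pop),
                }
            )
    per_marker = pd.DataFrame(rows).set_index(["population", "marker"])
    overall = per_marker.groupby(level="population", sort=False).mean()
    return DiversitySummary(per_marker=per_marker, overall=overall.loc[pops])
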