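"""Haplotype-based population distances.

Each diploid genotype sequence is split into two haplotypes and the
distance -> population-mean -> cross-marker pipeline is run on the
haplotypes. Statistical phasing is deliberately not attempted: at every
heterozygous site haplotype 1 receives the alphabetically smaller base
and haplotype 2 the larger. The rule is deterministic and its site-wise
collapse reproduces the input genotype exactly, but it does not preserve
within-individual linkage between heterozygous sites; externally phased
haplotypes can be supplied instead wherever an :class:`AlignedMarkerSet`
of haplotypes is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotype import (
    F84Params,
    combine_markers_euclidean,
    pairwise_distance_matrix,
    population_mean_distances,
)
from .model import IUPAC_BASES, AlignedMarkerSet, DistanceMatrix, PopulationMap

__all__ = [
    "HaplotypeSet",
    "phase_genotype",
    "phase_marker",
    "haplotype_population_matrix",
]

_TWO_BASE = {sym: bases for sym, bases in IUPAC_BASES.items() if len(bases) == 2}


def phase_genotype(seq: str) -> tuple[str, str]:
    """Split one diploid IUPAC sequence into two haplotypes.

    Homozygous and missing sites are copied to both haplotypes; at a
    heterozygous site the alphabetically smaller base goes to haplotype 1.
    Three- and four-base ambiguity codes cannot represent a diploid site
    and are rejected with the offending 1-based position.
    """
    h1, h2 = [], []
    for pos, sym in enumerate(seq.upper()):
        bases = IUPAC_BASES.get(sym)
        if bases is None:
            raise ValueError(f"illegal symbol {sym!r} at position {pos + 1}")
        if len(bases) > 2:
            raise ValueError(
                f"ambiguity code {sym!r} at position {pos + 1} denotes "
                f"{len(bases)} bases and cannot represent a diploid site"
            )
        if len(bases) == 2:
            h1.append(bases[0])
            h2.append(bases[1])
        else:  # homozygote or missing symbol
            h1.append(sym)
            h2.append(sym)
    return "".join(h1), "".join(h2)


@dataclass
class HaplotypeSet:
    """Phased haplotypes (two per individual) for one marker."""

    marker: AlignedMarkerSet          # haplotype ids are "<sample>/1", "<sample>/2"
    parent_ids: list[str]             # parent sample per haplotype

    @property
    def n_haplotypes(self) -> int:
        return self.marker.n_samples


def phase_marker(marker: AlignedMarkerSet) -> HaplotypeSet:
    ids, seqs, parents = [], [], []
    for sid, seq in zip(marker.sample_ids, marker.sequences):
        try:
            h1, h2 = phase_genotype(seq)
        except ValueError as exc:
            raise ValueError(f"cannot phase sample {sid!r}: {exc}") from exc
        ids.extend([f"{sid}/1", f"{sid}/2"])
        seqs.extend([h1, h2])
        parents.extend([sid, sid])
    return HaplotypeSet(
        AlignedMarkerSet(marker.marker_name, ids, seqs), parents
    )


def haplotype_popmap(haps: HaplotypeSet, popmap: PopulationMap) -> PopulationMap:
    """Population map over haplotype ids, inherited from the parents."""
    mapping = {}
    for hid, parent in zip(haps.marker.sample_ids, haps.parent_ids):
        pop = popmap.sample_to_population.get(parent)
        if pop is None:
            raise KeyError(f"sample {parent!r} missing from the population map")
        mapping[hid] = pop
    return PopulationMap(mapping, popmap.population_to_cluster)


def haplotype_population_matrix(
    markers: list[AlignedMarkerSet],
    popmap: PopulationMap,
    params: F84Params | None = None,
    phased: list[AlignedMarkerSet] | None = None,
) -> tuple[DistanceMatrix, list[DistanceMatrix], list[DistanceMatrix]]:
    """Haplotype-level F84 pipeline over one or more markers.

    For each marker the genotypes are phased (unless pre-phased haplotype
    sets are supplied in ``phased``, aligned with ``markers``), all
    haplotype pairwise F84 distances are computed, averaged into a
    population matrix, and the per-marker matrices are combined with the
    Euclidean rule. Returns ``(combined, per_marker_population, per_marker
    _haplotype)`` matrices.
    """
    pop_matrices: list[DistanceMatrix] = []
    hap_matrices: list[DistanceMatrix] = []
    for i, marker in enumerate(markers):
        if phased is not None and phased[i] is not None:
            hap_marker = phased[i]
            parents = [hid.rsplit("/", 1)[0] for hid in hap_marker.sample_ids]
            haps = HaplotypeSet(hap_marker, parents)
        else:
            haps = phase_marker(marker)
        hap_map = haplotype_popmap(haps, popmap)
        ind = pairwise_distance_matrix(haps.marker, params)
        ind.level = "haplotype"
        hap_matrices.append(ind)
        pop_matrices.append(population_mean_distances(ind, hap_map))
    return combine_markers_euclidean(pop_matrices), pop_matrices, hap_matrices
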