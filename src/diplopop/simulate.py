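"""Synthetic diploid two-marker datasets with hierarchical structure.

The generator emulates a multi-population amplicon survey: a fixed
number of populations, grouped into clusters, genotyped at two aligned
nuclear markers whose polymorphic sites are biallelic SNPs. Allele
frequencies follow the Balding-Nichols hierarchical island model: for a
site with ancestral frequency p, each cluster draws its frequency from

    Beta(p (1-F)/F, (1-p)(1-F)/F)     with F = F_between,

whose mean is p and variance F p (1-p); each population then draws its
frequency around its cluster's the same way with F = F_within.
Individual genotypes are Hardy-Weinberg draws from the population
frequency; heterozygotes are written with the two-base IUPAC code.

``simulate_dataset`` additionally ascertains SNPs: a site whose realized
pooled sample happens to be monomorphic is redrawn, so the configured
polymorphic-site counts are realized exactly — mirroring how real SNP
panels are conditioned on observed polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .model import AlignedMarkerSet, PopulationMap

__all__ = [
    "SimulationConfig",
    "MarkerFrequencies",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_dataset",
]

_HET_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """Study-scale defaults: 14 populations in clusters of 3+3+3+5, two
    markers of 425 and 239 positions carrying 30 and 33 SNPs."""

    pops_per_cluster: tuple[int, ...] = (3, 3, 3, 5)
    n_per_pop: int | tuple[int, ...] = 20
    marker_names: tuple[str, ...] = ("EF1", "NaKA")
    L_per_marker: tuple[int, ...] = (425, 239)
    n_snps_per_marker: tuple[int, ...] = (30, 33)
    F_between: float = 0.2
    F_within: float = 0.05
    base_composition: tuple[float, ...] = (0.28, 0.22, 0.22, 0.28)
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.L_per_marker) != len(self.marker_names) or len(
            self.n_snps_per_marker
        ) != len(self.marker_names):
            raise ValueError("per-marker lists must match marker_names")
        for L, s in zip(self.L_per_marker, self.n_snps_per_marker):
            if s > L:
                raise ValueError(f"n_snps {s} exceeds marker length {L}")
        if not 0 <= self.F_within <= self.F_between < 1:
            raise ValueError("need 0 <= F_within <= F_between < 1")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be 4 proportions summing to 1")
        lo, hi = self.ancestral_freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")

    @property
    def n_populations(self) -> int:
        return int(sum(self.pops_per_cluster))

    @property
    def population_names(self) -> list[str]:
        return [f"pop{i + 1:02d}" for i in range(self.n_populations)]

    @property
    def cluster_of(self) -> dict[str, str]:
        out = {}
        i = 0
        for c, size in enumerate(self.pops_per_cluster):
            for _ in range(size):
                out[self.population_names[i]] = f"cluster{c + 1}"
                i += 1
        return out

    def samples_per_population(self) -> list[int]:
        if isinstance(self.n_per_pop, int):
            return [self.n_per_pop] * self.n_populations
        if len(self.n_per_pop) != self.n_populations:
            raise ValueError("n_per_pop list must have one entry per population")
        return list(self.n_per_pop)


@dataclass
class MarkerFrequencies:
    """Simulated truth for one marker."""

    marker_name: str
    length: int
    snp_positions: list[int]          # 1-based
    ancestral_sequence: str           # background (monomorphic) bases
    ref_base: np.ndarray              # (n_snps,) reference allele per SNP
    alt_base: np.ndarray              # (n_snps,) alternate allele per SNP
    ancestral_freq: np.ndarray        # (n_snps,) ancestral ref-allele frequency
    cluster_freq: np.ndarray          # (n_clusters, n_snps)
    population_freq: np.ndarray       # (n_pops, n_snps)


def _beta_around(rng: np.random.Generator, mean: np.ndarray, f: float,
                 size) -> np.ndarray:
    """Balding-Nichols draw: Beta with mean ``mean`` and variance f*mean*(1-mean)."""
    if f == 0:
        return np.broadcast_to(mean, size).copy()
    mean = np.clip(mean, 1e-9, 1 - 1e-9)
    scale = (1 - f) / f
    return rng.beta(mean * scale, (1 - mean) * scale, size=size)


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[MarkerFrequencies]:
    """Draw per-population biallelic SNP frequencies for every marker."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.F_between == 0:
        warnings.warn(
            "F_between = 0: all populations share the ancestral frequencies",
            RuntimeWarning,
            stacklevel=2,
        )
    comp = np.asarray(config.base_composition, dtype=float)
    n_clusters = len(config.pops_per_cluster)
    cluster_index = np.repeat(np.arange(n_clusters), config.pops_per_cluster)
    out = []
    for name, L, n_snps in zip(
        config.marker_names, config.L_per_marker, config.n_snps_per_marker
    ):
        ancestral = rng.choice(_BASES, size=L, p=comp)
        positions = np.sort(rng.choice(L, size=n_snps, replace=False))
        ref = ancestral[positions].copy()
        alt = np.empty(n_snps, dtype=ref.dtype)
        for k in range(n_snps):
            others = [b for b in _BASES if b != ref[k]]
            alt[k] = rng.choice(others)
        lo, hi = config.ancestral_freq_range
        p0 = rng.uniform(lo, hi, size=n_snps)
        cl = _beta_around(rng, p0, config.F_between, (n_clusters, n_snps))
        pop = _beta_around(
            rng, cl[cluster_index], config.F_within,
            (config.n_populations, n_snps),
        )
        out.append(
            MarkerFrequencies(
                marker_name=name,
                length=L,
                snp_positions=[int(p) + 1 for p in positions],
                ancestral_sequence="".join(ancestral),
                ref_base=ref,
                alt_base=alt,
                ancestral_freq=p0,
                cluster_freq=cl,
                population_freq=pop,
            )
        )
    return out


def _genotype_symbol(ref: str, alt: str, n_ref: int) -> str:
    if n_ref == 2:
        return ref
    if n_ref == 0:
        return alt
    return _HET_CODE[frozenset((ref, alt))]


def simulate_genotypes(
    freqs: list[MarkerFrequencies],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignedMarkerSet], PopulationMap]:
    """Hardy-Weinberg genotypes for every individual at every marker."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sizes = config.samples_per_population()
    pops = config.population_names
    sample_ids = [
        f"{pop}_ind{i + 1:02d}" for pop, n in zip(pops, sizes) for i in range(n)
    ]
    sample_pop = [pop for pop, n in zip(pops, sizes) for _ in range(n)]
    markers = []
    for mf in freqs:
        grid = np.array([list(mf.ancestral_sequence) for _ in sample_ids])
        for k, pos in enumerate(mf.snp_positions):
            col = []
            for pop_i, n in enumerate(sizes):
                p = mf.population_freq[pop_i, k]
                col.extend(rng.binomial(2, p, size=n))
            grid[:, pos - 1] = [
                _genotype_symbol(str(mf.ref_base[k]), str(mf.alt_base[k]), c)
                for c in col
            ]
        markers.append(
            AlignedMarkerSet(
                mf.marker_name, list(sample_ids), ["".join(r) for r in grid]
            )
        )
    popmap = PopulationMap(dict(zip(sample_ids, sample_pop)), config.cluster_of)
    return markers, popmap


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[list[AlignedMarkerSet], PopulationMap, list[MarkerFrequencies]]:
    """Full dataset with SNP ascertainment.

    Draws frequencies and genotypes from ``config.seed``, then redraws
    any SNP site whose realized pooled sample is monomorphic (first the
    genotypes, then — if the frequencies drifted to fixation — the site's
    frequencies as well), so every configured SNP is polymorphic in the
    emitted data. Background positions are monomorphic by construction.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    freqs = simulate_frequencies(config, rng)
    markers, popmap = simulate_genotypes(freqs, config, rng)
    sizes = config.samples_per_population()
    n_clusters = len(config.pops_per_cluster)
    cluster_index = np.repeat(np.arange(n_clusters), config.pops_per_cluster)
    lo, hi = config.ancestral_freq_range

    out_markers = []
    for mf, marker in zip(freqs, markers):
        grid = np.array([list(s) for s in marker.sequences])
        for k, pos in enumerate(mf.snp_positions):
            for attempt in range(200):
                column = grid[:, pos - 1]
                symbols = set(column)
                if len(symbols) > 1 or (len(symbols) == 1 and
                                        next(iter(symbols)) in _HET_CODE.values()):
                    break
                if attempt % 10 == 9:  # frequencies near fixation: redraw them
                    p0 = rng.uniform(lo, hi)
                    cl = _beta_around(rng, np.array(p0), config.F_between,
                                      (n_clusters,))
                    mf.ancestral_freq[k] = p0
                    mf.cluster_freq[:, k] = cl
                    mf.population_freq[:, k] = _beta_around(
                        rng, cl[cluster_index], config.F_within,
                        (config.n_populations,),
                    )
                col = []
                for pop_i, n in enumerate(sizes):
                    p = mf.population_freq[pop_i, k]
                    col.extend(rng.binomial(2, p, size=n))
                grid[:, pos - 1] = [
                    _genotype_symbol(str(mf.ref_base[k]), str(mf.alt_base[k]), c)
                    for c in col
                ]
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError(f"could not ascertain SNP at position {pos}")
        out_markers.append(
            AlignedMarkerSet(
                mf.marker_name, list(marker.sample_ids),
                ["".join(r) for r in grid],
            )
        )
    return out_markers, popmap, freqs
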