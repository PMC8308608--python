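"""Core domain types shared by every analysis stage.

The pipeline works on aligned diploid sequences in which heterozygous
sites are encoded with two-base IUPAC ambiguity codes (R, Y, S, W, K, M).
Gaps (``-``) and ``N`` are accepted on input and treated as missing data
by every downstream computation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IUPAC_BASES",
    "MISSING_SYMBOLS",
    "ALPHABET",
    "AlignedMarkerSet",
    "PopulationMap",
    "DistanceMatrix",
    "Dendrogram",
    "AlignmentError",
]

#: Base sets for every accepted alignment symbol (missing symbols map to "").
IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "", "-": "",
}

MISSING_SYMBOLS = frozenset({"N", "-"})
ALPHABET = frozenset(IUPAC_BASES)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class AlignmentError(ValueError):
    """Raised when an alignment violates a structural invariant."""


@dataclass
class AlignedMarkerSet:
    """One marker's aligned diploid sequences.

    Parameters
    ----------
    marker_name:
        Label of the marker (e.g. a gene fragment name).
    sample_ids:
        Unique, ordered sample identifiers, one per sequence.
    sequences:
        Upper-case IUPAC strings, all of identical length.
    """

    marker_name: str
    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise AlignmentError(f"duplicate sample ids: {sorted(dupes)}")
        if not self.sequences:
            raise AlignmentError("marker set is empty")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            offenders = [
                sid for sid, s in zip(self.sample_ids, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise AlignmentError(
                f"ragged alignment for marker {self.marker_name!r}: records "
                f"{offenders} differ in length from the first record"
            )
        for sid, seq in zip(self.sample_ids, self.sequences):
            for pos, sym in enumerate(seq):
                if sym not in ALPHABET:
                    raise AlignmentError(
                        f"illegal symbol {sym!r} in record {sid!r} at "
                        f"position {pos + 1}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def allele_weights(self) -> np.ndarray:
        """Per-sample, per-site base weights, shape ``(n, L, 4)``.

        Each diploid sample contributes total weight 1 per site split over
        its base set (1 for a homozygote, 0.5+0.5 for a two-base IUPAC
        heterozygote, 1/3 each for a three-base code); missing sites carry
        zero weight. The ACGT axis ordering is fixed.
        """
        w = np.zeros((self.n_samples, self.length, 4))
        for i, seq in enumerate(self.sequences):
            for k, sym in enumerate(seq):
                bases = IUPAC_BASES[sym]
                if not bases:
                    continue
                share = 1.0 / len(bases)
                for b in bases:
                    w[i, k, _BASE_INDEX[b]] = share
        return w

    def subset(self, sample_ids: list[str]) -> "AlignedMarkerSet":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in marker set: {missing}")
        return AlignedMarkerSet(
            self.marker_name,
            list(sample_ids),
            [self.sequences[index[s]] for s in sample_ids],
        )


@dataclass
class PopulationMap:
    """Sample-to-population (and optional population-to-cluster) assignment."""

    sample_to_population: dict[str, str]
    population_to_cluster: dict[str, str] | None = None

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_to_population.values():
            seen.setdefault(pop)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_population.items() if p == population]

    def small_populations(self, min_size: int = 2) -> list[str]:
        """Populations with fewer than ``min_size`` samples (flagged, not fatal)."""
        return [p for p in self.populations if len(self.samples_of(p)) < min_size]

    def require_complete(self, marker: AlignedMarkerSet) -> None:
        unmapped = [s for s in marker.sample_ids if s not in self.sample_to_population]
        if unmapped:
            raise KeyError(
                f"samples of marker {marker.marker_name!r} missing from the "
                f"population map: {unmapped[:5]}{'...' if len(unmapped) > 5 else ''}"
            )


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray
    level: str = "population"  # one of {"individual", "haplotype", "population"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")
        # clean tiny numeric asymmetries so equality tests are exact
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self.values[self.values < 0] = 0.0

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def off_diagonal_pairs(self):
        """Yield ``(label_a, label_b, d)`` over the strict upper triangle."""
        for i, j in itertools.combinations(range(self.n), 2):
            yield self.labels[i], self.labels[j], float(self.values[i, j])

    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.level)


@dataclass
class Dendrogram:
    """Complete-linkage merge history over a set of leaves.

    ``merges`` holds ``(i, j, height)`` triples using scipy's convention:
    leaves are clusters ``0..n-1`` and the cluster formed by merge ``m``
    gets index ``n + m``.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError(
                f"{n} leaves require {n - 1} merges, got {len(self.merges)}"
            )
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights decrease (inversion)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into ``k`` clusters by undoing the last merges."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for m, (i, j, _) in enumerate(self.merges[: n - k]):
            members[n + m] = members.pop(i) + members.pop(j)
        out: dict[str, int] = {}
        for group, leaves in enumerate(sorted(members.values(), key=min)):
            for leaf in leaves:
                out[self.leaf_labels[leaf]] = group
        return out

    def newick(self) -> str:
        """Ultrametric Newick string; child branch = (parent − child height)/2."""

        def escape(label: str) -> str:
            return label.replace(" ", "_")

        n = self.n_leaves
        node_height = {i: 0.0 for i in range(n)}
        node_str = {i: escape(l) for i, l in enumerate(self.leaf_labels)}
        for m, (i, j, h) in enumerate(self.merges):
            bi = (h - node_height[i]) / 2.0
            bj = (h - node_height[j]) / 2.0
            node_str[n + m] = f"({node_str[i]}:{bi:g},{node_str[j]}:{bj:g})"
            node_height[n + m] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node_str[root] + ";"
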