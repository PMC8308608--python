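"""Genotype-based population distances under the F84 substitution model.

The F84 model distinguishes transitions from transversions and allows
unequal base composition. Its pairwise distance has the closed form

    d = -2A ln(1 - P/(2A) - (A-B)Q/(2AC)) + 2(A-B-C) ln(1 - Q/(2C))

with pi the base frequencies, pi_R = pi_A + pi_G, pi_Y = pi_C + pi_T,

    A = pi_C pi_T / pi_Y + pi_A pi_G / pi_R,
    B = pi_C pi_T + pi_A pi_G,
    C = pi_R pi_Y,

and P, Q the observed proportions of transition and transversion
differences. Diploid sequences may carry two-base IUPAC codes at
heterozygous sites; mismatch proportions are then fractional: at each
site the shared base mass of the two genotypes is matched first and only
the residual mass (coupled independently) is classified as transition or
transversion. Two identical heterozygotes (R against R) therefore count
as no difference, while A against R counts as half a transition.

Sites where either sequence is missing ('-' or 'N') are excluded
pairwise. Saturated pairs, for which the log arguments are non-positive
and the distance is undefined, are recorded at a configurable ceiling so
population means stay finite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import IUPAC_BASES, AlignedMarkerSet, DistanceMatrix, PopulationMap

__all__ = [
    "F84Params",
    "empirical_base_frequencies",
    "f84_distance",
    "pairwise_distance_matrix",
    "population_mean_distances",
    "combine_markers_euclidean",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class F84Params:
    """Settings of the F84 distance engine.

    ``ts_tv_ratio`` is the model's expected transition/transversion ratio.
    It is carried in run manifests for the record but does not enter the
    closed-form distance, which estimates the transition and transversion
    proportions directly from each pair. ``base_frequencies`` (ACGT order)
    default to the empirical composition of the whole marker set, the
    behaviour of classical distance programs. ``saturation_ceiling`` is
    the sentinel distance recorded for saturated pairs.
    """

    ts_tv_ratio: float = 2.0
    base_frequencies: np.ndarray | None = None
    saturation_ceiling: float = 5.0

    def __post_init__(self) -> None:
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be positive")
        if self.base_frequencies is not None:
            f = np.asarray(self.base_frequencies, dtype=float)
            if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-6:
                raise ValueError(
                    "base_frequencies must be 4 positive values summing to 1"
                )
            self.base_frequencies = f / f.sum()


def empirical_base_frequencies(marker: AlignedMarkerSet) -> np.ndarray:
    """Base composition over all samples and sites, ambiguity-weighted."""
    totals = marker.allele_weights().sum(axis=(0, 1))
    if np.any(totals == 0):
        absent = [b for b, i in _BASE_INDEX.items() if totals[i] == 0]
        raise ValueError(
            f"base(s) {absent} absent from marker {marker.marker_name!r}; "
            "supply base_frequencies explicitly"
        )
    return totals / totals.sum()


def _seq_weights(seq: str) -> np.ndarray:
    w = np.zeros((len(seq), 4))
    for k, sym in enumerate(seq):
        bases = IUPAC_BASES[sym]
        if bases:
            share = 1.0 / len(bases)
            for b in bases:
                w[k, _BASE_INDEX[b]] = share
    return w


def _pq_counts(wa: np.ndarray, wb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fractional transition/transversion counts for batched weight tensors.

    ``wa``, ``wb`` have shape ``(..., L, 4)``; returns per-batch sums of
    transition mass P, transversion mass Q and the number of comparable
    sites, each of shape ``(...)``.
    """
    present = (wa.sum(axis=-1) > 0) & (wb.sum(axis=-1) > 0)
    m = np.minimum(wa, wb)
    shared = m.sum(axis=-1)
    mismatch = np.where(present, 1.0 - shared, 0.0)
    ra = wa - m
    rb = wb - m
    # residual independent coupling: mass on ordered pair (a,b) is
    # ra[a] * rb[b] / (1 - shared); transitions are A<->G and C<->T
    pnum = (
        ra[..., 0] * rb[..., 2] + ra[..., 2] * rb[..., 0]
        + ra[..., 1] * rb[..., 3] + ra[..., 3] * rb[..., 1]
    )
    denom = np.where(mismatch > 1e-12, 1.0 - shared, 1.0)
    p_site = np.where(mismatch > 1e-12, pnum / denom, 0.0)
    q_site = mismatch - p_site
    return p_site.sum(axis=-1), q_site.sum(axis=-1), present.sum(axis=-1)


def _f84_constants(freqs: np.ndarray) -> tuple[float, float, float]:
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    a = pc * pt / py + pa * pg / pr
    b = pc * pt + pa * pg
    c = pr * py
    return a, b, c


def f84_from_proportions(p: float, q: float, freqs: np.ndarray,
                         saturation_ceiling: float = 5.0) -> float:
    """Closed-form F84 distance from transition/transversion proportions."""
    a, b, c = _f84_constants(np.asarray(freqs, dtype=float))
    arg1 = 1.0 - p / (2.0 * a) - (a - b) * q / (2.0 * a * c)
    arg2 = 1.0 - q / (2.0 * c)
    if arg1 <= 0 or arg2 <= 0:
        warnings.warn(
            "saturated pair (undefined F84 log); recording ceiling distance",
            RuntimeWarning,
            stacklevel=2,
        )
        return saturation_ceiling
    d = -2.0 * a * np.log(arg1) + 2.0 * (a - b - c) * np.log(arg2)
    return max(float(d), 0.0)


def f84_distance(seq_a: str, seq_b: str, params: F84Params | None = None) -> float:
    """F84 distance (substitutions/site) between two aligned IUPAC sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    params = params or F84Params()
    if params.base_frequencies is None:
        freqs = empirical_base_frequencies(
            AlignedMarkerSet("pair", ["a", "b"], [seq_a.upper(), seq_b.upper()])
        )
    else:
        freqs = params.base_frequencies
    p_sum, q_sum, n_comp = _pq_counts(_seq_weights(seq_a.upper()),
                                      _seq_weights(seq_b.upper()))
    if n_comp == 0:
        raise ValueError("no comparable sites after missing-data exclusion")
    return f84_from_proportions(
        p_sum / n_comp, q_sum / n_comp, freqs, params.saturation_ceiling
    )


def pairwise_distance_matrix(
    marker: AlignedMarkerSet,
    params: F84Params | None = None,
    chunk_size: int = 4096,
) -> DistanceMatrix:
    """All n(n-1)/2 F84 distances between the sequences of one marker.

    Base frequencies default to the empirical composition of the whole
    marker set (not per pair). Computation is vectorised over chunks of
    pairs; ``level`` of the result is ``individual``.
    """
    if marker.n_samples < 2:
        raise ValueError("need at least 2 samples")
    params = params or F84Params()
    freqs = (
        params.base_frequencies
        if params.base_frequencies is not None
        else empirical_base_frequencies(marker)
    )
    a, b, c = _f84_constants(freqs)
    w = marker.allele_weights()
    n = marker.n_samples
    pairs = np.array(list(itertools.combinations(range(n), 2)))
    dist = np.zeros((n, n))
    n_saturated = 0
    for start in range(0, len(pairs), chunk_size):
        sel = pairs[start: start + chunk_size]
        p_sum, q_sum, n_comp = _pq_counts(w[sel[:, 0]], w[sel[:, 1]])
        if np.any(n_comp == 0):
            bad = sel[n_comp == 0][0]
            raise ValueError(
                f"no comparable sites between {marker.sample_ids[bad[0]]!r} "
                f"and {marker.sample_ids[bad[1]]!r}"
            )
        p = p_sum / n_comp
        q = q_sum / n_comp
        arg1 = 1.0 - p / (2 * a) - (a - b) * q / (2 * a * c)
        arg2 = 1.0 - q / (2 * c)
        ok = (arg1 > 0) & (arg2 > 0)
        d = np.full(len(sel), params.saturation_ceiling)
        d[ok] = np.maximum(
            -2 * a * np.log(arg1[ok]) + 2 * (a - b - c) * np.log(arg2[ok]), 0.0
        )
        n_saturated += int((~ok).sum())
        dist[sel[:, 0], sel[:, 1]] = d
        dist[sel[:, 1], sel[:, 0]] = d
    if n_saturated:
        warnings.warn(
            f"{n_saturated} saturated pair(s) recorded at ceiling "
            f"{params.saturation_ceiling}",
            RuntimeWarning,
            stacklevel=2,
        )
    return DistanceMatrix(list(marker.sample_ids), dist, level="individual")


def population_mean_distances(
    ind_matrix: DistanceMatrix, popmap: PopulationMap
) -> DistanceMatrix:
    """Average cross-population individual distances into a population matrix.

    Entry (p, q) for p != q is the arithmetic mean of all individual
    distances with one member in p and the other in q; the diagonal is 0.
    """
    pops = popmap.populations
    indices: dict[str, list[int]] = {p: [] for p in pops}
    for i, label in enumerate(ind_matrix.labels):
        pop = popmap.sample_to_population.get(label)
        if pop is None:
            raise KeyError(f"label {label!r} missing from the population map")
        indices[pop].append(i)
    empty = [p for p, idx in indices.items() if not idx]
    if empty:
        raise ValueError(f"population(s) with no samples in the matrix: {empty}")
    k = len(pops)
    out = np.zeros((k, k))
    for (ia, pa), (ib, pb) in itertools.combinations(enumerate(pops), 2):
        block = ind_matrix.values[np.ix_(indices[pa], indices[pb])]
        out[ia, ib] = out[ib, ia] = block.mean()
    return DistanceMatrix(list(pops), out, level="population")


def combine_markers_euclidean(matrices: list[DistanceMatrix]) -> DistanceMatrix:
    """Entrywise sqrt of the sum of squares across marker matrices."""
    if not matrices:
        raise ValueError("no matrices to combine")
    ref = matrices[0]
    aligned = [ref.values]
    for m in matrices[1:]:
        if set(m.labels) != set(ref.labels):
            raise ValueError("marker matrices have different label sets")
        aligned.append(m.reorder(ref.labels).values)
    combined = np.sqrt(np.sum([v ** 2 for v in aligned], axis=0))
    return DistanceMatrix(list(ref.labels), combined, level=ref.level)
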