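"""Cluster construction and statistical comparison of population groups.

Covers the downstream inference applied to every population distance
matrix: furthest-neighbour (complete-linkage) dendrograms, a label
permutation test of within- versus among-cluster mean distance, one-way
ANOVA with Bonferroni-adjusted pairwise post-hoc t-tests (pooled
within-group variance), and a one-sample Kolmogorov-Smirnov normality
check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import Dendrogram, DistanceMatrix

__all__ = [
    "complete_linkage_tree",
    "PermutationResult",
    "permutation_test",
    "AnovaResult",
    "one_way_anova",
    "bonferroni_posthoc",
    "ks_normality",
]


def complete_linkage_tree(matrix: DistanceMatrix) -> Dendrogram:
    """Furthest-neighbour agglomeration of a distance matrix.

    At each step the pair of clusters with minimal distance is merged;
    the distance between clusters is the maximum over cross pairs. Ties
    are broken deterministically in favour of the pair whose smallest
    original leaf indices are lexicographically lowest.
    """
    n = matrix.n
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if np.any(~np.isfinite(matrix.values)):
        raise ValueError("distance matrix contains NaN/inf")
    # active cluster id -> (representative = smallest leaf index, member leaves)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(matrix.values[i, j])
        for i, j in itertools.combinations(range(n), 2)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        best_key = None
        for (i, j), d in dist.items():
            key = (d, min(members[i]), min(members[j]))
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j)
        i, j = best
        height = dist[(i, j)]
        del dist[(i, j)]
        # list the cluster with the smallest original leaf first
        if min(members[j]) < min(members[i]):
            i, j = j, i
        merged = members.pop(i) + members.pop(j)
        new_dist = {}
        for k in members:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            new_dist[(k, next_id)] = max(dik, djk)
        dist.update(new_dist)
        members[next_id] = merged
        merges.append((i, j, height))
        next_id += 1
    return Dendrogram(list(matrix.labels), merges)


@dataclass
class PermutationResult:
    observed_within: float
    observed_among: float
    statistic: float          # among - within
    n_permutations: int
    p_estimate: float
    seed: int | None
    exhaustive: bool = False


def _within_among(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    d = values[iu]
    within = d[same]
    among = d[~same]
    if among.size == 0:
        raise ValueError("all populations in one cluster")
    w = float(within.mean()) if within.size else float("nan")
    return w, float(among.mean())


def _distinct_label_permutations(labels: list[str]):
    """Yield distinct orderings of a label multiset (recursive, sorted)."""
    counts = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    keys = sorted(counts)
    out = [None] * len(labels)

    def rec(pos: int):
        if pos == len(labels):
            yield tuple(out)
            return
        for k in keys:
            if counts[k]:
                counts[k] -= 1
                out[pos] = k
                yield from rec(pos + 1)
                counts[k] += 1

    yield from rec(0)


def permutation_test(
    matrix: DistanceMatrix,
    clusters: dict[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Compare within- vs among-cluster mean distance by label permutation.

    The statistic is (mean among-cluster distance) - (mean within-cluster
    distance), pooled over pairs (pair-weighted). The null distribution
    permutes cluster labels over populations, preserving cluster sizes.
    The Monte-Carlo p uses the add-one estimator
    ``(1 + #{permuted >= observed}) / (n_perm + 1)`` so it is never 0;
    with ``exhaustive=True`` all distinct label assignments are
    enumerated instead and the observed one counts itself.

    Clusters of size 1 contribute no within pairs and are excluded from
    the within mean with a warning.
    """
    missing = [p for p in matrix.labels if p not in clusters]
    if missing:
        raise KeyError(f"populations without cluster assignment: {missing}")
    labels = np.array([clusters[p] for p in matrix.labels])
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    sizes = pd.Series(labels).value_counts()
    singletons = sizes[sizes == 1].index.tolist()
    if singletons:
        warnings.warn(
            f"cluster(s) {singletons} have a single population and "
            "contribute no within-cluster pairs",
            RuntimeWarning,
            stacklevel=2,
        )
    obs_within, obs_among = _within_among(matrix.values, labels)
    if math.isnan(obs_within):
        raise ValueError("no within-cluster pairs at all")
    observed = obs_among - obs_within

    if exhaustive:
        counts = pd.Series(labels).value_counts()
        total = math.factorial(len(labels))
        for c in counts:
            total //= math.factorial(int(c))
        if total > 2_000_000:
            raise ValueError(f"{total} distinct assignments; too many to enumerate")
        n_ge = 0
        n_all = 0
        for perm in _distinct_label_permutations(list(labels)):
            w, a = _within_among(matrix.values, np.array(perm))
            n_all += 1
            if a - w >= observed - 1e-12:
                n_ge += 1
        p = n_ge / n_all
        return PermutationResult(obs_within, obs_among, observed, n_all, p,
                                 seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w, a = _within_among(matrix.values, perm)
        if a - w >= observed - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return PermutationResult(obs_within, obs_among, observed, n_perm, p, seed)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    msw: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (SSB/SSW decomposition)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups differ in length")
    uniq = list(dict.fromkeys(groups.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: values[groups == g] for g in uniq}
    if all(len(v) < 2 for v in by_group.values()):
        raise ValueError("at least one group needs >= 2 values")
    grand = values.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    df_b = len(uniq) - 1
    df_w = len(values) - len(uniq)
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        if msb == 0:
            raise ValueError("zero variance within and between groups: F undefined")
        f = float("inf")
        p = 0.0
    else:
        f = msb / msw
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        F=float(f), df_between=df_b, df_within=df_w, p=p, msw=float(msw),
        group_means={g: float(v.mean()) for g, v in by_group.items()},
        group_sizes={g: int(len(v)) for g, v in by_group.items()},
    )


def bonferroni_posthoc(values, groups) -> pd.DataFrame:
    """Pairwise two-sided t-tests with pooled MSW, Bonferroni-adjusted.

    Each pair is tested with the pooled within-group variance (MSW) and
    its ANOVA degrees of freedom; raw p-values are multiplied by the
    number of pairs and capped at 1.
    """
    res = one_way_anova(values, groups)
    pairs = list(itertools.combinations(res.group_means, 2))
    rows = []
    for a, b in pairs:
        se = math.sqrt(res.msw * (1 / res.group_sizes[a] + 1 / res.group_sizes[b]))
        if se == 0:
            raise ValueError("zero pooled variance: t undefined")
        t = (res.group_means[a] - res.group_means[b]) / se
        p_raw = 2 * float(stats.t.sf(abs(t), res.df_within))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": t,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def ks_normality(values, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample mean and SD.

    By default the asymptotic KS p-value is used with the estimated
    parameters plugged in (the legacy one-sample procedure of classical
    statistics packages); it is conservative because estimation is not
    accounted for. ``lilliefors=True`` applies the Lilliefors correction
    instead.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        d, p = _lf(values, dist="norm")
        return float(d), float(p)
    d, p = stats.kstest(values, "norm", args=(values.mean(), sd))
    return float(d), float(p)
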