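"""Published summary data for the 14-population *Chthamalus stellatus* survey.

The survey genotyped 14 Mediterranean and East-Atlantic populations of
Poli's stellate barnacle at two nuclear markers (EF1, 425 aligned
positions; NaKA, 239 positions). The tables below carry its published
per-population diversity statistics (marker-averaged), the four-cluster
assignment of the populations (EA = Eastern Atlantic, WM = Western
Mediterranean, MM = Mid-Mediterranean, EM = Eastern Mediterranean), the
per-population sample sizes, and the published within-cluster means of
the SNP-distribution population distances. They serve as fixed inputs
for deterministic cross-checks of the inference stage.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SAMPLE_SIZES",
    "CLUSTERS",
    "diversity_table",
    "WITHIN_CLUSTER_SNP_MEANS",
]

#: Individuals genotyped per population and marker (EF1, NaKA).
SAMPLE_SIZES: dict[str, tuple[int, int]] = {
    "Bastia": (21, 22),
    "Biarritz": (21, 25),
    "Birzebbuga": (20, 21),
    "Bizerte": (23, 23),
    "Bodrum": (22, 25),
    "Canary Islands": (25, 15),
    "Dubrovnik": (24, 26),
    "Fazana": (27, 27),
    "Larnaca": (27, 28),
    "Madeira": (18, 15),
    "Malaga": (27, 26),
    "Melilla": (22, 23),
    "Pantelleria": (21, 22),
    "Rethymno": (17, 18),
}

#: Four-cluster division of the populations.
CLUSTERS: dict[str, str] = {
    "Biarritz": "EA", "Canary Islands": "EA", "Madeira": "EA",
    "Bizerte": "WM", "Malaga": "WM", "Melilla": "WM",
    "Bastia": "MM", "Birzebbuga": "MM", "Pantelleria": "MM",
    "Bodrum": "EM", "Dubrovnik": "EM", "Fazana": "EM",
    "Larnaca": "EM", "Rethymno": "EM",
}

_DIVERSITY_ROWS = [
    # population, mean alleles/position, expected heterozygosity, % polymorphic
    ("Bastia", 1.870, 0.198, 74.394),
    ("Biarritz", 1.391, 0.072, 37.576),
    ("Birzebbuga", 1.785, 0.215, 65.909),
    ("Bizerte", 1.721, 0.151, 61.212),
    ("Bodrum", 1.979, 0.229, 79.091),
    ("Canary Islands", 1.389, 0.083, 35.606),
    ("Dubrovnik", 1.933, 0.228, 75.758),
    ("Fazana", 1.997, 0.228, 82.273),
    ("Larnaca", 1.902, 0.226, 77.576),
    ("Madeira", 1.302, 0.054, 28.636),
    ("Malaga", 1.762, 0.144, 69.697),
    ("Melilla", 1.864, 0.168, 70.758),
    ("Pantelleria", 1.917, 0.203, 77.424),
    ("Rethymno", 1.902, 0.241, 72.576),
]


def diversity_table() -> pd.DataFrame:
    """Published marker-averaged diversity statistics, one row per population.

    Columns: ``mean_alleles_per_position``, ``expected_heterozygosity``,
    ``percent_polymorphic``, ``cluster``.
    """
    df = pd.DataFrame(
        _DIVERSITY_ROWS,
        columns=[
            "population",
            "mean_alleles_per_position",
            "expected_heterozygosity",
            "percent_polymorphic",
        ],
    ).set_index("population")
    df["cluster"] = df.index.map(CLUSTERS)
    return df


#: Published mean SNP-distribution distance within each cluster, per metric.
WITHIN_CLUSTER_SNP_MEANS: dict[str, dict[str, float]] = {
    "sq_euclidean": {"EA": 0.0185, "WM": 0.0186, "MM": 0.0142, "EM": 0.0184},
    "sq_chord": {"EA": 0.0362, "WM": 0.0244, "MM": 0.0202, "EM": 0.0238},
    "manhattan": {"EA": 0.0869, "WM": 0.1186, "MM": 0.1223, "EM": 0.1428},
}
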