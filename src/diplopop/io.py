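"""Readers and writers: aligned FASTA, population maps, matrices, trees.

All alignment coordinates in error messages are 1-based; internal storage
is 0-based.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import AlignedMarkerSet, DistanceMatrix, Dendrogram, PopulationMap

__all__ = [
    "read_aligned_fasta",
    "write_fasta",
    "load_population_map",
    "write_population_map",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_newick",
]


def read_aligned_fasta(path: str | os.PathLike, marker_name: str) -> AlignedMarkerSet:
    """Read an aligned (equal-length) IUPAC FASTA file.

    Symbol case is normalised to upper; all structural checks (equal
    lengths, legal alphabet, unique ids) are enforced by
    :class:`~diplopop.model.AlignedMarkerSet`.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs.append(str(record.seq).upper())
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return AlignedMarkerSet(marker_name, ids, seqs)


def write_fasta(path: str | os.PathLike, marker: AlignedMarkerSet) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(marker.sample_ids, marker.sequences):
            fh.write(f">{sid}\n{seq}\n")


def load_population_map(path: str | os.PathLike) -> PopulationMap:
    """Load a delimited table with columns ``sample_id, population[, cluster]``.

    The delimiter (tab or comma) is sniffed; a header row is required.
    Duplicate sample rows and missing mandatory columns are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"population map missing column(s): {sorted(missing)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample_id rows: {sorted(set(dupes))}")
    sample_to_pop = dict(zip(df["sample_id"], df["population"]))
    pop_to_cluster = None
    if "cluster" in df.columns:
        sub = df.dropna(subset=["cluster"])[["population", "cluster"]].drop_duplicates()
        conflicting = sub["population"][sub["population"].duplicated()].tolist()
        if conflicting:
            raise ValueError(
                f"populations assigned to multiple clusters: {sorted(set(conflicting))}"
            )
        pop_to_cluster = dict(zip(sub["population"], sub["cluster"]))
    return PopulationMap(sample_to_pop, pop_to_cluster)


def write_population_map(path: str | os.PathLike, popmap: PopulationMap) -> None:
    with open(path, "w") as fh:
        if popmap.population_to_cluster:
            fh.write("sample_id\tpopulation\tcluster\n")
            for sid, pop in popmap.sample_to_population.items():
                cl = popmap.population_to_cluster.get(pop, "")
                fh.write(f"{sid}\t{pop}\t{cl}\n")
        else:
            fh.write("sample_id\tpopulation\n")
            for sid, pop in popmap.sample_to_population.items():
                fh.write(f"{sid}\t{pop}\n")


def write_distance_matrix(
    matrix: DistanceMatrix, path: str | os.PathLike, dialect: str = "csv"
) -> None:
    """Write a matrix as ``csv`` (labelled) or square ``phylip``.

    Values are written with enough digits to round-trip to 6 decimals.
    """
    if dialect == "csv":
        df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
        df.to_csv(path, float_format="%.10g")
    elif dialect == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{matrix.n}\n")
            for label, row in zip(matrix.labels, matrix.values):
                safe = label.replace(" ", "_")
                fh.write(safe + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_distance_matrix(
    path: str | os.PathLike, dialect: str = "csv", level: str = "population"
) -> DistanceMatrix:
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0)
        return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(float), level)
    elif dialect == "phylip":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return DistanceMatrix(labels, np.array(rows), level)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_newick(tree: Dendrogram, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
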