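"""End-to-end orchestration of the three analysis approaches.

``run_full_analysis`` reproduces the complete workflow on a pair of
aligned marker FASTAs (or in-memory marker sets): genotype-based F84
distances, haplotype-based distances, the SNP-distribution method under
all three metrics, dendrograms for each final matrix, the diversity
table, cluster permutation tests and ANOVA comparisons, plus a manifest
recording the seed and every modelling assumption in force.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .diversity import diversity_summary
from .genotype import (
    F84Params,
    combine_markers_euclidean,
    pairwise_distance_matrix,
    population_mean_distances,
)
from .haplotype import haplotype_population_matrix
from .inference import (
    bonferroni_posthoc,
    complete_linkage_tree,
    ks_normality,
    one_way_anova,
    permutation_test,
)
from .io import (
    load_population_map,
    read_aligned_fasta,
    write_distance_matrix,
    write_newick,
)
from .model import AlignedMarkerSet, PopulationMap
from .snp import (
    METRICS,
    find_polymorphic_positions,
    population_site_frequencies,
    snp_combined_matrix,
    snp_population_matrix,
)

__all__ = ["RunConfig", "run_full_analysis", "run_from_config"]

log = logging.getLogger("diplopop")

#: Modelling assumptions recorded in every run manifest.
DECISIONS_IN_FORCE = [
    "gap and N symbols treated as missing data",
    "F84 base frequencies empirical over the whole marker set unless overridden",
    "IUPAC two-base codes counted fractionally; shared base mass matched first",
    "saturated F84 pairs recorded at the configured ceiling distance",
    "haplotypes phased by the deterministic alphabetical rule (no linkage)",
    "SNP allele counting is haplotype-based (each diploid contributes 2)",
    "polymorphism for SNP selection is pooled over all populations",
    "missing alleles excluded from per-population site denominators",
    "diversity statistics averaged over markers unweighted",
    "per-population polymorphism counted within the population",
    "expected-heterozygosity denominator is the full marker length",
    "complete-linkage ties broken by lowest original leaf index pair",
    "permutation p uses the add-one estimator, one-sided (among - within)",
    "Newick branch lengths: ultrametric, (parent - child height)/2",
]


@dataclass
class RunConfig:
    """File-level configuration of a full run."""

    fasta_paths: list[str]
    marker_names: list[str]
    popmap_path: str
    out_dir: str
    metric: str = "all"
    ts_tv_ratio: float = 2.0
    n_perm: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.metric not in (*METRICS, "all"):
            raise ValueError(f"metric must be one of {METRICS} or 'all'")
        if len(self.fasta_paths) != len(self.marker_names):
            raise ValueError("need one marker name per FASTA path")


def run_from_config(config: RunConfig) -> dict:
    markers = [
        read_aligned_fasta(p, name)
        for p, name in zip(config.fasta_paths, config.marker_names)
    ]
    popmap = load_population_map(config.popmap_path)
    metrics = list(METRICS) if config.metric == "all" else [config.metric]
    return run_full_analysis(
        markers,
        popmap,
        config.out_dir,
        metrics=metrics,
        params=F84Params(ts_tv_ratio=config.ts_tv_ratio),
        n_perm=config.n_perm,
        seed=config.seed,
    )


def run_full_analysis(
    markers: list[AlignedMarkerSet],
    popmap: PopulationMap,
    out_dir: str | Path,
    metrics: list[str] | None = None,
    params: F84Params | None = None,
    n_perm: int = 1000,
    seed: int = 42,
) -> dict:
    """Run every stage and write the output bundle under ``out_dir``.

    Returns a dict of in-memory results (matrices, trees, tables, test
    results) mirroring the files written. Any stage failure aborts with
    the stage name; artifacts of completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = metrics or list(METRICS)
    params = params or F84Params()
    for marker in markers:
        popmap.require_complete(marker)
    results: dict = {"trees": {}, "matrices": {}, "permutation": {}}
    stage = "setup"
    try:
        # ------------------------------------------------ genotype-based
        stage = "genotype"
        log.info("stage %s", stage)
        geno_pop = []
        for marker in markers:
            ind = pairwise_distance_matrix(marker, params)
            write_distance_matrix(
                ind, out / f"genotype_individual_{marker.marker_name}.csv"
            )
            pop = population_mean_distances(ind, popmap)
            write_distance_matrix(
                pop, out / f"genotype_population_{marker.marker_name}.csv"
            )
            geno_pop.append(pop)
        geno_combined = combine_markers_euclidean(geno_pop)
        write_distance_matrix(geno_combined, out / "genotype_population_combined.csv")
        write_distance_matrix(
            geno_combined, out / "genotype_population_combined.phy", "phylip"
        )
        tree = complete_linkage_tree(geno_combined)
        write_newick(tree, out / "genotype_tree.nwk")
        results["matrices"]["genotype"] = geno_combined
        results["trees"]["genotype"] = tree

        # ----------------------------------------------- haplotype-based
        stage = "haplotype"
        log.info("stage %s", stage)
        hap_combined, hap_pop, _ = haplotype_population_matrix(
            markers, popmap, params
        )
        for marker, pop in zip(markers, hap_pop):
            write_distance_matrix(
                pop, out / f"haplotype_population_{marker.marker_name}.csv"
            )
        write_distance_matrix(hap_combined, out / "haplotype_population_combined.csv")
        tree = complete_linkage_tree(hap_combined)
        write_newick(tree, out / "haplotype_tree.nwk")
        results["matrices"]["haplotype"] = hap_combined
        results["trees"]["haplotype"] = tree

        # --------------------------------------------- SNP-distribution
        stage = "snp_profile"
        log.info("stage %s", stage)
        profiles = {}
        for marker in markers:
            positions = find_polymorphic_positions(marker)
            if not positions:
                raise ValueError(
                    f"marker {marker.marker_name!r} has no polymorphic positions"
                )
            profiles[marker.marker_name] = population_site_frequencies(
                marker, popmap, positions
            )
        for metric in metrics:
            per_marker = []
            audit_lines = ["marker\tposition\tpop_a\tpop_b\tdistance"]
            for marker in markers:
                audit: dict = {}
                mat = snp_population_matrix(
                    profiles[marker.marker_name], metric, audit
                )
                for (pa, pb), dvec in audit["per_site"].items():
                    for pos, d in zip(audit["positions"], dvec):
                        audit_lines.append(
                            f"{marker.marker_name}\t{pos}\t{pa}\t{pb}\t{d:.10g}"
                        )
                write_distance_matrix(
                    mat, out / f"snp_{metric}_{marker.marker_name}.csv"
                )
                per_marker.append(mat)
            combined = snp_combined_matrix(per_marker)
            write_distance_matrix(combined, out / f"snp_{metric}_combined.csv")
            write_distance_matrix(
                combined, out / f"snp_{metric}_combined.phy", "phylip"
            )
            (out / f"snp_{metric}_per_site.tsv").write_text(
                "\n".join(audit_lines) + "\n"
            )
            tree = complete_linkage_tree(combined)
            write_newick(tree, out / f"snp_{metric}_tree.nwk")
            results["matrices"][f"snp_{metric}"] = combined
            results["trees"][f"snp_{metric}"] = tree

        # -------------------------------------------------- diversity
        stage = "diversity"
        log.info("stage %s", stage)
        summary = diversity_summary(markers, popmap)
        summary.to_tsv(out / "diversity.tsv")
        summary.per_marker.to_csv(out / "diversity_per_marker.tsv", sep="\t")
        results["diversity"] = summary

        # -------------------------------------------------- inference
        stage = "inference"
        log.info("stage %s", stage)
        clusters = popmap.population_to_cluster
        if clusters:
            for i, metric in enumerate(metrics):
                perm = permutation_test(
                    results["matrices"][f"snp_{metric}"],
                    clusters,
                    n_perm=n_perm,
                    seed=seed + i,
                )
                results["permutation"][metric] = perm
                (out / f"permutation_{metric}.json").write_text(
                    json.dumps(
                        {
                            "metric": metric,
                            "mean_within": perm.observed_within,
                            "mean_among": perm.observed_among,
                            "statistic": perm.statistic,
                            "n_permutations": perm.n_permutations,
                            "p_estimate": perm.p_estimate,
                            "seed": perm.seed,
                        },
                        indent=2,
                    )
                )
            anova_report = {}
            table = summary.overall.copy()
            table["cluster"] = table.index.map(clusters)
            for column in (
                "mean_alleles_per_position",
                "expected_heterozygosity",
                "percent_polymorphic",
            ):
                values = table[column].to_numpy()
                groups = table["cluster"].to_numpy()
                res = one_way_anova(values, groups)
                posthoc = bonferroni_posthoc(values, groups)
                d, p_ks = ks_normality(values)
                anova_report[column] = {
                    "F": res.F,
                    "df": [res.df_between, res.df_within],
                    "p": res.p,
                    "group_means": res.group_means,
                    "ks_normality": {"D": d, "p": p_ks},
                    "bonferroni": posthoc.to_dict(orient="records"),
                }
            (out / "anova.json").write_text(json.dumps(anova_report, indent=2))
            results["anova"] = anova_report

        # --------------------------------------------------- manifest
        stage = "manifest"
        manifest = {
            "diplopop_version": __version__,
            "markers": [m.marker_name for m in markers],
            "n_samples": {m.marker_name: m.n_samples for m in markers},
            "alignment_lengths": {m.marker_name: m.length for m in markers},
            "polymorphic_positions": {
                m.marker_name: find_polymorphic_positions(m) for m in markers
            },
            "metrics": metrics,
            "ts_tv_ratio": params.ts_tv_ratio,
            "saturation_ceiling": params.saturation_ceiling,
            "n_permutations": n_perm,
            "seed": seed,
            "decisions_in_force": DECISIONS_IN_FORCE,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
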