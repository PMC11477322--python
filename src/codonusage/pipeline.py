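"""End-to-end two-gene codon-usage study.

``run_pipeline`` chains every stage in the order of the original analysis:
validation, per-species indices, pooled RSCU, frequency classes and the
two-gene codon intersection, delta-RSCU optimal codons, PR2, index
correlations, hierarchical clustering, PCA (species and codon modes),
k-means on the two-gene CAI plane, and NJ trees with bootstrap. All outputs
are TSV/newick/JSON under one directory, plus a manifest describing the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .comparative import (
    delta_rscu,
    pooled_rscu,
    pr2_coordinates,
    pr2_summary,
    rank_expression_groups,
    shared_codons,
)
from .genetics import standard_code
from .indices import count_codons, rscu, summarize_indices
from .io import CdsSet, read_cds_fasta
from .multivariate import (
    DEFAULT_SEED,
    hierarchical_cluster_rscu,
    index_correlations,
    kmeans_cai,
    pca_rscu,
    rscu_matrix,
)
from .phylogeny import bootstrap_support, write_newick

logger = logging.getLogger("codonusage")

STAGES = [
    "validate",
    "indices",
    "pooled_rscu",
    "codon_sets",
    "delta_rscu",
    "pr2",
    "correlations",
    "hierarchical_clustering",
    "pca",
    "kmeans",
    "nj_bootstrap",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    fasta_a: str
    fasta_b: str
    out_dir: str
    gene_a: str = "geneA"
    gene_b: str = "geneB"
    group_size: int = 5
    delta_threshold: float = 0.08
    k: int = 3
    bootstrap_replicates: int = 1000
    seed: int = DEFAULT_SEED
    metric: str = "euclidean"
    linkage: str = "ward"
    normalization: str = "zscore"
    validation_policy: str = "trim_stop"

    def validate(self):
        if self.group_size <= 0 or self.k <= 0 or self.bootstrap_replicates <= 0:
            raise ValueError("group_size, k and bootstrap_replicates must be positive")
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be positive")


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = "species"):
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for both genes; returns the manifest dict.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of earlier stages are kept on disk.
    """
    config.validate()
    code = standard_code()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "version": __version__,
        "stages": [],
    }
    genes: dict[str, CdsSet] = {}
    results: dict = {}

    def stage(name):
        def deco(fn):
            logger.info("stage %s", name)
            try:
                info = fn() or {}
            except Exception as exc:  # abort, retain partial outputs
                _dump_manifest(manifest, out)
                raise PipelineError(name, exc) from exc
            manifest["stages"].append({"stage": name, **info})
        return deco

    @stage("validate")
    def _():
        for gene, path in ((config.gene_a, config.fasta_a), (config.gene_b, config.fasta_b)):
            genes[gene] = read_cds_fasta(path, gene, policy=config.validation_policy)
        return {"n_records": {g: len(s) for g, s in genes.items()}}

    @stage("indices")
    def _():
        for gene, cds in genes.items():
            table = summarize_indices(cds, code=code)
            results[f"indices_{gene}"] = table
            _write_tsv(table, out / f"indices_{gene}.tsv")
        return {"rows": {g: len(results[f"indices_{g}"]) for g in genes}}

    @stage("pooled_rscu")
    def _():
        for gene, cds in genes.items():
            pooled = pooled_rscu(cds, code)
            results[f"pooled_{gene}"] = pooled
            df = pd.DataFrame(
                {
                    "codon": list(pooled.values),
                    "amino_acid": [code.codon_to_aa[c] for c in pooled.values],
                    "count": [pooled.counts[c] for c in pooled.values],
                    "rscu": list(pooled.values.values()),
                }
            )
            df["high_frequency"] = df["rscu"] > 1
            _write_tsv(df, out / f"pooled_rscu_{gene}.tsv", index_label=None)
        return {"codons": len(results[f"pooled_{config.gene_a}"].values)}

    @stage("codon_sets")
    def _():
        comp = shared_codons(
            results[f"pooled_{config.gene_a}"], results[f"pooled_{config.gene_b}"]
        )
        results["codon_sets"] = comp
        rows = []
        for name, s in (
            ("high_a", comp.high_a), ("high_b", comp.high_b),
            ("low_a", comp.low_a), ("low_b", comp.low_b),
            ("shared_high", comp.shared_high), ("shared_low", comp.shared_low),
        ):
            rows.append({"set": name, "size": len(s), "codons": ",".join(sorted(s))})
        _write_tsv(pd.DataFrame(rows), out / "codon_sets.tsv", index_label=None)
        return {"shared_high": len(comp.shared_high), "shared_low": len(comp.shared_low)}

    @stage("delta_rscu")
    def _():
        info = {}
        for gene, cds in genes.items():
            per_species = {
                r.species: rscu(count_codons(r, code), code) for r in cds
            }
            results[f"per_species_rscu_{gene}"] = per_species
            high, low = rank_expression_groups(
                results[f"indices_{gene}"], g=config.group_size
            )
            res = delta_rscu(per_species, high, low, threshold=config.delta_threshold)
            results[f"delta_{gene}"] = res
            df = pd.DataFrame(
                {
                    "codon": list(res.delta),
                    "rscu_high": [res.rscu_high.values[c] for c in res.delta],
                    "rscu_low": [res.rscu_low.values[c] for c in res.delta],
                    "delta_rscu": list(res.delta.values()),
                    "optimal": [c in res.optimal_codons for c in res.delta],
                }
            )
            _write_tsv(df, out / f"delta_rscu_{gene}.tsv", index_label=None)
            info[gene] = list(res.optimal_codons)
        return {"optimal_codons": info}

    @stage("pr2")
    def _():
        info = {}
        for gene in genes:
            points = pr2_coordinates(results[f"indices_{gene}"])
            df = pd.DataFrame(
                {"species": [p.species for p in points],
                 "x_A3_AT3": [p.x for p in points],
                 "y_G3_GC3": [p.y for p in points]}
            )
            _write_tsv(df, out / f"pr2_{gene}.tsv", index_label=None)
            info[gene] = pr2_summary(points)
        results["pr2"] = info
        return {g: {"mean_x": round(v["mean_x"], 4), "mean_y": round(v["mean_y"], 4)}
                for g, v in info.items()}

    @stage("correlations")
    def _():
        for gene in genes:
            corr = index_correlations(results[f"indices_{gene}"])
            results[f"corr_{gene}"] = corr
            annotated = corr.r.round(3).astype(str) + corr.stars()
            _write_tsv(annotated, out / f"correlations_{gene}.tsv", index_label="index")
        return {"n_indices": corr.r.shape[0]}

    @stage("hierarchical_clustering")
    def _():
        for gene in genes:
            mat = rscu_matrix(results[f"per_species_rscu_{gene}"])
            results[f"rscu_matrix_{gene}"] = mat
            tree = hierarchical_cluster_rscu(mat, config.metric, config.linkage)
            (out / f"dendrogram_{gene}.nwk").write_text(tree.to_newick() + "\n")
        return {"linkage": config.linkage, "metric": config.metric}

    @stage("pca")
    def _():
        for gene in genes:
            mat = results[f"rscu_matrix_{gene}"]
            for mode in ("species", "codons"):
                res = pca_rscu(mat, mode=mode)
                _write_tsv(res.scores, out / f"pca_{mode}_scores_{gene}.tsv",
                           index_label=mode[:-1])
        return {"modes": ["species", "codons"]}

    @stage("kmeans")
    def _():
        pairs = pd.DataFrame(
            {
                config.gene_a: results[f"indices_{config.gene_a}"]["CAI"],
                config.gene_b: results[f"indices_{config.gene_b}"]["CAI"],
            }
        ).dropna()
        res = kmeans_cai(pairs, k=config.k, normalization=config.normalization,
                         seed=config.seed)
        _write_tsv(res.assignments.to_frame(), out / "kmeans_cai.tsv")
        results["kmeans"] = res
        return {"k": res.k, "inertia": round(res.inertia, 6)}

    @stage("nj_bootstrap")
    def _():
        supports = {}
        for gene in genes:
            tree, support = bootstrap_support(
                results[f"rscu_matrix_{gene}"],
                b_replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            write_newick(tree, out / f"nj_{gene}.nwk")
            rows = [
                {"bipartition": "|".join(sorted(bp)), "support": s}
                for bp, s in sorted(support.items(), key=lambda kv: -kv[1])
            ]
            _write_tsv(pd.DataFrame(rows), out / f"nj_support_{gene}.tsv",
                       index_label=None)
            supports[gene] = len(support)
        return {"n_bipartitions": supports, "B": config.bootstrap_replicates}

    _dump_manifest(manifest, out)
    return manifest


def _dump_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
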