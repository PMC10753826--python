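"""End-to-end orchestration: generate -> preprocess -> core -> ordination -> pangenome.

Each stage writes its artifacts under the output directory and the run ends
with a ``manifest.json`` recording the effective configuration, the seeds
used, package versions and a SHA-256 checksum per artifact, so two runs with
the same configuration and seed can be diffed file by file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .amplicon import (
    AsvCountTable,
    SampleMetadata,
    TaxonomyTable,
    preprocess,
    read_asv_table,
    read_metadata,
    read_taxonomy,
)
from .core import (
    DEFAULT_DETECTION_GRID,
    DEFAULT_PREVALENCE_GRID,
    build_core_layers,
    compute_core_grid,
    export_core_sets,
    innermost_core,
)
from .ordination import bray_curtis, nmds, permanova
from .pangenome import (
    build_similarity_graph,
    count_annotation_categories,
    estimate_metabolism,
    mcl_cluster,
    partition_clusters,
    presence_absence,
    read_annotations,
    read_bitscores,
    read_genome_map,
    read_modules,
)
from .simulate import CommunitySimConfig, PangenomeSimConfig, generate_community, generate_pangenome

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML/JSON-loadable via :meth:`from_file`."""

    out_dir: str = "morelbiome_out"
    seed: int = 0
    simulate: bool = True
    community: CommunitySimConfig = field(default_factory=CommunitySimConfig)
    asv_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    genus_level: bool = True
    p_grid: tuple[float, ...] = DEFAULT_PREVALENCE_GRID
    d_grid: tuple[float, ...] = DEFAULT_DETECTION_GRID
    layer_mode: str = "diagonal"
    permanova_column: str = "sample_type"
    n_permutations: int = 999
    nmds_dimensions: int = 2
    nmds_restarts: int = 20
    run_pangenome: bool = True
    pangenome_sim: PangenomeSimConfig = field(default_factory=PangenomeSimConfig)
    bitscores: str | None = None
    genome_map: str | None = None
    annotations: str | None = None
    modules: str | None = None
    pangenome_group: tuple[str, ...] | None = None
    minbit_threshold: float = 0.5
    mcl_inflation: float = 2.0
    completeness_threshold: float = 0.75

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise PipelineError("config: seed must be an integer")
        if not self.simulate:
            for name in ("asv_table", "taxonomy", "metadata"):
                path = getattr(self, name)
                if path is None:
                    raise PipelineError(f"config: {name} required when simulate=false")
                if not Path(path).exists():
                    raise PipelineError(f"config: {name} path does not exist: {path}")
            if self.run_pangenome:
                for name in ("bitscores", "genome_map"):
                    path = getattr(self, name)
                    if path is None:
                        raise PipelineError(
                            f"config: {name} required when simulate=false and "
                            "run_pangenome=true"
                        )
                    if not Path(path).exists():
                        raise PipelineError(f"config: {name} path does not exist: {path}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        if "community" in data and isinstance(data["community"], Mapping):
            comm = dict(data["community"])
            if "planted_core" in comm:
                from .simulate import PlantedTaxon

                comm["planted_core"] = [
                    PlantedTaxon(**p) if isinstance(p, Mapping) else PlantedTaxon(*p)
                    for p in comm["planted_core"]
                ]
            data["community"] = CommunitySimConfig(**comm)
        if "pangenome_sim" in data and isinstance(data["pangenome_sim"], Mapping):
            data["pangenome_sim"] = PangenomeSimConfig(**data["pangenome_sim"])
        for key in ("p_grid", "d_grid", "pangenome_group"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, Mapping):
            raise PipelineError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_jsonable(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all enabled stages; returns the manifest dictionary.

    A failing stage aborts the run with :class:`PipelineError` naming the
    stage; artifacts written by earlier stages are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    summary: dict[str, Any] = {}
    stage = "generate"
    try:
        if config.simulate:
            comm_cfg = dataclasses.replace(config.community, seed=config.seed)
            table, taxonomy, meta = generate_community(comm_cfg)
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            table.to_tsv(inputs / "asv_counts.tsv")
            taxonomy.to_tsv(inputs / "taxonomy.tsv")
            meta.to_tsv(inputs / "metadata.tsv")
            artifacts += [
                inputs / "asv_counts.tsv", inputs / "taxonomy.tsv", inputs / "metadata.tsv",
            ]
        else:
            table = read_asv_table(config.asv_table)
            taxonomy = read_taxonomy(config.taxonomy)
            meta = read_metadata(config.metadata)

        stage = "preprocess"
        rel = preprocess(table, taxonomy, meta, genus_level=config.genus_level)
        rel.to_tsv(out / "relative_abundance.tsv")
        artifacts.append(out / "relative_abundance.tsv")
        kept_meta = SampleMetadata(meta.table.loc[rel.sample_ids].copy())

        stage = "core"
        from .amplicon import RelAbundanceTable

        core_summary: dict[str, Any] = {}
        for stype in ("mycelium", "sclerotia", "fruiting_body"):
            samples = [s for s in rel.sample_ids if kept_meta.sample_type(s) == stype]
            if len(samples) < 2:
                continue
            sub = RelAbundanceTable(rel.values[samples].copy())
            # the pooled "unassigned" bucket is bookkeeping, not a taxon
            grid = compute_core_grid(
                sub, config.p_grid, config.d_grid, exclude=("unassigned",)
            )
            layers = build_core_layers(grid, config.layer_mode)
            export_core_sets(layers, out / f"core_layers_{stype}.json")
            grid.to_frame().to_csv(out / f"core_grid_{stype}.tsv", sep="\t", index=False)
            artifacts += [out / f"core_layers_{stype}.json", out / f"core_grid_{stype}.tsv"]
            inner, max_prev = innermost_core(grid)
            core_summary[stype] = {
                "innermost_members": sorted(inner.members),
                "innermost_thresholds": [inner.thresholds.p, inner.thresholds.d],
                "innermost_max_prevalence": max_prev,
                "n_layers": len(layers),
            }
        summary["core"] = core_summary

        stage = "ordination"
        dist = bray_curtis(rel)
        ord_result = nmds(
            dist, config.nmds_dimensions,
            seed=config.seed + 1, n_starts=config.nmds_restarts,
        )
        ord_result.coordinates.to_csv(out / "nmds_coordinates.tsv", sep="\t")
        artifacts.append(out / "nmds_coordinates.tsv")
        groups = kept_meta.groups(config.permanova_column)
        perm = permanova(
            dist, groups, n_permutations=config.n_permutations, seed=config.seed + 2
        )
        summary["ordination"] = {
            "metric": "bray-curtis",
            "level": "genus" if config.genus_level else "asv",
            "stress": ord_result.stress,
            "nmds_converged": ord_result.converged,
            "permanova_factor": config.permanova_column,
            "pseudo_F": perm.pseudo_F,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
            "group_sizes": perm.group_sizes,
        }
        (out / "ordination.json").write_text(json.dumps(summary["ordination"], indent=2))
        artifacts.append(out / "ordination.json")

        if config.run_pangenome:
            stage = "pangenome"
            if config.simulate:
                pg_cfg = dataclasses.replace(config.pangenome_sim, seed=config.seed + 3)
                bitscores, genome_map, annotations, modules = generate_pangenome(pg_cfg)
            else:
                bitscores = read_bitscores(config.bitscores)
                genome_map = read_genome_map(config.genome_map)
                annotations = read_annotations(config.annotations) if config.annotations else None
                modules = read_modules(config.modules) if config.modules else []
            graph = build_similarity_graph(bitscores, config.minbit_threshold)
            clusters = mcl_cluster(graph, inflation=config.mcl_inflation)
            clusters.to_tsv(out / "gene_clusters.tsv")
            pa = presence_absence(clusters, genome_map)
            pa.to_csv(out / "cluster_presence_absence.tsv", sep="\t")
            bins = partition_clusters(clusters, genome_map, config.pangenome_group)
            pg_summary: dict[str, Any] = {
                "n_genes": len(genome_map.mapping),
                "n_clusters": len(clusters),
                "mcl_converged": clusters.converged,
                "core_clusters": len(bins.core),
                "unique_clusters": {g: len(s) for g, s in bins.unique.items()},
                "accessory_clusters": len(bins.accessory),
            }
            if bins.group_core is not None:
                pg_summary["group_core_clusters"] = len(bins.group_core)
            artifacts += [out / "gene_clusters.tsv", out / "cluster_presence_absence.tsv"]
            if annotations is not None and modules:
                metab = estimate_metabolism(
                    modules, annotations, genome_map, config.completeness_threshold
                )
                metab.to_csv(out / "module_completeness.tsv", sep="\t", index=False)
                artifacts.append(out / "module_completeness.tsv")
                pg_summary["n_modules"] = len(modules)
                pg_summary["complete_module_fraction"] = float(metab["complete"].mean())
            if annotations is not None:
                cats = count_annotation_categories(annotations, genome_map)
                cats.to_csv(out / "category_counts.tsv", sep="\t")
                artifacts.append(out / "category_counts.tsv")
            summary["pangenome"] = pg_summary
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "morelbiome",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "seed": config.seed,
        "config": config.to_jsonable(),
        "summary": summary,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
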