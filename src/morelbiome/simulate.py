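"""Synthetic amplicon communities and pangenomes with planted structure.

The community generator emulates the structure of a morel (Morchella)
bacteriome survey: three fungal structure types — mycelium, sclerotia and
fruiting bodies — each carrying its own planted core taxa, a shared pool of
background genera, and no-template control samples containing reagent
contaminants.  Mycelium and sclerotia receive a single high-occupancy,
high-abundance dominant genus (Pseudomonas-like); fruiting bodies receive a
diffuse low-occupancy, low-abundance core.  The generative model is:

* presence of a planted taxon in a sample of its type is Bernoulli(pi),
* present planted taxa claim their mean relative abundance mu of the
  sample's composition; background genera share the remaining mass with
  log-normal weights,
* the realised composition is a Dirichlet perturbation of that target
  profile and read counts are multinomial at a uniform-random depth.

The pangenome generator plants gene clusters across a set of genomes —
single-copy core clusters (one member per genome), genome-unique clusters
and optional group-specific clusters — and emits pairwise protein bitscores
drawn from separated within-/between-cluster distributions, a gene-to-genome
map, KO / category annotations, and stepwise metabolic-module definitions
with known per-genome completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import (
    RANKS,
    UNASSIGNED,
    AsvCountTable,
    SampleMetadata,
    TaxonomyTable,
)
from .pangenome import AnnotationTable, BitscoreTable, GenomeMap, KeggModule

__all__ = [
    "PlantedTaxon",
    "CommunitySimConfig",
    "generate_community",
    "PangenomeSimConfig",
    "generate_pangenome",
    "planted_clusters",
]


@dataclass(frozen=True)
class PlantedTaxon:
    """A core taxon planted into one sample type.

    ``occupancy`` (pi) is the probability the taxon is present in a sample of
    that type; ``mean_abundance`` (mu) is its expected relative abundance
    conditional on presence.
    """

    taxon_id: str
    sample_type: str
    occupancy: float
    mean_abundance: float


def _default_planted() -> tuple[PlantedTaxon, ...]:
    # Study conditions: a Pseudomonas-like dominant in mycelium (pi=0.95) and
    # sclerotia (pi=1.0) at mu=0.2; a diffuse fruiting-body core at pi=0.55,
    # mu=0.02; Ralstonia-like secondary core in the vegetative structures.
    return (
        PlantedTaxon("Pseudomonas", "mycelium", 0.95, 0.20),
        PlantedTaxon("Pseudomonas", "sclerotia", 1.00, 0.20),
        PlantedTaxon("Ralstonia", "mycelium", 0.70, 0.05),
        PlantedTaxon("Ralstonia", "sclerotia", 0.70, 0.05),
        PlantedTaxon("Pedobacter", "fruiting_body", 0.55, 0.02),
        PlantedTaxon("Bradyrhizobium", "fruiting_body", 0.55, 0.02),
    )


@dataclass
class CommunitySimConfig:
    """Parameters of the community generator (defaults = study conditions)."""

    n_samples_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"mycelium": 26, "fruiting_body": 10, "sclerotia": 8}
    )
    n_background_taxa: int = 40
    planted_core: Sequence[PlantedTaxon] = field(default_factory=_default_planted)
    background_lognormal: tuple[float, float] = (0.0, 1.5)
    background_occupancy: float = 0.3
    depth_range: tuple[int, int] = (2000, 20000)
    n_controls: int = 2
    contaminant_taxa: Sequence[str] = ("contaminant_1", "contaminant_2")
    contaminant_mean_abundance: float = 0.002
    contaminant_occupancy: float = 0.5
    dirichlet_concentration: float = 200.0
    n_nonbacterial: int = 2
    n_placeholder_genus: int = 3
    seed: int = 0

    def validate(self) -> None:
        for t, n in self.n_samples_per_type.items():
            if t not in ("mycelium", "sclerotia", "fruiting_body"):
                raise ValueError(f"n_samples_per_type: unknown sample type {t!r}")
            if n < 0:
                raise ValueError(f"n_samples_per_type[{t!r}] must be >= 0")
        if self.n_background_taxa < 1:
            raise ValueError("n_background_taxa must be >= 1")
        mu_per_type: dict[str, float] = {}
        for pt in self.planted_core:
            if not (0.0 <= pt.occupancy <= 1.0):
                raise ValueError(
                    f"planted_core: occupancy of {pt.taxon_id!r} outside [0, 1]"
                )
            if not (0.0 < pt.mean_abundance < 1.0):
                raise ValueError(
                    f"planted_core: mean_abundance of {pt.taxon_id!r} outside (0, 1)"
                )
            mu_per_type[pt.sample_type] = (
                mu_per_type.get(pt.sample_type, 0.0) + pt.mean_abundance
            )
        for t, total in mu_per_type.items():
            if total + len(self.contaminant_taxa) * self.contaminant_mean_abundance >= 1.0:
                raise ValueError(
                    f"planted_core: total mean abundance for {t!r} must be < 1"
                )
        if self.background_lognormal[1] <= 0:
            raise ValueError("background_lognormal: sd must be > 0")
        if not (0.0 < self.background_occupancy <= 1.0):
            raise ValueError("background_occupancy must lie in (0, 1]")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range: need 1 <= min <= max")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        if self.n_controls > 0 and not self.contaminant_taxa:
            raise ValueError("contaminant_taxa must be non-empty when n_controls > 0")
        if not (0.0 <= self.contaminant_occupancy <= 1.0):
            raise ValueError("contaminant_occupancy must lie in [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.n_nonbacterial < 0:
            raise ValueError("n_nonbacterial must be >= 0")
        if self.n_placeholder_genus > self.n_background_taxa:
            raise ValueError("n_placeholder_genus cannot exceed n_background_taxa")


_BG_PHYLA = ("Proteobacteria", "Bacteroidota", "Actinobacteriota", "Firmicutes")


def _taxonomy_rows(
    planted_genera: list[str],
    background: list[str],
    contaminants: list[str],
    nonbacterial: list[str],
    n_placeholder: int,
) -> pd.DataFrame:
    rows: dict[str, tuple[str, ...]] = {}

    def lineage(genus: str, kingdom: str = "Bacteria", phylum: str = "Proteobacteria"):
        return (kingdom, phylum, UNASSIGNED, UNASSIGNED, UNASSIGNED, genus, UNASSIGNED)

    for g in planted_genera:
        rows[f"asv_{g}"] = lineage(g)
    for i, g in enumerate(background):
        genus = "uncultured" if i >= len(background) - n_placeholder else g
        rows[f"asv_{g}"] = lineage(genus, phylum=_BG_PHYLA[i % len(_BG_PHYLA)])
    for g in contaminants:
        rows[f"asv_{g}"] = lineage(g)
    for g in nonbacterial:
        rows[f"asv_{g}"] = lineage(g, kingdom="Eukaryota")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))


def generate_community(
    config: CommunitySimConfig,
) -> tuple[AsvCountTable, TaxonomyTable, SampleMetadata]:
    """Draw one synthetic survey: counts, taxonomy and sample metadata.

    Deterministic under ``config.seed``; every control sample contains every
    contaminant taxon with a positive count.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    planted_genera = sorted({pt.taxon_id for pt in config.planted_core})
    background = [f"Genus_{i:03d}" for i in range(config.n_background_taxa)]
    contaminants = list(config.contaminant_taxa)
    nonbacterial = [f"Eukaryote_{i}" for i in range(config.n_nonbacterial)]
    taxa = planted_genera + background + contaminants + nonbacterial
    features = [f"asv_{t}" for t in taxa]
    index = {t: i for i, t in enumerate(taxa)}

    planted_by_type: dict[str, list[PlantedTaxon]] = {}
    for pt in config.planted_core:
        planted_by_type.setdefault(pt.sample_type, []).append(pt)

    clades = ("Elata", "Esculenta", "Rufobrunnea")
    sample_ids: list[str] = []
    meta_rows: list[tuple[str, str, str]] = []
    columns: list[np.ndarray] = []

    def draw_counts(profile: np.ndarray) -> np.ndarray:
        pos = profile > 0
        alpha = config.dirichlet_concentration * profile[pos]
        comp = np.zeros_like(profile)
        comp[pos] = rng.dirichlet(alpha)
        depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
        return rng.multinomial(depth, comp)

    specimen = 0
    for stype in ("mycelium", "fruiting_body", "sclerotia"):
        n = config.n_samples_per_type.get(stype, 0)
        for k in range(n):
            specimen += 1
            sid = f"{stype[0].upper()}{k + 1:02d}"
            profile = np.zeros(len(taxa))
            for pt in planted_by_type.get(stype, ()):
                if rng.random() < pt.occupancy:
                    profile[index[pt.taxon_id]] += pt.mean_abundance
            for c in contaminants:
                if rng.random() < config.contaminant_occupancy:
                    profile[index[c]] = config.contaminant_mean_abundance
            remaining = 1.0 - profile.sum()
            weights = rng.lognormal(*config.background_lognormal, len(background))
            # High between-sample turnover: each background genus occurs in a
            # Bernoulli(background_occupancy) subset of samples.
            mask = rng.random(len(background)) < config.background_occupancy
            if not mask.any():
                mask[:] = True
            weights = weights * mask
            bg_idx = [index[b] for b in background]
            profile[bg_idx] = remaining * weights / weights.sum()
            counts = draw_counts(profile)
            sample_ids.append(sid)
            meta_rows.append((stype, clades[(specimen - 1) % len(clades)], f"SP{specimen:03d}"))
            columns.append(counts)

    for k in range(config.n_controls):
        sid = f"NTC{k + 1:02d}"
        profile = np.zeros(len(taxa))
        for c in contaminants:
            profile[index[c]] = 1.0 / len(contaminants)
        counts = draw_counts(profile)
        for c in contaminants:  # controls must contain every contaminant
            counts[index[c]] = max(counts[index[c]], 1)
        sample_ids.append(sid)
        meta_rows.append(("control", "unknown", f"NTC{k + 1:03d}"))
        columns.append(counts)

    counts_df = pd.DataFrame(
        np.column_stack(columns) if columns else np.zeros((len(taxa), 0), dtype=int),
        index=features,
        columns=sample_ids,
        dtype=np.int64,
    )
    taxonomy = TaxonomyTable(
        _taxonomy_rows(
            planted_genera, background, contaminants, nonbacterial,
            config.n_placeholder_genus,
        )
    )
    meta = SampleMetadata(
        pd.DataFrame(
            meta_rows, index=sample_ids, columns=["sample_type", "clade", "specimen_id"]
        )
    )
    return AsvCountTable(counts_df), taxonomy, meta


# ---------------------------------------------------------------------------
# pangenome generator


@dataclass
class PangenomeSimConfig:
    """Parameters of the pangenome generator.

    Defaults emulate a six-strain Pseudomonas panel at desk scale: a shared
    single-copy core, per-genome unique clusters, and a group-specific block
    shared by the first three genomes only.
    """

    n_genomes: int = 6
    n_core_clusters: int = 40
    n_unique_clusters_per_genome: int = 8
    group_specific: Sequence[tuple[Sequence[int], int]] = (((0, 1, 2), 12),)
    within_cluster_bitscore: tuple[float, float] = (300.0, 15.0)
    between_cluster_bitscore: tuple[float, float] = (30.0, 10.0)
    self_score_scale: float = 1.1
    n_modules: int = 6
    module_steps: int = 4
    n_categories: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.n_core_clusters < 0 or self.n_unique_clusters_per_genome < 0:
            raise ValueError("cluster counts must be >= 0")
        if self.within_cluster_bitscore[0] <= self.between_cluster_bitscore[0]:
            raise ValueError(
                "within_cluster_bitscore mean must exceed between_cluster_bitscore mean"
            )
        if min(self.within_cluster_bitscore[1], self.between_cluster_bitscore[1]) <= 0:
            raise ValueError("bitscore sds must be > 0")
        if self.self_score_scale < 1.0:
            raise ValueError(
                "self_score_scale must be >= 1 (self-scores may not fall below "
                "pairwise scores)"
            )
        for members, count in self.group_specific:
            if count < 0:
                raise ValueError("group_specific cluster counts must be >= 0")
            if any(g < 0 or g >= self.n_genomes for g in members):
                raise ValueError("group_specific genome indices out of range")


def _genome_name(i: int) -> str:
    return f"G{i + 1}"


def generate_pangenome(
    config: PangenomeSimConfig,
) -> tuple[BitscoreTable, GenomeMap, AnnotationTable, list[KeggModule]]:
    """Draw one synthetic pangenome.

    Gene ids encode their planted cluster (``G2|CORE0005`` etc.) so ground
    truth can be recovered with :func:`planted_clusters`.  Within-cluster
    pairs score from the within distribution, all cross-cluster pairs from
    the between distribution; every self-score is ``self_score_scale`` times
    the largest score involving that gene.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genomes = [_genome_name(i) for i in range(config.n_genomes)]

    clusters: dict[str, list[str]] = {}  # cluster id -> gene ids
    gene_genome: dict[str, str] = {}

    def add_gene(cluster: str, genome: str) -> None:
        gid = f"{genome}|{cluster}"
        clusters.setdefault(cluster, []).append(gid)
        gene_genome[gid] = genome

    for c in range(config.n_core_clusters):
        for g in genomes:
            add_gene(f"CORE{c:04d}", g)
    for gi, g in enumerate(genomes):
        for c in range(config.n_unique_clusters_per_genome):
            add_gene(f"UNIQ{gi:02d}_{c:04d}", g)
    for bi, (members, count) in enumerate(config.group_specific):
        for c in range(count):
            for gi in members:
                add_gene(f"GRP{bi}_{c:04d}", genomes[gi])

    genes = sorted(gene_genome)
    cluster_of = {gid: gid.split("|", 1)[1] for gid in genes}

    w_mean, w_sd = config.within_cluster_bitscore
    b_mean, b_sd = config.between_cluster_bitscore
    scores: dict[tuple[str, str], float] = {}
    max_involving = {g: 0.0 for g in genes}
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if cluster_of[a] == cluster_of[b]:
                s = rng.normal(w_mean, w_sd)
            else:
                s = rng.normal(b_mean, b_sd)
            s = float(max(s, 1.0))
            scores[(a, b)] = s
            max_involving[a] = max(max_involving[a], s)
            max_involving[b] = max(max_involving[b], s)
    for g in genes:
        base = max(max_involving[g], float(rng.normal(w_mean, w_sd)), 1.0)
        scores[(g, g)] = config.self_score_scale * base

    bitscores = BitscoreTable(scores)
    genome_map = GenomeMap(dict(gene_genome))

    # KO annotation: one KO per core / group-specific cluster (every member
    # gene inherits it) and one per unique cluster, so per-genome KO sets
    # mirror cluster occupancy.
    ko_of_cluster: dict[str, str] = {}
    for k, cid in enumerate(sorted(clusters)):
        ko_of_cluster[cid] = f"K{k + 1:05d}"
    categories = [f"GH{i + 1}" for i in range(config.n_categories)]
    ann_rows = []
    for gid in genes:
        cid = cluster_of[gid]
        cat = ""
        if cid.startswith("CORE"):
            c_idx = int(cid[4:])
            if c_idx < config.n_categories:
                cat = categories[c_idx]
        ann_rows.append((gid, ko_of_cluster[cid], cat))
    annotations = AnnotationTable(
        pd.DataFrame(ann_rows, columns=["gene_id", "ko", "category"])
    )

    # Modules alternate between all-core steps (complete everywhere) and
    # steps drawing on group-specific clusters (complete only in the group).
    core_kos = [ko_of_cluster[f"CORE{c:04d}"] for c in range(config.n_core_clusters)]
    group_kos = [
        ko_of_cluster[cid] for cid in sorted(clusters) if cid.startswith("GRP")
    ]
    modules: list[KeggModule] = []
    pool_idx = 0
    for m in range(config.n_modules):
        steps: list[frozenset[str]] = []
        use_group = bool(m % 2) and group_kos
        for s in range(config.module_steps):
            # group modules take two group-specific steps so genomes outside
            # the group land clearly below the 0.75 completeness threshold
            if use_group and s < 2:
                steps.append(frozenset({group_kos[(m + s) % len(group_kos)]}))
            else:
                ko = core_kos[pool_idx % len(core_kos)] if core_kos else f"K9{m:02d}{s:02d}"
                alt = core_kos[(pool_idx + 1) % len(core_kos)] if len(core_kos) > 1 else ko
                steps.append(frozenset({ko, alt}))
                pool_idx += 2
        modules.append(KeggModule(f"M{m + 1:05d}", steps))

    return bitscores, genome_map, annotations, modules


def planted_clusters(genome_map: GenomeMap) -> dict[str, frozenset[str]]:
    """Recover the planted cluster partition from generated gene ids."""
    out: dict[str, set[str]] = {}
    for gid in genome_map.genes:
        out.setdefault(gid.split("|", 1)[1], set()).add(gid)
    return {cid: frozenset(members) for cid, members in out.items()}
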