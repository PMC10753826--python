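"""Pangenome comparison from precomputed protein bitscores.

The workflow mirrors the standard pangenomic recipe for a panel of bacterial
genomes: all-vs-all protein bitscores (alignment itself is upstream and out
of scope) are normalised into minbit similarities — the pairwise bitscore
divided by the smaller of the two self-alignment bitscores — weak links are
dropped at a minbit threshold (default 0.5), the surviving similarity graph
is partitioned into gene clusters with the Markov Cluster (MCL) algorithm,
and cluster presence/absence across genomes is binned into core, unique,
group-specific and accessory sets.  Metabolic potential is summarised as
KEGG-module completeness: a module is an ordered list of steps, each
satisfiable by alternative KEGG Orthologs (KOs), and a genome's completeness
is the satisfied-step fraction, called complete at >= 0.75 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BitscoreTable",
    "GenomeMap",
    "AnnotationTable",
    "KeggModule",
    "CompletenessResult",
    "GeneClusterSet",
    "ClusterBins",
    "minbit",
    "build_similarity_graph",
    "mcl_cluster",
    "presence_absence",
    "partition_clusters",
    "module_completeness",
    "estimate_metabolism",
    "count_annotation_categories",
    "read_bitscores",
    "read_genome_map",
    "read_annotations",
    "read_modules",
    "write_modules",
]


@dataclass
class BitscoreTable:
    """Pairwise protein bitscores, self-pairs included.

    ``scores[(a, b)]`` is the bitscore of aligning gene a against gene b;
    every gene appearing in any pair must carry a self-score ``(g, g)``.
    """

    scores: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        genes: set[str] = set()
        for (a, b), s in self.scores.items():
            if s < 0:
                raise ValueError(f"negative bitscore for pair ({a!r}, {b!r})")
            genes.add(a)
            genes.add(b)
        missing = [g for g in genes if (g, g) not in self.scores]
        if missing:
            raise ValueError(f"missing self-score for gene(s): {sorted(missing)[:5]}")
        self._genes = sorted(genes)

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    def self_score(self, gene: str) -> float:
        return self.scores[(gene, gene)]

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), s in self.scores.items():
            yield a, b, s

    def to_tsv(self, path: str | Path) -> None:
        rows = [(a, b, s) for (a, b), s in sorted(self.scores.items())]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "bitscore"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class GenomeMap:
    """gene id -> genome id."""

    mapping: dict[str, str]

    @property
    def genes(self) -> list[str]:
        return sorted(self.mapping)

    @property
    def genomes(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def genome_of(self, gene: str) -> str:
        return self.mapping[gene]

    def covers(self, genes: Iterable[str]) -> bool:
        return set(genes) <= set(self.mapping)

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(self.mapping.items())
        pd.DataFrame(rows, columns=["gene_id", "genome_id"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class AnnotationTable:
    """Per-gene functional annotations: KO identifier and/or category label.

    Empty strings mean "no annotation of that kind".
    """

    table: pd.DataFrame  # columns: gene_id, ko, category

    def __post_init__(self) -> None:
        for col in ("gene_id", "ko", "category"):
            if col not in self.table.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        self.table = self.table.fillna("")

    def kos_of_genes(self, genes: Iterable[str]) -> frozenset[str]:
        genes = set(genes)
        mask = self.table["gene_id"].isin(genes) & (self.table["ko"] != "")
        return frozenset(self.table.loc[mask, "ko"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class KeggModule:
    """A metabolic module: ordered steps, each a set of alternative KOs."""

    module_id: str
    steps: list[frozenset[str]]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"module {self.module_id!r} has no steps")
        if any(not step for step in self.steps):
            raise ValueError(f"module {self.module_id!r} has an empty step")
        self.steps = [frozenset(s) for s in self.steps]

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass
class CompletenessResult:
    """Completeness of one module in one genome."""

    module_id: str
    genome_id: str
    completeness: float
    complete: bool
    satisfied_steps: int
    total_steps: int


# ---------------------------------------------------------------------------
# similarity graph


def minbit(score_ab: float, score_aa: float, score_bb: float) -> float:
    """minbit similarity: pairwise bitscore over the smaller self-score."""
    if score_aa <= 0 or score_bb <= 0:
        raise ValueError("self-scores must be > 0")
    return score_ab / min(score_aa, score_bb)


def build_similarity_graph(
    bitscores: BitscoreTable, threshold: float = 0.5
) -> nx.Graph:
    """Undirected gene graph with minbit edge weights >= ``threshold``.

    When both (a, b) and (b, a) are scored, the larger bitscore is used.
    Self-pairs become nodes, never self-edges.
    """
    graph = nx.Graph()
    graph.add_nodes_from(bitscores.genes)
    best: dict[tuple[str, str], float] = {}
    for a, b, s in bitscores.pairs():
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if s > best.get(key, -1.0):
            best[key] = s
    for (a, b), s in best.items():
        mb = minbit(s, bitscores.self_score(a), bitscores.self_score(b))
        if mb >= threshold:
            graph.add_edge(a, b, weight=mb)
    return graph


# ---------------------------------------------------------------------------
# Markov clustering


@dataclass
class GeneClusterSet:
    """A partition of genes into clusters (singletons allowed)."""

    clusters: dict[str, frozenset[str]]
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {cid!r} is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"genes in multiple clusters: {sorted(overlap)[:5]}")
            seen |= set(members)
        self._genes = seen

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._genes)

    def __len__(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, str]:
        return {g: cid for cid, members in self.clusters.items() for g in members}

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (cid, g) for cid, members in sorted(self.clusters.items())
            for g in sorted(members)
        ]
        pd.DataFrame(rows, columns=["cluster_id", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> GeneClusterSet:
    """Markov clustering of a weighted similarity graph.

    The walk matrix is column-stochastic with self-loops weighted by each
    node's maximum incident edge weight (1 for isolated nodes).  Iteration
    alternates expansion (matrix power) with inflation (entrywise power and
    column renormalisation), pruning entries below ``prune``, until the
    largest entry change falls under ``tol`` or ``max_iter`` is reached
    (``converged`` is False in the latter case).  Clusters are the connected
    components of the limit matrix's non-zero support.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop
    m = m / m.sum(axis=0)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        col = m.sum(axis=0)
        col[col == 0] = 1.0  # fully pruned column: leave as absorbing zero
        m = m / col
        if np.abs(m - prev).max() < tol:
            converged = True
            break

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    support.add_edges_from(zip(rows, cols))
    clusters: dict[str, frozenset[str]] = {}
    components = sorted(
        (sorted(c) for c in nx.connected_components(support)),
        key=lambda c: (-len(c), nodes[c[0]]),
    )
    for k, comp in enumerate(components):
        clusters[f"GC{k + 1:05d}"] = frozenset(nodes[i] for i in comp)
    return GeneClusterSet(clusters, converged=converged, n_iterations=it)


# ---------------------------------------------------------------------------
# presence/absence and bins


def presence_absence(clusters: GeneClusterSet, genome_map: GenomeMap) -> pd.DataFrame:
    """cluster x genome 0/1 matrix (1 iff the cluster has a gene there)."""
    if not genome_map.covers(clusters.genes):
        missing = sorted(set(clusters.genes) - set(genome_map.mapping))
        raise ValueError(f"genome map does not cover genes: {missing[:5]}")
    genomes = genome_map.genomes
    data = np.zeros((len(clusters.clusters), len(genomes)), dtype=int)
    cids = sorted(clusters.clusters)
    gidx = {g: j for j, g in enumerate(genomes)}
    for i, cid in enumerate(cids):
        for gene in clusters.clusters[cid]:
            data[i, gidx[genome_map.genome_of(gene)]] = 1
    return pd.DataFrame(data, index=cids, columns=genomes)


@dataclass
class ClusterBins:
    """Core / unique / group-specific / accessory partition of clusters."""

    core: frozenset[str]
    unique: dict[str, frozenset[str]]  # genome -> its unique clusters
    group_core: frozenset[str] | None
    accessory: frozenset[str]

    @property
    def n_unique_total(self) -> int:
        return sum(len(v) for v in self.unique.values())


def partition_clusters(
    clusters: GeneClusterSet,
    genome_map: GenomeMap,
    group: Sequence[str] | None = None,
) -> ClusterBins:
    """Bin clusters by genome occupancy.

    ``core`` clusters occur in every genome; each genome's ``unique`` bin
    holds clusters found only there; with ``group`` given, ``group_core``
    holds clusters present in every group member and absent from all other
    genomes; everything else is ``accessory``.
    """
    pa = presence_absence(clusters, genome_map)
    genomes = list(pa.columns)
    if group is not None:
        unknown = set(group) - set(genomes)
        if unknown:
            raise ValueError(f"group contains unknown genomes: {sorted(unknown)}")
        group = sorted(set(group))
    core: set[str] = set()
    unique: dict[str, set[str]] = {g: set() for g in genomes}
    group_core: set[str] = set()
    accessory: set[str] = set()
    arr = pa.to_numpy(dtype=bool)
    for i, cid in enumerate(pa.index):
        present = [g for g, p in zip(genomes, arr[i]) if p]
        if len(present) == len(genomes):
            core.add(cid)
        elif len(present) == 1:
            unique[present[0]].add(cid)
        elif group is not None and present == group and len(group) < len(genomes):
            group_core.add(cid)
        else:
            accessory.add(cid)
    return ClusterBins(
        core=frozenset(core),
        unique={g: frozenset(s) for g, s in unique.items()},
        group_core=frozenset(group_core) if group is not None else None,
        accessory=frozenset(accessory),
    )


# ---------------------------------------------------------------------------
# KEGG-module completeness and annotation tallies


def module_completeness(
    module: KeggModule,
    kos_present: Iterable[str],
    threshold: float = 0.75,
    genome_id: str = "",
) -> CompletenessResult:
    """Satisfied-step fraction of a module given a genome's KO set.

    A step is satisfied when any of its alternative KOs is present; the
    module is complete when the fraction reaches ``threshold``.
    """
    kos = set(kos_present)
    satisfied = sum(1 for step in module.steps if step & kos)
    completeness = satisfied / module.n_steps
    return CompletenessResult(
        module_id=module.module_id,
        genome_id=genome_id,
        completeness=completeness,
        complete=completeness >= threshold,
        satisfied_steps=satisfied,
        total_steps=module.n_steps,
    )


def estimate_metabolism(
    modules: Sequence[KeggModule],
    annotations: AnnotationTable,
    genome_map: GenomeMap,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Completeness of every module in every genome (long format)."""
    genes_by_genome: dict[str, list[str]] = {g: [] for g in genome_map.genomes}
    for gene, genome in genome_map.mapping.items():
        genes_by_genome[genome].append(gene)
    rows = []
    for genome, genes in sorted(genes_by_genome.items()):
        kos = annotations.kos_of_genes(genes)
        for module in modules:
            r = module_completeness(module, kos, threshold, genome_id=genome)
            rows.append(
                (r.module_id, r.genome_id, r.completeness, r.complete,
                 r.satisfied_steps, r.total_steps)
            )
    return pd.DataFrame(
        rows,
        columns=["module_id", "genome_id", "completeness", "complete",
                 "satisfied_steps", "total_steps"],
    )


def count_annotation_categories(
    annotations: AnnotationTable, genome_map: GenomeMap
) -> pd.DataFrame:
    """Per-genome hit counts for each category label, plus a total column."""
    tab = annotations.table
    tab = tab[tab["category"] != ""]
    genomes = genome_map.genomes
    categories = sorted(set(tab["category"]))
    counts = pd.DataFrame(0, index=genomes, columns=categories, dtype=int)
    for _, row in tab.iterrows():
        gene = row["gene_id"]
        if gene in genome_map.mapping:
            counts.at[genome_map.genome_of(gene), row["category"]] += 1
    counts["total"] = counts.sum(axis=1)
    return counts


# ---------------------------------------------------------------------------
# file io


def read_bitscores(path: str | Path) -> BitscoreTable:
    """Read a (gene_a, gene_b, bitscore) TSV, self-pairs included."""
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: expected columns gene_a, gene_b, bitscore")
    scores = {
        (a, b): float(s)
        for a, b, s in zip(raw.iloc[:, 0], raw.iloc[:, 1], raw.iloc[:, 2])
    }
    return BitscoreTable(scores)


def read_genome_map(path: str | Path) -> GenomeMap:
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id, genome_id")
    return GenomeMap(dict(zip(raw.iloc[:, 0], raw.iloc[:, 1])))


def read_annotations(path: str | Path) -> AnnotationTable:
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return AnnotationTable(raw)


def read_modules(path: str | Path) -> list[KeggModule]:
    """Read module definitions: ``MODULE_ID<TAB>k1,k2;k3;...`` per line."""
    modules = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            module_id, spec = line.split("\t", 1)
        except ValueError:
            raise ValueError(f"malformed module line: {line!r}") from None
        steps = [
            frozenset(k.strip() for k in step.split(",") if k.strip())
            for step in spec.split(";")
            if step.strip()
        ]
        modules.append(KeggModule(module_id, steps))
    return modules


def write_modules(modules: Sequence[KeggModule], path: str | Path) -> None:
    lines = [
        m.module_id + "\t" + ";".join(",".join(sorted(step)) for step in m.steps)
        for m in modules
    ]
    Path(path).write_text("\n".join(lines) + "\n")
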