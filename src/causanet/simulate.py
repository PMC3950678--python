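"""Synthetic genetical-genomics data with known causal structure.

The generator emulates the structure of a two-condition tumor cohort:
two phenotype groups, SNP genotypes with linkage blocks, and expression
produced by a linear-Gaussian structural equation model (SEM) over a
known gene DAG with eQTL perturbations.  Group-dependent features come
in two flavours: per-gene mean shifts between the phenotype groups
(differential expression, which drives the Hotelling gate of module
discovery) and condition-gated edges whose coefficient is active in one
group only (coexpression rewiring, which drives the r2 part of the
bonding score).

The default scenario builds six regulatory chains of five genes, each on
its own chromosome, each rooted in one cis-eQTL inside a small linkage
block, surrounded by decoy SNP blocks, bystander noise genes and decoy
interactome edges.  Gene labels are shuffled against chain positions so
that lexicographic identifiers carry no ordering information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    GlobalNetwork,
    Interactome,
    PhenotypeLabels,
)

__all__ = [
    "TruthModel",
    "Scenario",
    "ConcordanceResult",
    "simulate_genotypes",
    "simulate_expression",
    "make_interactome",
    "evaluate_concordance",
    "default_scenario",
    "write_scenario",
]


@dataclass
class TruthModel:
    """Ground-truth generative model for one synthetic scenario."""

    genes: list[str]
    dag_edges: list[tuple[str, str, float]]  # (parent, child, effect b)
    eqtl_map: list[tuple[str, str, float]]  # (snp, target gene, effect a)
    condition_edges: set[tuple[str, str]] = field(default_factory=set)
    noise_sd: float = 0.5
    maf: float = 0.3
    ld_blocks: list[list[str]] = field(default_factory=list)  # first member = anchor
    ld_flip: float = 0.05
    snp_positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    gene_spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    group_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for u, v, b in self.dag_edges:
            if b == 0:
                raise ValueError(f"zero effect size on edge {u}->{v}")
            g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("truth DAG contains a cycle")
        skeleton = {(u, v) for u, v, _ in self.dag_edges}
        if not self.condition_edges <= skeleton:
            raise ValueError("condition_edges must be a subset of the DAG edges")
        self._graph = g

    @property
    def snps(self) -> list[str]:
        return [s for block in self.ld_blocks for s in block]

    def directed_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, _ in self.dag_edges]

    def topological_genes(self) -> list[str]:
        return list(nx.topological_sort(self._graph))


def simulate_genotypes(truth: TruthModel, n_samples: int, seed: int = 0) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes with copy-based linkage blocks.

    Block anchors are Binomial(2, maf); other block members copy the anchor
    and are independently redrawn with probability ``ld_flip`` per sample.
    """
    if not (0 < truth.maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for block in truth.ld_blocks:
        anchor = rng.binomial(2, truth.maf, size=n_samples)
        for k, snp in enumerate(block):
            if k == 0:
                dos = anchor
            else:
                redraw = rng.random(n_samples) < truth.ld_flip
                dos = np.where(redraw, rng.binomial(2, truth.maf, size=n_samples), anchor)
            snp_ids.append(snp)
            rows.append(dos)
    positions = pd.DataFrame(
        [
            (s, truth.snp_positions[s][0], truth.snp_positions[s][1])
            for s in snp_ids
        ],
        columns=["snp", "chromosome", "position"],
    ).set_index("snp")
    return GenotypeMatrix(snp_ids, sample_ids, np.vstack(rows), positions)


def simulate_expression(
    truth: TruthModel,
    geno: GenotypeMatrix,
    labels: PhenotypeLabels,
    seed: int = 0,
) -> ExpressionMatrix:
    """Linear-Gaussian SEM over the truth DAG with eQTL and group effects.

    In topological order,
    x_g = shift_g * 1[group 1] + sum_parents b * x_parent * 1[edge active]
        + sum_eqtls a * dosage + Normal(0, noise_sd^2),
    where condition-gated edges are active only in phenotype group 1.
    """
    rng = np.random.default_rng(seed)
    n = len(geno.sample_ids)
    if labels.sample_ids != geno.sample_ids:
        raise ValueError("genotype and label samples not aligned")
    in_group1, _ = labels.group_masks()
    eqtls_of: dict[str, list[tuple[str, float]]] = {}
    for snp, gene, a in truth.eqtl_map:
        eqtls_of.setdefault(gene, []).append((snp, a))
    parents_of: dict[str, list[tuple[str, float]]] = {}
    for u, v, b in truth.dag_edges:
        parents_of.setdefault(v, []).append((u, b))
    values: dict[str, np.ndarray] = {}
    for gene in truth.topological_genes():
        x = rng.normal(0.0, truth.noise_sd, size=n)
        x += truth.group_shift.get(gene, 0.0) * in_group1
        for parent, b in parents_of.get(gene, ()):
            gate = in_group1 if (parent, gene) in truth.condition_edges else 1.0
            x = x + b * values[parent] * gate
        for snp, a in eqtls_of.get(gene, ()):
            x = x + a * geno.dosages[geno.snp_index(snp)]
        values[gene] = x
    mat = np.vstack([values[g] for g in truth.genes])
    return ExpressionMatrix(list(truth.genes), list(geno.sample_ids), mat)


def make_interactome(truth: TruthModel, n_decoy_edges: int, seed: int = 0) -> Interactome:
    """Undirected truth skeleton plus random non-truth decoy pairs."""
    rng = np.random.default_rng(seed)
    skeleton = {frozenset((u, v)) for u, v, _ in truth.dag_edges}
    genes = list(truth.genes)
    n_pairs = len(genes) * (len(genes) - 1) // 2
    if n_decoy_edges > n_pairs - len(skeleton):
        raise ValueError("requested more decoys than available gene pairs")
    decoys: set[frozenset[str]] = set()
    while len(decoys) < n_decoy_edges:
        a, b = rng.choice(len(genes), size=2, replace=False)
        pair = frozenset((genes[a], genes[b]))
        if pair not in skeleton and pair not in decoys:
            decoys.add(pair)
    return Interactome(frozenset(skeleton | decoys))


@dataclass
class ConcordanceResult:
    concordant: int
    inverted: int
    rate: float | None  # None when no inferred edge overlaps the reference

    @property
    def overlap(self) -> int:
        return self.concordant + self.inverted


def evaluate_concordance(
    inferred: list[tuple[str, str]] | GlobalNetwork,
    reference: list[tuple[str, str]],
) -> ConcordanceResult:
    """Directional agreement of inferred edges with a reference network.

    Only inferred edges whose unordered pair appears in the reference count;
    ``rate`` = concordant / overlap.  Edges present in just one of the two
    networks are ignored on both sides.
    """
    if isinstance(inferred, GlobalNetwork):
        inferred = [(s, t) for s, t, *_ in inferred.edges]
    ref_directed = set(reference)
    ref_pairs = {frozenset(e) for e in reference}
    concordant = inverted = 0
    for s, t in inferred:
        if frozenset((s, t)) not in ref_pairs:
            continue
        if (s, t) in ref_directed:
            concordant += 1
        else:
            inverted += 1
    overlap = concordant + inverted
    rate = concordant / overlap if overlap else None
    return ConcordanceResult(concordant, inverted, rate)


@dataclass
class Scenario:
    """A complete synthetic input set plus its generating truth."""

    truth: TruthModel
    expr: ExpressionMatrix
    geno: GenotypeMatrix
    labels: PhenotypeLabels
    annotation: GeneAnnotation
    interactome: Interactome

    @property
    def reference_edges(self) -> list[tuple[str, str]]:
        return self.truth.directed_edges()


def default_scenario(
    seed: int = 0,
    n_modules: int = 6,
    genes_per_module: int = 5,
    n_samples: int = 200,
    eqtl_effect: float = 1.0,
    edge_effect: float = 0.8,
    noise_sd: float = 0.5,
    group_shift: float = 0.6,
    n_bystanders: int = 70,
    n_decoy_edges: int = 500,
    maf: float = 0.3,
    ld_block_size: int = 3,
    ld_flip: float = 0.05,
    n_decoy_blocks: int = 3,
    n_condition_edges: int = 0,
) -> Scenario:
    """Build the study's standard synthetic scenario.

    ``n_modules`` regulatory chains of ``genes_per_module`` genes, one
    cis-eQTL per chain acting on its first gene, chain coefficients
    ``edge_effect``, eQTL effect ``eqtl_effect``, residual scale
    ``noise_sd``, and a per-gene phenotype mean shift ``group_shift`` on
    the chain genes that makes the chains discriminative.
    """
    rng = np.random.default_rng(seed)
    n_module_genes = n_modules * genes_per_module
    total = n_module_genes + n_bystanders
    names = [f"G{i:03d}" for i in range(total)]
    shuffled = list(rng.permutation(names))
    chains = [
        shuffled[m * genes_per_module : (m + 1) * genes_per_module]
        for m in range(n_modules)
    ]
    bystanders = shuffled[n_module_genes:]

    dag_edges: list[tuple[str, str, float]] = []
    eqtl_map: list[tuple[str, str, float]] = []
    ld_blocks: list[list[str]] = []
    snp_positions: dict[str, tuple[str, int]] = {}
    gene_spans: dict[str, tuple[str, int, int]] = {}
    shifts: dict[str, float] = {}
    offsets = [k * 50_000 for k in range(ld_block_size)]
    for m, chain in enumerate(chains):
        chrom = f"chr{m + 1}"
        for k in range(len(chain) - 1):
            dag_edges.append((chain[k], chain[k + 1], edge_effect))
        for k, gene in enumerate(chain):
            start = 10_200_000 + k * 350_000
            gene_spans[gene] = (chrom, start, start + 10_000)
            shifts[gene] = group_shift
        # causal linkage block near the chain head, then decoy blocks
        block_starts = [10_000_000] + [
            11_000_000 + d * 700_000 for d in range(n_decoy_blocks)
        ]
        for b, bstart in enumerate(block_starts):
            tag = "c" if b == 0 else f"d{b}"
            block = [f"rs{m + 1}_{tag}{k}" for k in range(ld_block_size)]
            for snp, off in zip(block, offsets):
                snp_positions[snp] = (chrom, bstart + off)
            ld_blocks.append(block)
        eqtl_map.append((f"rs{m + 1}_c0", chain[0], eqtl_effect))
    for i, gene in enumerate(bystanders):
        gene_spans[gene] = ("chr0", 1_000_000 * (i + 1), 1_000_000 * (i + 1) + 10_000)

    condition_edges: set[tuple[str, str]] = set()
    if n_condition_edges:
        all_edges = [(u, v) for u, v, _ in dag_edges]
        pick = rng.choice(len(all_edges), size=min(n_condition_edges, len(all_edges)), replace=False)
        condition_edges = {all_edges[i] for i in pick}

    truth = TruthModel(
        genes=sorted(names),
        dag_edges=dag_edges,
        eqtl_map=eqtl_map,
        condition_edges=condition_edges,
        noise_sd=noise_sd,
        maf=maf,
        ld_blocks=ld_blocks,
        ld_flip=ld_flip,
        snp_positions=snp_positions,
        gene_spans=gene_spans,
        group_shift=shifts,
    )
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    geno = simulate_genotypes(truth, n_samples, int(seeds[0]))
    half = n_samples // 2
    labels = PhenotypeLabels(
        list(geno.sample_ids), ["A"] * half + ["B"] * (n_samples - half)
    )
    expr = simulate_expression(truth, geno, labels, int(seeds[1]))
    interactome = make_interactome(truth, n_decoy_edges, int(seeds[2]))
    annotation = GeneAnnotation(
        pd.DataFrame(
            [(g, *truth.gene_spans[g]) for g in truth.genes],
            columns=["gene", "chromosome", "start", "end"],
        ).set_index("gene")
    )
    return Scenario(truth, expr, geno, labels, annotation, interactome)


def write_scenario(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Write all standard input files plus the truth files; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "genotypes": out / "genotypes.tsv",
        "snp_annotation": out / "snp_annotation.tsv",
        "gene_annotation": out / "gene_annotation.tsv",
        "labels": out / "labels.tsv",
        "interactome": out / "interactome.tsv",
        "truth_dag": out / "truth_dag.tsv",
        "truth_eqtls": out / "truth_eqtls.tsv",
    }
    scenario.expr.to_frame().to_csv(paths["expression"], sep="\t", index_label="gene")
    pd.DataFrame(
        scenario.geno.dosages,
        index=scenario.geno.snp_ids,
        columns=scenario.geno.sample_ids,
    ).to_csv(paths["genotypes"], sep="\t", index_label="snp")
    scenario.geno.positions.loc[scenario.geno.snp_ids].to_csv(
        paths["snp_annotation"], sep="\t", index_label="snp"
    )
    scenario.annotation.table.to_csv(paths["gene_annotation"], sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": scenario.labels.sample_ids, "label": scenario.labels.labels}
    ).to_csv(paths["labels"], sep="\t", index=False)
    with open(paths["interactome"], "w") as fh:
        for a, b in scenario.interactome.edge_list():
            fh.write(f"{a}\t{b}\n")
    pd.DataFrame(scenario.truth.dag_edges, columns=["parent", "child", "effect"]).to_csv(
        paths["truth_dag"], sep="\t", index=False
    )
    pd.DataFrame(scenario.truth.eqtl_map, columns=["snp", "gene", "effect"]).to_csv(
        paths["truth_eqtls"], sep="\t", index=False
    )
    return paths
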