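"""End-to-end orchestration of the four reconstruction steps.

``run_steps`` is the functional core: it takes aligned in-memory inputs
and returns every intermediate artifact (modules, per-module eQTLs,
causation matrix, ranks, rank-assembled network, major-direction
baseline).  ``run_pipeline`` wraps it with file I/O: it reads the inputs
named in a :class:`PipelineConfig`, writes each stage's artifact under
``out_dir`` and records a manifest (parameters, seed, stage counts,
runtimes).  Reruns with an identical config and seed reproduce identical
outputs, independent of the number of parallel jobs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayesnet, data_io, discovery, eqtl, ranking

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_steps", "run_pipeline"]


@dataclass
class PipelineConfig:
    # input paths
    expression: str = ""
    genotypes: str = ""
    snp_annotation: str = ""
    gene_annotation: str = ""
    labels: str = ""
    interactome: str = ""
    out_dir: str = "causanet_out"
    # step 1
    r_cut: float = 0.90
    alpha: float = 0.05
    size_cap: int = 10
    # step 2
    window: int = 1_000_000
    block_cut: int = 500_000
    eta_grid: tuple[float, ...] = eqtl.EqtlParams.eta_grid
    K_grid: tuple[int, ...] = eqtl.EqtlParams.K_grid
    folds: int = 5
    # step 3
    restarts: int = 5
    max_parents: int = 4
    use_eqtls: bool = True
    # step 4
    K: int = 100
    anneal_t0: float = 1.0
    anneal_alpha: float = 0.995
    anneal_iters: int = 20_000
    anneal_patience: int = 2_000
    # execution
    seed: int = 0
    jobs: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("eta_grid", "K_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eta_grid"] = list(self.eta_grid)
        d["K_grid"] = list(self.K_grid)
        return d


@dataclass
class PipelineResult:
    modules: list[discovery.Module]
    module_eqtls: list[eqtl.ModuleEqtls] = field(default_factory=list)
    causation: bayesnet.CausationMatrix | None = None
    ranks: ranking.RankCoordinates | None = None
    network: data_io.GlobalNetwork | None = None
    major_network: list[tuple[str, str, int, int]] = field(default_factory=list)
    message: str = "ok"
    timings: dict[str, float] = field(default_factory=dict)


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_steps(
    expr: data_io.ExpressionMatrix,
    geno: data_io.GenotypeMatrix,
    labels: data_io.PhenotypeLabels,
    annotation: data_io.GeneAnnotation,
    interactome: data_io.Interactome,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run modules -> eQTLs -> subnetworks -> rank assembly on aligned data."""
    config = config or PipelineConfig()
    expr, geno, labels = data_io.align_samples(expr, geno, labels)
    seeds = _stage_seeds(config.seed, 3)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    mods = discovery.discover_modules(
        expr,
        labels,
        interactome,
        discovery.ModuleParams(config.r_cut, config.alpha, config.size_cap),
    )
    timings["modules"] = time.perf_counter() - t0
    logger.info("step 1: %d modules", len(mods))
    if len(mods) < 2:
        return PipelineResult(
            modules=mods,
            message=(
                f"only {len(mods)} discriminative module(s) found; at least two "
                "are needed for pairwise subnetwork inference — stopping after step 1"
            ),
            timings=timings,
        )

    t0 = time.perf_counter()
    eq_params = eqtl.EqtlParams(
        window=config.window,
        block_cut=config.block_cut,
        eta_grid=config.eta_grid,
        K_grid=config.K_grid,
        folds=config.folds,
    )
    module_eqtls = []
    if config.use_eqtls:
        for i, mod in enumerate(mods):
            module_eqtls.append(
                eqtl.map_module_eqtls(
                    mod, geno, expr, annotation, eq_params,
                    seed=seeds[0] + i, module_id=f"M{i + 1}",
                )
            )
    else:
        module_eqtls = [eqtl.ModuleEqtls(f"M{i + 1}", [], [], []) for i in range(len(mods))]
    timings["eqtls"] = time.perf_counter() - t0
    logger.info(
        "step 2: %d eQTL representatives", sum(len(e.eqtls) for e in module_eqtls)
    )

    t0 = time.perf_counter()
    C = bayesnet.accumulate_causation(
        mods,
        module_eqtls,
        expr,
        geno,
        bayesnet.SearchConfig(restarts=config.restarts, max_parents=config.max_parents),
        seed=seeds[1],
        jobs=config.jobs,
        use_eqtls=config.use_eqtls,
        labels=labels,
    )
    timings["subnets"] = time.perf_counter() - t0
    logger.info("step 3: causation matrix with %d total counts", int(C.counts.sum()))

    t0 = time.perf_counter()
    schedule = ranking.AnnealSchedule(
        config.anneal_t0, config.anneal_alpha, config.anneal_iters, config.anneal_patience
    )
    ranks = ranking.estimate_ranks(C, K=config.K, seed=seeds[2], schedule=schedule)
    net = ranking.assemble_global_network(C, ranks)
    major = bayesnet.major_direction_network(C)
    timings["assemble"] = time.perf_counter() - t0
    logger.info("step 4: %d oriented edges (major baseline: %d)", len(net.edges), len(major))
    return PipelineResult(mods, module_eqtls, C, ranks, net, major, "ok", timings)


def _write_modules(mods: list[discovery.Module], path: Path) -> None:
    rows = [
        {
            "module_id": f"M{i + 1}",
            "seed": m.seed,
            "members": ",".join(m.members),
            "t2": m.t2,
            "pvalue": m.pvalue,
        }
        for i, m in enumerate(mods)
    ]
    pd.DataFrame(rows, columns=["module_id", "seed", "members", "t2", "pvalue"]).to_csv(
        path, sep="\t", index=False
    )


def _write_eqtls(eqs: list[eqtl.ModuleEqtls], geno: data_io.GenotypeMatrix, path: Path) -> None:
    rows = []
    for e in eqs:
        for b_id, block in enumerate(e.blocks):
            chrom, pos = geno.position_of(block.representative)
            rows.append(
                {
                    "module_id": e.module_id,
                    "snp_id": block.representative,
                    "chromosome": chrom,
                    "position": pos,
                    "block_id": f"{e.module_id}_B{b_id + 1}",
                    "wilks_p": block.wilks_p,
                }
            )
    pd.DataFrame(
        rows, columns=["module_id", "snp_id", "chromosome", "position", "block_id", "wilks_p"]
    ).to_csv(path, sep="\t", index=False)


def _write_ranks(ranks: ranking.RankCoordinates, path: Path) -> None:
    pd.DataFrame(
        {
            "gene": ranks.genes,
            "mean_rank": ranks.mean_rank,
            "sd_rank": ranks.sd_rank,
            "final_order": [ranks.final_order[g] for g in ranks.genes],
        }
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read inputs, run all four steps, write artifacts and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    expr = data_io.read_expression_matrix(config.expression)
    geno = data_io.read_genotype_matrix(config.genotypes, config.snp_annotation)
    labels = data_io.read_phenotype_labels(config.labels)
    annotation = data_io.read_gene_annotation(config.gene_annotation)
    interactome = data_io.read_interactome(config.interactome)

    result = run_steps(expr, geno, labels, annotation, interactome, config)

    _write_modules(result.modules, out / "modules.tsv")
    if result.causation is not None:
        _write_eqtls(result.module_eqtls, geno, out / "eqtls.tsv")
        pd.DataFrame(
            result.causation.counts,
            index=result.causation.genes,
            columns=result.causation.genes,
        ).to_csv(out / "causation.tsv", sep="\t", index_label="gene")
        _write_ranks(result.ranks, out / "ranks.tsv")
        data_io.write_network(result.network, out / "network.tsv")
        data_io.write_network(
            data_io.GlobalNetwork(result.major_network), out / "major_network.tsv"
        )
    manifest = {
        "seed": config.seed,
        "jobs": config.jobs,
        "parameters": config.to_dict(),
        "n_modules": len(result.modules),
        "n_eqtls": sum(len(e.eqtls) for e in result.module_eqtls),
        "n_edges": len(result.network.edges) if result.network else 0,
        "message": result.message,
        "runtimes_s": {k: round(v, 3) for k, v in result.timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if result.message != "ok":
        logger.warning(result.message)
    return result
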