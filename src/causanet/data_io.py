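"""Typed containers and file I/O for genetical-genomics inputs.

All downstream stages operate on the containers defined here:
expression (genes x samples), genotype dosages (SNPs x samples, coded
0/1/2), a binary phenotype, gene annotation, and an undirected
molecular-interaction network.  Files are plain tab-delimited text;
genotypes may alternatively come from a VCF (GT field -> allele count).

Sample order is canonicalized to the expression-file order by
:func:`align_samples`; every later stage assumes aligned inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "Interactome",
    "PhenotypeLabels",
    "GeneAnnotation",
    "GlobalNetwork",
    "LoadError",
    "read_expression_matrix",
    "read_genotype_matrix",
    "read_phenotype_labels",
    "read_interactome",
    "read_gene_annotation",
    "align_samples",
    "write_network",
    "read_network",
]


class LoadError(ValueError):
    """Raised when an input file violates a format or content invariant."""


@dataclass
class ExpressionMatrix:
    """Gene expression values, genes x samples, assumed normalized/log scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if np.isnan(self.values).any():
            raise ValueError("expression contains missing values")
        if len(self.sample_ids) < 4:
            raise ValueError("need at least 4 samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def subset_genes(self, genes: Sequence[str]) -> np.ndarray:
        """Rows for ``genes`` in the given order, shape (len(genes), n_samples)."""
        idx = [self.gene_ids.index(g) for g in genes]
        return self.values[idx, :]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GenotypeMatrix:
    """SNP dosages (0/1/2) with genomic positions."""

    snp_ids: list[str]
    sample_ids: list[str]
    dosages: np.ndarray  # shape (n_snps, n_samples), int
    positions: pd.DataFrame  # index snp_id, columns: chromosome (str), position (int)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage shape does not match id lists")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage out of range for SNP {self.snp_ids[i]}, sample {self.sample_ids[j]}"
            )
        missing_pos = [s for s in self.snp_ids if s not in self.positions.index]
        if missing_pos:
            raise ValueError(f"SNPs without positions: {missing_pos[:5]}")
        if (self.positions.loc[self.snp_ids, "position"] < 0).any():
            raise ValueError("negative SNP position")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp: str) -> int:
        return self.snp_ids.index(snp)

    def subset_snps(self, snps: Sequence[str]) -> np.ndarray:
        idx = [self.snp_ids.index(s) for s in snps]
        return self.dosages[idx, :]

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return GenotypeMatrix(
            list(self.snp_ids), list(samples), self.dosages[:, idx], self.positions
        )

    def position_of(self, snp: str) -> tuple[str, int]:
        row = self.positions.loc[snp]
        return str(row["chromosome"]), int(row["position"])


@dataclass
class Interactome:
    """Undirected molecular-interaction network as a set of unordered pairs."""

    edges: frozenset[frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Interactome":
        edges = set()
        for a, b in pairs:
            if a == b:
                continue  # self-loops carry no bonding information
            edges.add(frozenset((a, b)))
        return cls(frozenset(edges))

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def neighbors(self, gene: str) -> set[str]:
        return {next(iter(e - {gene})) for e in self.edges if gene in e}

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as sorted tuples, deterministically ordered."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self.edges

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class PhenotypeLabels:
    """Binary group indicator per sample (e.g. metastatic vs non-metastatic)."""

    sample_ids: list[str]
    labels: list

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("labels length mismatch")
        groups = sorted(set(map(str, self.labels)))
        if len(groups) != 2:
            raise ValueError(f"need exactly two phenotype groups, got {groups}")
        self.labels = [str(l) for l in self.labels]
        for g in groups:
            if self.labels.count(g) < 3:
                raise ValueError(f"group {g!r} has fewer than 3 samples")

    @property
    def groups(self) -> tuple[str, str]:
        a, b = sorted(set(self.labels))
        return a, b

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.labels)
        a, b = self.groups
        return arr == a, arr == b

    def subset_samples(self, samples: Sequence[str]) -> "PhenotypeLabels":
        lookup = dict(zip(self.sample_ids, self.labels))
        return PhenotypeLabels(list(samples), [lookup[s] for s in samples])


@dataclass
class GeneAnnotation:
    """Genomic spans per gene: gene_id -> (chromosome, start, end)."""

    table: pd.DataFrame  # index gene_id, columns: chromosome, start, end

    def __post_init__(self) -> None:
        bad = self.table["start"] > self.table["end"]
        if bad.any():
            raise ValueError(f"start > end for genes {list(self.table.index[bad])[:5]}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def span(self, gene: str) -> tuple[str, int, int]:
        row = self.table.loc[gene]
        return str(row["chromosome"]), int(row["start"]), int(row["end"])


@dataclass
class GlobalNetwork:
    """Oriented gene-gene edges with causation counts and rank coordinates.

    ``edges`` rows are (source, target, c_source_target, c_target_source);
    ``ranks`` maps gene -> final integer rank (1 = most upstream).
    """

    edges: list[tuple[str, str, int, int]]
    ranks: dict[str, int] = field(default_factory=dict)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _, _ in self.edges}


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.size == 0:
        raise LoadError(f"{path}: no sample columns in header")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise LoadError(f"{path}: duplicated gene id {dup[0]!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            # locate the offending cell for the error message
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[conv.isna()]
            raise LoadError(
                f"{path}: non-numeric or empty cell at gene {bad[0]!r}, sample {col!r}"
            ) from None
        if np.isnan(values[:, j]).any():
            bad_gene = df.index[np.isnan(values[:, j])][0]
            raise LoadError(f"{path}: empty cell at gene {bad_gene!r}, sample {col!r}")
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def _read_genotype_tsv(path: str | Path, impute: bool) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    snp_ids = list(df.index.astype(str))
    sample_ids = list(df.columns.astype(str))
    raw = df.to_numpy(dtype=float)
    missing = np.isnan(raw)
    valid = np.isin(raw, (0.0, 1.0, 2.0)) | missing
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise LoadError(
            f"{path}: dosage {raw[i, j]!r} outside {{0,1,2,missing}} "
            f"for SNP {snp_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    if missing.any():
        if not impute:
            i, j = np.argwhere(missing)[0]
            raise LoadError(
                f"{path}: missing dosage for SNP {snp_ids[i]!r}, sample "
                f"{sample_ids[j]!r} (imputation disabled)"
            )
        for i in range(raw.shape[0]):
            row_missing = missing[i]
            if row_missing.any():
                if row_missing.all():
                    raise LoadError(f"{path}: SNP {snp_ids[i]!r} entirely missing")
                fill = float(np.round(raw[i, ~row_missing].mean()))
                raw[i, row_missing] = min(2.0, max(0.0, fill))
    return snp_ids, sample_ids, raw.astype(int)


def _read_genotype_vcf(path: str | Path) -> tuple[list[str], list[str], np.ndarray, pd.DataFrame]:
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    pos_rows: list[tuple[str, str, int]] = []
    for rec in vcf:
        sid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types)
        dos = np.where(gt == 3, 2, np.where(gt == 1, 1, np.where(gt == 0, 0, -1)))
        if (dos == -1).any():
            known = dos[dos != -1]
            fill = int(np.clip(np.round(known.mean()), 0, 2)) if known.size else 0
            dos = np.where(dos == -1, fill, dos)
        snp_ids.append(sid)
        rows.append(dos)
        pos_rows.append((sid, str(rec.CHROM), int(rec.POS)))
    positions = pd.DataFrame(pos_rows, columns=["snp", "chromosome", "position"]).set_index("snp")
    return snp_ids, sample_ids, np.vstack(rows), positions


def read_genotype_matrix(
    path: str | Path, annotation_path: str | Path | None = None, impute: bool = True
) -> GenotypeMatrix:
    """Read SNP dosages from TSV (with an annotation TSV) or a VCF.

    The annotation TSV has columns (snp, chromosome, position).  Missing
    dosages are replaced by the per-SNP rounded mean when ``impute`` is on.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or str(path).endswith(".vcf.gz"):
        snp_ids, sample_ids, dosages, positions = _read_genotype_vcf(path)
    else:
        if annotation_path is None:
            raise LoadError("annotation_path required for TSV genotype input")
        snp_ids, sample_ids, dosages = _read_genotype_tsv(path, impute)
        ann = pd.read_csv(annotation_path, sep="\t", dtype={0: str, 1: str, 2: int})
        ann.columns = ["snp", "chromosome", "position"]
        positions = ann.set_index("snp")
        missing = [s for s in snp_ids if s not in positions.index]
        if missing:
            raise LoadError(f"SNPs without annotation: {missing[:5]}")
    return GenotypeMatrix(snp_ids, sample_ids, dosages, positions)


def read_phenotype_labels(path: str | Path) -> PhenotypeLabels:
    """Read a two-column TSV (sample_id, label) with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise LoadError(f"{path}: need two columns (sample, label)")
    return PhenotypeLabels(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def read_interactome(path: str | Path) -> Interactome:
    """Read a 2-column TSV edge list or a SIF file ("A interacts B")."""
    pairs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2:
                pairs.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                # SIF: source relation target [target...]
                for tgt in parts[2:]:
                    pairs.append((parts[0], tgt))
            else:
                raise LoadError(f"{path}:{line_no}: cannot parse interaction line")
    return Interactome.from_pairs(pairs)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a TSV with columns (gene, chromosome, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["gene", "chromosome", "start", "end"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return GeneAnnotation(df.set_index("gene"))


def align_samples(
    expr: ExpressionMatrix, geno: GenotypeMatrix, labels: PhenotypeLabels
) -> tuple[ExpressionMatrix, GenotypeMatrix, PhenotypeLabels]:
    """Restrict all three inputs to their common samples, in expression order.

    Idempotent; raises if fewer than 4 samples remain.
    """
    common = set(expr.sample_ids) & set(geno.sample_ids) & set(labels.sample_ids)
    ordered = [s for s in expr.sample_ids if s in common]
    if len(ordered) < 4:
        raise ValueError(f"only {len(ordered)} samples shared across inputs")
    dropped = (
        (set(expr.sample_ids) | set(geno.sample_ids) | set(labels.sample_ids)) - common
    )
    if dropped:
        logger.warning("align_samples dropped samples: %s", sorted(dropped))
    if ordered == expr.sample_ids == geno.sample_ids == labels.sample_ids:
        return expr, geno, labels
    return (
        expr.subset_samples(ordered),
        geno.subset_samples(ordered),
        labels.subset_samples(ordered),
    )


def write_network(net: GlobalNetwork, path: str | Path) -> None:
    """Write the oriented network as TSV plus a SIF companion file."""
    path = Path(path)
    rows = []
    for s, t, cst, cts in net.edges:
        rows.append(
            {
                "source": s,
                "target": t,
                "c_source_target": cst,
                "c_target_source": cts,
                "rank_source": net.ranks.get(s, ""),
                "rank_target": net.ranks.get(t, ""),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "source",
            "target",
            "c_source_target",
            "c_target_source",
            "rank_source",
            "rank_target",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    with open(str(path) + ".sif", "w") as fh:
        for s, t, _, _ in net.edges:
            fh.write(f"{s}\tregulates\t{t}\n")


def read_network(path: str | Path) -> GlobalNetwork:
    """Re-read a network written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    edges = [
        (r.source, r.target, int(r.c_source_target), int(r.c_target_source))
        for r in df.itertuples()
    ]
    ranks: dict[str, int] = {}
    for r in df.itertuples():
        if r.rank_source == r.rank_source and str(r.rank_source) != "":  # not NaN
            ranks[r.source] = int(r.rank_source)
        if r.rank_target == r.rank_target and str(r.rank_target) != "":
            ranks[r.target] = int(r.rank_target)
    return GlobalNetwork(edges, ranks)
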