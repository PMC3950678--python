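"""Module-level eQTL mapping by two-stage sparse partial least squares.

Step 2 of the pipeline.  For each discriminative module, the member
transcripts form a multivariate response Y and the candidate predictors
are all SNPs within a cis window (default 1 Mb) of any member gene.
Because candidate sets can be large, selection runs in two stages:
SPLS per chromosome first, then SPLS on the union of per-chromosome
selections.  Finally, selected SNPs are grouped into linkage blocks by
complete-linkage hierarchical clustering on basepair distance (cut at
500 kb) and each block is reduced to the single representative SNP with
the strongest multivariate association (smallest Wilks-lambda MANOVA
p-value of module expression on genotype groups).

The SPLS direction vectors follow the L1/L2-penalized formulation of
Chun & Keles: at each component the first left singular vector z of
X'Y_res is soft-thresholded, c_j = sign(z_j)(|z_j| - eta*max|z|)_+, the
union of nonzero surrogates over components is the active set, and an
ordinary PLS fit restricted to the active set yields the coefficients.
``eta`` in [0, 1) controls sparsity; ``kappa`` (fixed at the standard
0.5) weights the multivariate objective.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .data_io import ExpressionMatrix, GeneAnnotation, GenotypeMatrix
from .discovery import Module

logger = logging.getLogger(__name__)

__all__ = [
    "SplsFit",
    "SnpBlock",
    "ModuleEqtls",
    "EqtlParams",
    "cis_candidate_snps",
    "spls_fit",
    "tune_spls",
    "two_stage_select",
    "cluster_snp_blocks",
    "manova_representative",
    "map_module_eqtls",
]


@dataclass
class SplsFit:
    selected: list[int]  # predictor column indices with nonzero coefficients
    W: np.ndarray  # direction vectors, (p, K_used), unit-norm columns
    beta: np.ndarray  # coefficients, (p, q); rows outside `selected` are zero
    eta: float
    K: int
    kappa: float = 0.5


@dataclass
class SnpBlock:
    chromosome: str
    members: list[str]
    representative: str | None = None
    wilks_p: float = np.nan
    flagged: bool = False


@dataclass
class ModuleEqtls:
    module_id: str
    eqtls: list[str]  # representative SNP ids
    blocks: list[SnpBlock] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)  # stage-2 SPLS selection


@dataclass
class EqtlParams:
    window: int = 1_000_000
    block_cut: int = 500_000
    eta_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    K_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    folds: int = 5
    kappa: float = 0.5


def cis_candidate_snps(
    module: Module,
    genes: GeneAnnotation,
    geno: GenotypeMatrix,
    window: int = 1_000_000,
) -> list[str]:
    """SNPs within ``window`` bp of any member gene's span, same chromosome.

    Returns unique SNP ids ordered by (chromosome, position).  Unannotated
    member genes are skipped with a warning.
    """
    hits: set[str] = set()
    pos = geno.positions.loc[geno.snp_ids]
    for gene in module.members:
        if gene not in genes:
            logger.warning("cis_candidate_snps: gene %s lacks annotation", gene)
            continue
        chrom, start, end = genes.span(gene)
        mask = (
            (pos["chromosome"].astype(str) == chrom)
            & (pos["position"] >= start - window)
            & (pos["position"] <= end + window)
        )
        hits.update(pos.index[mask])
    ordered = sorted(
        hits, key=lambda s: (str(pos.loc[s, "chromosome"]), int(pos.loc[s, "position"]), s)
    )
    return ordered


def _first_left_singular_vector(M: np.ndarray) -> np.ndarray:
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    z = U[:, 0]
    # sign convention: largest-magnitude entry positive, for determinism
    j = int(np.argmax(np.abs(z)))
    return z * np.sign(z[j]) if z[j] != 0 else z


def spls_fit(
    X: np.ndarray, Y: np.ndarray, eta: float, K: int, kappa: float = 0.5
) -> SplsFit:
    """Sparse PLS fit selecting predictor columns of X for multivariate Y."""
    if not (0 <= eta < 1):
        raise ValueError("eta must be in [0, 1)")
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p = X.shape
    q = Y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if K < 1 or K > min(p, n - 1):
        raise ValueError(f"K={K} outside [1, min(p, n-1)={min(p, n - 1)}]")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    active: set[int] = set()
    beta = np.zeros((p, q))
    Y_res = Yc
    pls = None
    cols: list[int] = []
    for k in range(1, K + 1):
        M = Xc.T @ Y_res
        if not np.any(M):
            break
        z = _first_left_singular_vector(M)
        thr = eta * np.max(np.abs(z))
        c = np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
        active |= set(np.flatnonzero(c != 0).tolist())
        cols = sorted(active)
        ncomp = min(k, len(cols), n - 1)
        pls = PLSRegression(n_components=ncomp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(Xc[:, cols], Yc)
        beta = np.zeros((p, q))
        beta[cols, :] = pls.coef_.T  # sklearn coef_ is (q, |A|)
        Y_res = Yc - Xc[:, cols] @ beta[cols, :]
    W = np.zeros((p, pls.x_weights_.shape[1] if pls is not None else 1))
    if pls is not None:
        W[cols, :] = pls.x_weights_
    selected = sorted(np.flatnonzero(np.any(beta != 0, axis=1)).tolist())
    return SplsFit(selected=selected, W=W, beta=beta, eta=eta, K=K, kappa=kappa)


def tune_spls(
    X: np.ndarray,
    Y: np.ndarray,
    eta_grid: tuple[float, ...] = EqtlParams.eta_grid,
    K_grid: tuple[int, ...] = EqtlParams.K_grid,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, int]:
    """Choose (eta, K) by K-fold CV on summed squared prediction error.

    Uses the one-standard-error rule: among settings whose mean CV error is
    within one standard error (over folds) of the minimum, the sparsest is
    chosen — larger eta first, then smaller K.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p = X.shape
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    results: list[tuple[float, float, float, int]] = []  # (mean_mse, se, eta, K)
    for eta in eta_grid:
        for K in K_grid:
            fold_mse = []
            ok = True
            for tr, te in splits:
                if K > min(p, len(tr) - 1):
                    ok = False
                    break
                if np.allclose(Y[tr].std(axis=0), 0):
                    raise ValueError("constant response within a CV fold")
                fit = spls_fit(X[tr], Y[tr], eta=eta, K=K)
                mu_x, mu_y = X[tr].mean(axis=0), Y[tr].mean(axis=0)
                pred = (X[te] - mu_x) @ fit.beta + mu_y
                fold_mse.append(float(np.mean((Y[te] - pred) ** 2)))
            if ok:
                arr = np.asarray(fold_mse)
                se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
                results.append((float(arr.mean()), se, eta, K))
    if not results:
        raise ValueError("no feasible (eta, K) combination")
    best_mse, best_se, _, _ = min(results, key=lambda r: r[0])
    within = [r for r in results if r[0] <= best_mse + best_se]
    within.sort(key=lambda r: (-r[2], r[3]))  # larger eta, then smaller K
    _, _, eta, K = within[0]
    return eta, K


def _polymorphic(dosages: np.ndarray) -> np.ndarray:
    """Boolean mask of rows with more than one genotype value."""
    return np.array([np.unique(row).size > 1 for row in dosages])


def two_stage_select(
    module: Module,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    genes: GeneAnnotation,
    params: EqtlParams | None = None,
    seed: int = 0,
) -> list[str]:
    """Per-chromosome SPLS selection, then SPLS on the union of selections."""
    params = params or EqtlParams()
    candidates = cis_candidate_snps(module, genes, geno, params.window)
    if not candidates:
        logger.warning("module %s: empty cis candidate set", module.seed)
        return []
    Y = expr.subset_genes([g for g in module.members if g in expr.gene_ids]).T
    dos = geno.subset_snps(candidates).astype(float)
    poly = _polymorphic(dos)
    candidates = [s for s, keep in zip(candidates, poly) if keep]
    dos = dos[poly]
    if not candidates:
        return []
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(candidates):
        chrom, _ = geno.position_of(s)
        by_chrom.setdefault(chrom, []).append(i)

    def _select(X: np.ndarray, stage_seed: int) -> list[int]:
        eta, K = tune_spls(
            X, Y, params.eta_grid, params.K_grid, min(params.folds, X.shape[0]), stage_seed
        )
        return spls_fit(X, Y, eta=eta, K=K, kappa=params.kappa).selected

    stage1: list[int] = []
    for chrom in sorted(by_chrom):
        idx = by_chrom[chrom]
        sel = _select(dos[idx].T, seed)
        stage1.extend(idx[j] for j in sel)
    if not stage1:
        return []
    stage1 = sorted(set(stage1))
    if len(by_chrom) == 1:
        final = stage1  # single chromosome: stage 2 would refit the same model
    else:
        sel2 = _select(dos[stage1].T, seed + 1)
        final = [stage1[j] for j in sel2]
    return [candidates[i] for i in final]


def cluster_snp_blocks(
    snps: list[str], geno: GenotypeMatrix, block_cut: int = 500_000
) -> list[SnpBlock]:
    """Group SNPs into linkage blocks per chromosome.

    Complete-linkage hierarchical clustering on |pos_i - pos_j|, tree cut at
    ``block_cut`` basepairs; SNPs on different chromosomes never merge.
    """
    by_chrom: dict[str, list[str]] = {}
    for s in snps:
        chrom, _ = geno.position_of(s)
        by_chrom.setdefault(chrom, []).append(s)
    blocks: list[SnpBlock] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda s: (geno.position_of(s)[1], s))
        if len(members) == 1:
            blocks.append(SnpBlock(chrom, members))
            continue
        pos = np.array([[geno.position_of(s)[1]] for s in members], dtype=float)
        Z = linkage(pos, method="complete", metric="euclidean")
        assign = fcluster(Z, t=block_cut, criterion="distance")
        for label in sorted(set(assign), key=lambda l: min(i for i, a in enumerate(assign) if a == l)):
            blocks.append(SnpBlock(chrom, [m for m, a in zip(members, assign) if a == label]))
    return blocks


def _wilks_manova_p(Y: np.ndarray, groups: np.ndarray) -> float:
    """One-way MANOVA Wilks-lambda p-value of responses Y on group labels."""
    from statsmodels.multivariate.manova import MANOVA

    levels = np.unique(groups)
    if levels.size < 2:
        return 1.0
    q = Y.shape[1]
    df = pd.DataFrame(Y, columns=[f"y{i}" for i in range(q)])
    df["g"] = pd.Categorical(groups.astype(int).astype(str))
    formula = " + ".join(df.columns[:-1]) + " ~ C(g)"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MANOVA.from_formula(formula, data=df).mv_test()
        stat = res.results["C(g)"]["stat"]
        return float(stat.loc["Wilks' lambda", "Pr > F"])
    except Exception:  # singular within-group covariance etc.
        return 1.0


def manova_representative(
    block: SnpBlock, Y: np.ndarray, geno: GenotypeMatrix
) -> SnpBlock:
    """Pick the block member with the smallest Wilks-lambda MANOVA p-value.

    ``Y`` is samples x genes (module expression).  Monomorphic SNPs get
    p = 1; a fully monomorphic block keeps the smallest-position member and
    is flagged.  Ties break toward the smaller genomic position.
    """
    if not block.members:
        raise ValueError("empty SNP block")
    best: tuple[float, int, str] | None = None
    any_poly = False
    for snp in block.members:
        dosage = geno.dosages[geno.snp_index(snp)]
        if np.unique(dosage).size < 2:
            p = 1.0
        else:
            any_poly = True
            p = _wilks_manova_p(Y, dosage)
        key = (p, geno.position_of(snp)[1], snp)
        if best is None or key < best:
            best = key
    block.wilks_p, _, block.representative = best
    block.flagged = not any_poly
    return block


def map_module_eqtls(
    module: Module,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    genes: GeneAnnotation,
    params: EqtlParams | None = None,
    seed: int = 0,
    module_id: str | None = None,
) -> ModuleEqtls:
    """Full per-module mapping: cis window -> two-stage SPLS -> blocks -> reps."""
    params = params or EqtlParams()
    module_id = module_id or module.seed
    selected = two_stage_select(module, geno, expr, genes, params, seed)
    if not selected:
        return ModuleEqtls(module_id, [], [], [])
    Y = expr.subset_genes([g for g in module.members if g in expr.gene_ids]).T
    blocks = [
        manova_representative(b, Y, geno)
        for b in cluster_snp_blocks(selected, geno, params.block_cut)
    ]
    reps = [b.representative for b in blocks if b.representative is not None]
    return ModuleEqtls(module_id, reps, blocks, selected)
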