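"""Phenotype-discriminative module discovery on an interactome.

Step 1 of the pipeline.  Each physical interaction is scored by a hybrid
*bonding score* that favours pairs that either co-express strongly across
all samples or switch their co-expression between the two phenotype
groups (network rewiring).  Modules are grown greedily from every seed
gene, admitting a neighbour only while the joint expression of the
enlarged member set still discriminates the two phenotype groups under a
two-sample Hotelling T-squared test.

Scores
------
For interaction i between genes (x_i1, x_i2):

* ``r1 = |corr(x_i1, x_i2)|`` over all samples (Pearson),
* ``r2 = |corr_1 - corr_2|``, the absolute difference of the group-wise
  Pearson correlations,
* ``q1``, ``q2`` — the percentile ranks of r1 and r2 among all scored
  interactions (fraction of values <= v, so the maximum maps to 1.0),
* ``bonding = max(q1, q2)`` — high if the pair is extreme on either
  criterion.

Expansion from a seed considers, in decreasing bonding order, every
interaction that links a current member to an outside neighbour, skips
candidates at or below the bonding percentile cutoff ``r_cut`` (default
0.90), and admits a candidate iff the Hotelling test on the enlarged set
stays significant at ``alpha`` (default 0.05).  Expansion stops when no
eligible candidate passes or the size cap (default 10) is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import ExpressionMatrix, Interactome, PhenotypeLabels

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionScore",
    "Module",
    "ModuleParams",
    "interaction_correlations",
    "percentile_rank",
    "bonding_scores",
    "hotelling_t2",
    "expand_module",
    "discover_modules",
]


@dataclass
class InteractionScore:
    pair: tuple[str, str]  # sorted
    r1: float
    r2: float
    q1: float = np.nan
    q2: float = np.nan
    bonding: float = np.nan


@dataclass
class Module:
    seed: str
    members: list[str]  # insertion order
    t2: float = np.nan
    pvalue: float = np.nan
    trace: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class ModuleParams:
    r_cut: float = 0.90
    alpha: float = 0.05
    size_cap: int = 10


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation; NaN if either vector is constant."""
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def interaction_correlations(
    expr: ExpressionMatrix, labels: PhenotypeLabels, net: Interactome
) -> list[InteractionScore]:
    """Compute r1 (overall) and r2 (between-group difference) per interaction.

    Interactions with a gene absent from the expression matrix, or with a
    constant-expression gene, are skipped (counted in the log).
    """
    if expr.sample_ids != labels.sample_ids:
        raise ValueError("expression and labels are not sample-aligned")
    m1, m2 = labels.group_masks()
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("each phenotype group needs at least 3 samples")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    scores: list[InteractionScore] = []
    skipped = 0
    for a, b in net.edge_list():
        ia, ib = gene_pos.get(a), gene_pos.get(b)
        if ia is None or ib is None:
            skipped += 1
            continue
        xa, xb = expr.values[ia], expr.values[ib]
        r_all = _pearson(xa, xb)
        r_g1 = _pearson(xa[m1], xb[m1])
        r_g2 = _pearson(xa[m2], xb[m2])
        if np.isnan(r_all) or np.isnan(r_g1) or np.isnan(r_g2):
            skipped += 1
            continue
        scores.append(InteractionScore((a, b), abs(r_all), abs(r_g1 - r_g2)))
    if skipped:
        logger.info("interaction_correlations skipped %d edges", skipped)
    return scores


def percentile_rank(values: np.ndarray | list[float]) -> np.ndarray:
    """Percentile of each value: (# values <= v) / n; ties share, max -> 1.0."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    order = np.sort(v)
    return np.searchsorted(order, v, side="right") / v.size


def bonding_scores(scores: list[InteractionScore]) -> list[InteractionScore]:
    """Fill q1, q2 and the combined bonding score (max of the two percentiles)."""
    if not scores:
        return scores
    q1 = percentile_rank([s.r1 for s in scores])
    q2 = percentile_rank([s.r2 for s in scores])
    for s, a, b in zip(scores, q1, q2):
        s.q1, s.q2 = float(a), float(b)
        s.bonding = float(max(a, b))
    return scores


def hotelling_t2(
    expr_sub: np.ndarray, labels: PhenotypeLabels, ridge: float = 1e-6
) -> tuple[float, float]:
    """Two-sample Hotelling T-squared test on a p x n expression block.

    T2 = (n1*n2/(n1+n2)) * d' S_pooled^{-1} d with d the difference of group
    means; the p-value comes from the exact F transform
    F = ((n1+n2-p-1) / (p (n1+n2-2))) * T2 on (p, n1+n2-p-1) df.
    A small ridge (lambda = ridge * trace(S)/p) regularizes a singular
    pooled covariance.
    """
    X = np.atleast_2d(np.asarray(expr_sub, dtype=float))
    p, n = X.shape
    m1, m2 = labels.group_masks()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    if n != n1 + n2:
        raise ValueError("label/sample mismatch")
    if p >= n1 + n2 - 1:
        raise ValueError(f"dimension p={p} too large for n1+n2={n1 + n2}")
    X1, X2 = X[:, m1], X[:, m2]
    d = X1.mean(axis=1) - X2.mean(axis=1)
    S1 = np.cov(X1) if p > 1 else np.atleast_2d(np.var(X1, ddof=1))
    S2 = np.cov(X2) if p > 1 else np.atleast_2d(np.var(X2, ddof=1))
    S = ((n1 - 1) * np.atleast_2d(S1) + (n2 - 1) * np.atleast_2d(S2)) / (n1 + n2 - 2)
    tr = np.trace(S)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(S + ridge * tr / p * np.eye(p), d)
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    if t2 < 0:  # numerically singular S
        sol = np.linalg.solve(S + ridge * tr / p * np.eye(p), d)
        t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    df2 = n1 + n2 - p - 1
    f_stat = df2 / (p * (n1 + n2 - 2)) * t2
    pvalue = float(stats.f.sf(f_stat, p, df2))
    return t2, pvalue


def expand_module(
    seed: str,
    scores: list[InteractionScore],
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    params: ModuleParams | None = None,
) -> Module:
    """Greedy seeded expansion under the bonding threshold and Hotelling gate.

    Candidates (interactions linking a member to an outside neighbour) are
    tried in decreasing bonding order, ties broken lexicographically by
    gene id; all eligible candidates are tried each round and expansion
    stops when none passes the gate or the size cap is hit.
    """
    params = params or ModuleParams()
    if seed not in expr.gene_ids:
        raise ValueError(f"seed {seed!r} not in expression matrix")
    bonding: dict[frozenset[str], float] = {frozenset(s.pair): s.bonding for s in scores}
    neighbors: dict[str, set[str]] = {}
    for s in scores:
        a, b = s.pair
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    module = Module(seed=seed, members=[seed])
    members = {seed}
    while len(members) < params.size_cap:
        candidates: dict[str, float] = {}
        for m in module.members:
            for nb in neighbors.get(m, ()):
                if nb in members or nb not in expr.gene_ids:
                    continue
                b = bonding[frozenset((m, nb))]
                if b > params.r_cut and b > candidates.get(nb, -1.0):
                    candidates[nb] = b
        if not candidates:
            break
        admitted = False
        for nb, b in sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0])):
            trial = module.members + [nb]
            t2, p = hotelling_t2(expr.subset_genes(trial), labels)
            module.trace.append((nb, b, p))
            if p < params.alpha:
                module.members.append(nb)
                members.add(nb)
                module.t2, module.pvalue = t2, p
                admitted = True
                break
        if not admitted:
            break
    return module


def discover_modules(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    net: Interactome,
    params: ModuleParams | None = None,
) -> list[Module]:
    """Expand a module from every seed; drop singletons; deduplicate member sets."""
    params = params or ModuleParams()
    scores = bonding_scores(interaction_correlations(expr, labels, net))
    universe = sorted(net.genes & set(expr.gene_ids))
    seen: set[frozenset[str]] = set()
    modules: list[Module] = []
    for seed in universe:
        try:
            mod = expand_module(seed, scores, expr, labels, params)
        except ValueError:
            continue
        if mod.size < 2:
            continue
        key = mod.member_set()
        if key in seen:
            continue
        seen.add(key)
        modules.append(mod)
    logger.info("discover_modules: %d modules from %d seeds", len(modules), len(universe))
    return modules
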