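"""eQTL-anchored Bayesian subnetwork inference over module pairs.

Step 3 of the pipeline.  For every unordered pair of modules, a Gaussian
Bayesian network is learned over the union of their member genes plus
the union of their representative eQTLs.  The genetics supplies the
asymmetry that breaks Markov (score) equivalence: edges into an eQTL
node, and edges between eQTL nodes, are blacklisted, so an eQTL can only
act as a root cause.  Genotypes enter additively, coded 0/1/2, and all
nodes are scored with the score-equivalent BGe marginal likelihood
(conjugate normal-Wishart prior), so that on expression data alone
equivalent DAGs tie and only the eQTL constraints orient edges.

Every learned directed gene -> gene edge increments the corresponding
cell of the N x N causation matrix C; c_ij counts how often gene i was
inferred as a direct upstream regulator of gene j across all subnetwork
problems.  The major-direction baseline orients each supported pair by
comparing c_ij with c_ji and drops ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import multigammaln

from .data_io import ExpressionMatrix, GenotypeMatrix, PhenotypeLabels
from .discovery import Module
from .eqtl import ModuleEqtls

logger = logging.getLogger(__name__)

__all__ = [
    "BgeScore",
    "Dag",
    "SubnetworkProblem",
    "SearchConfig",
    "CausationMatrix",
    "gaussian_network_score",
    "build_blacklist",
    "learn_subnetwork",
    "accumulate_causation",
    "major_direction_network",
]


@dataclass
class Dag:
    """Directed acyclic graph as node -> frozenset of parents."""

    nodes: list[str]
    parents: dict[str, frozenset[str]]

    @classmethod
    def empty(cls, nodes: list[str]) -> "Dag":
        return cls(list(nodes), {v: frozenset() for v in nodes})

    def edges(self) -> list[tuple[str, str]]:
        return sorted((u, v) for v, ps in self.parents.items() for u in ps)

    def is_acyclic(self) -> bool:
        children: dict[str, set[str]] = {v: set() for v in self.nodes}
        for v, ps in self.parents.items():
            for u in ps:
                children[u].add(v)
        state: dict[str, int] = {}

        def visit(u: str) -> bool:
            state[u] = 1
            for w in children[u]:
                st = state.get(w, 0)
                if st == 1 or (st == 0 and not visit(w)):
                    return False
            state[u] = 2
            return True

        return all(visit(v) for v in self.nodes if state.get(v, 0) == 0)


class BgeScore:
    """BGe (Gaussian score-equivalent) marginal likelihood on a data matrix.

    Hyperparameters follow the standard recommendation: prior sample sizes
    ``alpha_mu`` = 1 and ``alpha_w`` = d + 2 (d = number of nodes), prior
    mean = sample mean, prior scale T = t * I with
    t = alpha_mu (alpha_w - d - 1) / (alpha_mu + 1), uniform structure
    prior.  The DAG score decomposes into local terms
    score(v | Pa) = log ml(Pa + {v}) - log ml(Pa), each a ratio of
    matrix-variate marginal likelihoods over column subsets.
    """

    def __init__(
        self,
        data: np.ndarray,
        node_names: list[str] | None = None,
        alpha_mu: float = 1.0,
        alpha_w: float | None = None,
    ) -> None:
        data = np.asarray(data, dtype=float)
        self.n, self.d = data.shape
        self.names = node_names or [f"v{i}" for i in range(self.d)]
        self.idx = {v: i for i, v in enumerate(self.names)}
        self.alpha_mu = alpha_mu
        self.alpha_w = alpha_w if alpha_w is not None else self.d + 2.0
        self.t = alpha_mu * (self.alpha_w - self.d - 1.0) / (alpha_mu + 1.0)
        xbar = data.mean(axis=0)
        centred = data - xbar
        # prior mean = sample mean, so the mean-shift term of R vanishes
        self.R = self.t * np.eye(self.d) + centred.T @ centred
        self._subset_ml = lru_cache(maxsize=None)(self._subset_ml_uncached)
        self.local = lru_cache(maxsize=None)(self._local_uncached)

    def _subset_ml_uncached(self, cols: tuple[int, ...]) -> float:
        l = len(cols)
        if l == 0:
            return 0.0
        ix = np.array(cols)
        R_sub = self.R[np.ix_(ix, ix)]
        sign, logdet_R = np.linalg.slogdet(R_sub)
        if sign <= 0:
            raise np.linalg.LinAlgError("posterior scale matrix not PD")
        aw, n, d = self.alpha_w, self.n, self.d
        return (
            -0.5 * n * l * np.log(np.pi)
            + 0.5 * l * np.log(self.alpha_mu / (self.alpha_mu + n))
            + multigammaln((aw + n - d + l) / 2.0, l)
            - multigammaln((aw - d + l) / 2.0, l)
            + 0.5 * (aw - d + l) * l * np.log(self.t)
            - 0.5 * (aw + n - d + l) * logdet_R
        )

    def _local_uncached(self, node: str, parents: frozenset[str]) -> float:
        pa = tuple(sorted(self.idx[p] for p in parents))
        fam = tuple(sorted(pa + (self.idx[node],)))
        return self._subset_ml(fam) - self._subset_ml(pa)

    def score(self, dag: Dag) -> float:
        return sum(self.local(v, dag.parents[v]) for v in dag.nodes)


def gaussian_network_score(
    data: np.ndarray,
    dag: Dag,
    node_names: list[str] | None = None,
    alpha_mu: float = 1.0,
    alpha_w: float | None = None,
) -> float:
    """Log marginal likelihood of ``dag`` for ``data`` (samples x nodes)."""
    if not dag.is_acyclic():
        raise ValueError("graph is cyclic")
    n = data.shape[0]
    if any(len(ps) > n - 2 for ps in dag.parents.values()):
        raise ValueError("parent set larger than n - 2")
    scorer = BgeScore(data, node_names or dag.nodes, alpha_mu, alpha_w)
    return scorer.score(dag)


def build_blacklist(gene_nodes: list[str], eqtl_nodes: list[str]) -> set[tuple[str, str]]:
    """Forbidden directed edges: anything into an eQTL, and eQTL -> eQTL."""
    genes, eqtls = set(gene_nodes), set(eqtl_nodes)
    if genes & eqtls:
        raise ValueError(f"overlapping gene/eqtl nodes: {sorted(genes & eqtls)}")
    bl: set[tuple[str, str]] = set()
    for q in eqtls:
        for x in genes | eqtls:
            if x != q:
                bl.add((x, q))
    return bl


@dataclass
class SubnetworkProblem:
    gene_nodes: list[str]
    eqtl_nodes: list[str]
    data: np.ndarray  # samples x (genes + eqtls), gene columns first
    blacklist: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.gene_nodes = sorted(self.gene_nodes)
        self.eqtl_nodes = sorted(self.eqtl_nodes)
        if not self.blacklist:
            self.blacklist = build_blacklist(self.gene_nodes, self.eqtl_nodes)
        if np.isnan(self.data).any():
            raise ValueError("subnetwork data contains missing values")

    @property
    def nodes(self) -> list[str]:
        return self.gene_nodes + self.eqtl_nodes


@dataclass
class SearchConfig:
    restarts: int = 5
    max_parents: int = 4
    init_edge_prob: float = 0.2
    tol: float = 1e-9


def _hill_climb(
    scorer: BgeScore,
    nodes: list[str],
    blacklist: set[tuple[str, str]],
    cfg: SearchConfig,
    init: dict[str, frozenset[str]] | None = None,
) -> tuple[dict[str, frozenset[str]], float]:
    parents = {v: frozenset() for v in nodes} if init is None else dict(init)
    children: dict[str, set[str]] = {v: set() for v in nodes}
    for v, ps in parents.items():
        for u in ps:
            children[u].add(v)

    def reachable(src: str, dst: str) -> bool:
        # True if a directed path src ->* dst exists
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for w in children[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    total = sum(scorer.local(v, parents[v]) for v in nodes)
    improved = True
    while improved:
        improved = False
        best_gain = cfg.tol
        best_move: tuple[str, str, str] | None = None
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                if u in parents[v]:
                    # delete u -> v
                    gain = scorer.local(v, parents[v] - {u}) - scorer.local(v, parents[v])
                    if gain > best_gain:
                        best_gain, best_move = gain, ("del", u, v)
                    # reverse u -> v  =>  v -> u
                    if (v, u) not in blacklist and len(parents[u]) < cfg.max_parents:
                        children[u].discard(v)
                        cyc = reachable(u, v)
                        children[u].add(v)
                        if not cyc:
                            gain = (
                                scorer.local(v, parents[v] - {u})
                                - scorer.local(v, parents[v])
                                + scorer.local(u, parents[u] | {v})
                                - scorer.local(u, parents[u])
                            )
                            if gain > best_gain:
                                best_gain, best_move = gain, ("rev", u, v)
                elif (
                    (u, v) not in blacklist
                    and len(parents[v]) < cfg.max_parents
                    and not reachable(v, u)
                ):
                    gain = scorer.local(v, parents[v] | {u}) - scorer.local(v, parents[v])
                    if gain > best_gain:
                        best_gain, best_move = gain, ("add", u, v)
        if best_move is not None:
            op, u, v = best_move
            if op == "add":
                parents[v] = parents[v] | {u}
                children[u].add(v)
            elif op == "del":
                parents[v] = parents[v] - {u}
                children[u].discard(v)
            else:  # reverse
                parents[v] = parents[v] - {u}
                children[u].discard(v)
                parents[u] = parents[u] | {v}
                children[v].add(u)
            total += best_gain
            improved = True
    return parents, total


def _random_dag(
    nodes: list[str],
    blacklist: set[tuple[str, str]],
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> dict[str, frozenset[str]]:
    order = list(rng.permutation(nodes))
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if (u, v) in blacklist or len(parents[v]) >= cfg.max_parents:
                continue
            if rng.random() < cfg.init_edge_prob:
                parents[v].add(u)
    return {v: frozenset(ps) for v, ps in parents.items()}


def learn_subnetwork(
    problem: SubnetworkProblem, search: SearchConfig | None = None, seed: int = 0
) -> Dag:
    """Greedy hill climbing (add/delete/reverse) with random restarts.

    Starts from the empty graph, then from ``restarts`` random DAGs sampled
    under the blacklist; returns the best-scoring DAG found.  Deterministic
    given the seed.
    """
    search = search or SearchConfig()
    nodes = problem.nodes
    n = problem.data.shape[0]
    cfg = SearchConfig(
        restarts=search.restarts,
        max_parents=min(search.max_parents, n - 2),
        init_edge_prob=search.init_edge_prob,
        tol=search.tol,
    )
    scorer = BgeScore(problem.data, nodes)
    best_parents, best_score = _hill_climb(scorer, nodes, problem.blacklist, cfg)
    rng = np.random.default_rng(seed)
    for _ in range(cfg.restarts):
        init = _random_dag(nodes, problem.blacklist, cfg, rng)
        parents, score = _hill_climb(scorer, nodes, problem.blacklist, cfg, init)
        if score > best_score + cfg.tol:
            best_parents, best_score = parents, score
    return Dag(nodes, best_parents)


@dataclass
class CausationMatrix:
    genes: list[str]
    counts: np.ndarray  # (N, N) nonnegative ints, zero diagonal

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.genes), len(self.genes)):
            raise ValueError("count matrix shape mismatch")
        if np.diag(self.counts).any():
            raise ValueError("nonzero diagonal")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def get(self, i: str, j: str) -> int:
        gi, gj = self.genes.index(i), self.genes.index(j)
        return int(self.counts[gi, gj])


def _make_problem(
    mod_a: Module,
    mod_b: Module,
    eq_a: ModuleEqtls,
    eq_b: ModuleEqtls,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    use_eqtls: bool = True,
    labels: PhenotypeLabels | None = None,
) -> SubnetworkProblem:
    genes = sorted(
        (set(mod_a.members) | set(mod_b.members)) & set(expr.gene_ids)
    )
    eqtls = sorted(set(eq_a.eqtls) | set(eq_b.eqtls)) if use_eqtls else []
    eqtls = [q for q in eqtls if q in geno.snp_ids and q not in genes]
    E = expr.subset_genes(genes).astype(float)
    if labels is not None:
        # The binary phenotype is an observed common cause of the module
        # genes (they were selected for group mean differences); centring
        # each gene within its phenotype group removes it as a latent
        # confounder that would otherwise distort edge orientation.
        for mask in labels.group_masks():
            E[:, mask] -= E[:, mask].mean(axis=1, keepdims=True)
    cols = [E]
    if eqtls:
        cols.append(geno.subset_snps(eqtls).astype(float))
    data = np.vstack(cols).T  # samples x nodes
    # z-score each column; constant columns stay centred at zero
    data = data - data.mean(axis=0)
    sd = data.std(axis=0)
    sd[sd == 0] = 1.0
    data = data / sd
    return SubnetworkProblem(genes, eqtls, data)


def _pair_counts(
    problem: SubnetworkProblem,
    gene_index: dict[str, int],
    search: SearchConfig,
    seed: int,
) -> np.ndarray:
    N = len(gene_index)
    C = np.zeros((N, N), dtype=int)
    dag = learn_subnetwork(problem, search, seed)
    gene_set = set(problem.gene_nodes)
    for u, v in dag.edges():
        if u in gene_set and v in gene_set:
            C[gene_index[u], gene_index[v]] += 1
    return C


def accumulate_causation(
    modules: list[Module],
    module_eqtls: list[ModuleEqtls],
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    search: SearchConfig | None = None,
    seed: int = 0,
    jobs: int = 1,
    use_eqtls: bool = True,
    labels: PhenotypeLabels | None = None,
) -> CausationMatrix:
    """Learn a subnetwork for every unordered module pair; count gene edges.

    The per-pair sub-seed is derived from (seed, pair index), so results do
    not depend on the processing order or on the number of parallel jobs.
    """
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    if len(module_eqtls) != len(modules):
        raise ValueError("module/eqtl list length mismatch")
    search = search or SearchConfig()
    genes = sorted({g for m in modules for g in m.members if g in expr.gene_ids})
    gene_index = {g: i for i, g in enumerate(genes)}
    pairs = [
        (a, b) for a in range(len(modules)) for b in range(a + 1, len(modules))
    ]
    tasks = []
    for k, (a, b) in enumerate(pairs):
        problem = _make_problem(
            modules[a], modules[b], module_eqtls[a], module_eqtls[b],
            expr, geno, use_eqtls, labels,
        )
        sub_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        tasks.append((problem, sub_seed))
    if jobs > 1:
        from joblib import Parallel, delayed

        parts = Parallel(n_jobs=jobs)(
            delayed(_pair_counts)(p, gene_index, search, s) for p, s in tasks
        )
    else:
        parts = [_pair_counts(p, gene_index, search, s) for p, s in tasks]
    counts = np.sum(parts, axis=0) if parts else np.zeros((len(genes),) * 2, int)
    return CausationMatrix(genes, counts)


def major_direction_network(C: CausationMatrix) -> list[tuple[str, str, int, int]]:
    """Orient each supported pair by its larger count; ties produce no edge."""
    edges = []
    N = len(C.genes)
    for i in range(N):
        for j in range(i + 1, N):
            cij, cji = int(C.counts[i, j]), int(C.counts[j, i])
            if cij + cji < 1 or cij == cji:
                continue
            if cij > cji:
                edges.append((C.genes[i], C.genes[j], cij, cji))
            else:
                edges.append((C.genes[j], C.genes[i], cji, cij))
    return edges
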