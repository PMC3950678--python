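# Methods

## Problem setting and model

The package reconstructs a directed gene network from a genetical-genomics
cohort: an expression matrix Y (genes × samples, assumed normalized and on
log scale), SNP dosages X coded additively as 0/1/2, a binary phenotype
splitting the samples into two condition groups, gene/SNP genomic
annotation, and an undirected molecular interactome. Because a full
directed-network search is super-exponential in the number of genes, the
method works divide-and-conquer: phenotype-relevant modules are selected
first, local causality is inferred per pair of modules with their eQTLs as
orientation anchors, and the local results are merged by a ranking
procedure borrowed from dominance-hierarchy analysis in animal societies.

## Step 1 — discriminative modules

Interactions are scored by `bonding = max(q1, q2)` over the percentile
ranks of r1 (absolute pooled Pearson correlation) and r2 (absolute
difference of the group-wise correlations). The max combination encodes
"strongly coexpressed OR strongly rewired". Percentiles use the fraction
of values ≤ v, so the maximum maps to 1.0 and the 90% cutoff excludes
interactions below the 90th percentile. Greedy expansion from every seed
admits, in decreasing bonding order, neighbours whose inclusion keeps the
two-sample Hotelling T² test significant:

    T² = (n1 n2 / (n1 + n2)) d' S_pooled⁻¹ d,
    F = ((n1 + n2 − p − 1) / (p (n1 + n2 − 2))) T²  ~  F(p, n1 + n2 − p − 1).

A ridge of 1e-6·trace(S)/p is added only when the pooled covariance is
numerically singular (rare with the size cap of 10 and n ≥ 20). All
eligible candidates are tried each round; expansion stops when none passes
or the cap is reached. Bonding ties break lexicographically by gene id, so
the output is deterministic. Note the gate tests *joint* discrimination:
once a module carries an overwhelming group separation, adding one
uninformative gene rarely breaks significance, so modules tend to grow to
the cap with occasional passenger genes — matching the behaviour the
method exhibits on real tumor cohorts.

## Step 2 — module-level eQTL mapping

Candidates are all SNPs within 1 Mb (default) of any member gene's span.
SPLS direction vectors follow the surrogate-thresholding formulation: at
each component the first left singular vector z of X'Y_res is thresholded,
c_j = sign(z_j)(|z_j| − η·max|z|)₊, the active set is the union of nonzero
surrogates over components, and an ordinary PLS refit (scikit-learn,
`scale=False`) on the active set gives the coefficients. η ∈ [0,1)
controls sparsity; κ is kept at the standard 0.5. (η, K) are tuned per
stage by 5-fold cross-validation with the one-standard-error rule
(sparsest setting within one SE of the CV minimum; ties prefer larger η
then smaller K), which guards against picking extra latent components on
CV noise. Monomorphic SNPs are dropped. Selection runs per chromosome and
then on the union; with a single candidate chromosome the second stage
would refit the identical problem and is skipped. Selected SNPs are
clustered per chromosome by complete-linkage on basepair distance, cut at
500 kb; each block's representative is the member with the smallest
Wilks-Λ p-value in a one-way MANOVA of module expression on genotype
groups (genotype is treated additively in SPLS but as a factor in MANOVA;
monomorphic members get p = 1, ties prefer the smaller position).

## Step 3 — pairwise Bayesian subnetworks

For each unordered pair of modules the node set is the union of member
genes plus the union of their representative eQTLs. All nodes are scored
with the score-equivalent BGe marginal likelihood under a conjugate
normal–Wishart prior: prior sample sizes α_μ = 1, α_w = d + 2 (d = number
of nodes), prior mean = sample mean, prior scale t·I with
t = α_μ(α_w − d − 1)/(α_μ + 1). The score of a DAG decomposes into local
terms score(v | Pa) = log ml(Pa ∪ {v}) − log ml(Pa), each a ratio of
subset marginal likelihoods; local terms are cached by (node, parent set).
Score equivalence means expression data alone cannot orient edges — the
genetics does: the blacklist forbids every edge into an eQTL and between
eQTLs, so an eQTL can only act as a root cause, which breaks the
equivalence class exactly where an anchor exists.

Search is greedy hill climbing over add/delete/reverse moves (best
improvement, ties in deterministic lexicographic enumeration order) from
the empty graph plus 5 random restarts (random blacklist-respecting DAGs,
edge probability 0.2), max 4 parents per node. Columns are z-scored.

Because the module genes are *selected* for group mean differences, the
binary phenotype is a common cause of all of them; left in the data it
acts as a latent confounder that systematically distorts edge orientation
(the hill climber explains the shared shift with spurious ancestral
structure). The phenotype is observed, so each gene is centred within its
phenotype group before scoring, which removes the confounder exactly in
the linear-Gaussian setting. On the default synthetic scenario this single
adjustment is the difference between systematic inversion and correct
recovery of the chains.

Every learned gene→gene edge increments the causation matrix C; eQTL
edges are not counted. Pairs are processed independently (optionally in
parallel via joblib); each pair's search seed derives from the master seed
and the pair index, so results are independent of processing order and job
count.

## Step 4 — random-field rank assembly

Control potentials use the Beta posterior of the per-pair counts under a
uniform prior: the point field is the posterior mean
P_ij = (c_ij + 1)/(c_ij + c_ji + 2), and K = 100 fields sampled from
Beta(1 + c_ij, 1 + c_ji) quantify uncertainty. Direct odds
O_ij = P_ij/(1 − P_ij) are combined with one-intermediate transitive odds
T_ihj = P_ih P_hj/(1 − P_ih P_hj) over common neighbours h in the support
graph (pairs with any causation count); transitive odds ≤ 1 are weak
information and are discarded; the overall odds are
W_ij = max(O_ij, max_h T_ihj). The enhanced potential renormalizes the
odds-implied potentials of the two directions,

    P*_ij = p̃_ij / (p̃_ij + p̃_ji),   p̃ = W / (1 + W),

which keeps P*_ij + P*_ji = 1 and reduces exactly to P_ij when no
transitive information exists. Only path length R = 1 is supported.
Potentials at exactly 0 or 1 are clamped at 1e±12.

Ranking minimizes J(σ) = #{(i,j): σ places i below j but P*_ij > 0.5}
(lower-triangle violations of the rearranged P*). Simulated annealing
uses random transpositions, Metropolis acceptance exp(−ΔJ/T), geometric
cooling T₀ = 1, α = 0.999, 20 000 iterations with early stop after 4 000
non-improving moves, and 3 independent restarts keeping the best result;
this schedule matches the exhaustive minimum on ≥ 99/100 random N = 7
fields. ΔJ for a transposition is computed in O(span) from the elements
between the two positions. The final integer order comes from annealing
the enhanced posterior-mean field; per-gene mean and sd of rank positions
come from the K sampled fields. Every pair with c_ij + c_ji ≥ 1 becomes an
edge oriented from the higher-ranked gene down — in particular pairs with
tied counts, which the major-direction baseline must drop.

## Synthetic data generator

The generator emulates a two-condition tumor cohort at desk scale rather
than array-level realism. Genotypes are Hardy–Weinberg Binomial(2, maf)
anchors; other members of a linkage block copy their anchor and are
redrawn with probability ε = 0.05 per sample (within-block r ≈ 0.95 at
the default). Expression follows a linear-Gaussian SEM in topological
order: x_g = shift_g·1[group 1] + Σ b·x_parent·1[edge active] +
Σ a·dosage + N(0, σ²). Condition-gated edges are active only in group 1
and create coexpression rewiring (the r2 signal); per-gene group shifts
create the mean differences the Hotelling gate needs. The default
scenario has 6 chains of 5 genes (one chain per chromosome, gene labels
shuffled against chain positions so identifiers carry no ordering
information), one cis-eQTL per chain on its first gene (effect a = 1,
inside a 3-SNP block, with 3 decoy blocks > 500 kb away per chromosome),
chain coefficients b = 0.8, noise σ = 0.5, group shift 0.6, 70 bystander
noise genes, 500 decoy interactions and n = 200 samples (100 per group).
The shift of 0.6 gives each chain decisive Hotelling significance while
keeping the cross-module correlation induced by the shared shift small
(≈ 0.1). Sizes were chosen so the full pipeline completes in minutes on
one CPU.

What passing tests on these data do *not* show: robustness to array
noise, probe effects, population structure, realistic LD decay,
non-linear regulation, or hidden confounders other than the phenotype
itself. The generator's SEM matches the linearity and additive-coding
assumptions of the scoring model, so recovery rates here are an upper
bound on what comparable real data would give.

## Numerical choices and degenerate inputs

- Missing genotypes are imputed at load by the per-SNP rounded mean
  (keeps dosages in {0,1,2}); entirely missing SNPs are an error.
- Sample order is canonicalized to the expression file; alignment drops
  unmatched samples with a warning and fails below 4 shared samples.
- Constant-expression genes make correlations undefined; their
  interactions are skipped with a logged count.
- An empty cis-candidate set, or an empty SPLS selection, flags the module
  and yields no eQTLs rather than an error.
- Chromosome names are matched verbatim as strings across files.
- Hill-climbing move ties and bonding ties break lexicographically;
  annealing is seeded; per-pair sub-seeds derive from (master seed, pair
  index) — identical configs and seeds reproduce byte-identical outputs.

## Known limitations

- The Hotelling gate does not test the marginal contribution of a
  candidate gene, so strong modules absorb passengers up to the size cap.
- Transitivity is limited to one intermediate (R = 1); longer paths are
  deliberately not followed.
- Only the single best-scoring DAG per module pair contributes to the
  causation matrix; near-optimal alternatives are ignored.
- The conditional-Gaussian treatment codes genotypes additively and models
  them as Gaussian nodes; dominant/recessive recodings are available only
  as a data recode, not as a discrete-node score.
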