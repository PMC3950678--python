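# causanet

Causal gene-network reconstruction from genetical-genomics data — paired
gene-expression and SNP-genotype profiles of one cohort — by eQTL-anchored
Bayesian subnetwork assembly.

Directed gene networks are hard to infer from expression data alone because
Gaussian networks that differ only in edge orientation are
likelihood-equivalent. Naturally occurring DNA variation breaks the tie:
a variant that drives a transcript (an eQTL) can only be a cause, never an
effect. `causanet` exploits this in four steps, designed for two-condition
cohorts (e.g. tumors with and without nodal metastasis):

1. **Discriminative module discovery.** Every interaction *i* of a
   molecular interactome is scored with a bonding score
   `b_i = max(q_i1, q_i2)`, where `q_i1` is the percentile of
   `r_i1 = |corr(x_i1, x_i2)|` (coexpression over all samples) and `q_i2`
   the percentile of `r_i2 = |corr_1 − corr_2|` (coexpression *rewiring*
   between the phenotype groups). Modules are grown greedily from every
   seed gene over interactions with `b_i > 0.90`, admitting a neighbour
   only while the member set still separates the two phenotype groups under
   a two-sample Hotelling T² test (α = 0.05), up to 10 genes.
2. **Module-level eQTL mapping.** Each module's transcripts form a
   multivariate response; candidate SNPs within 1 Mb of any member gene are
   screened by two-stage sparse partial least squares (per chromosome, then
   on the union), clustered into linkage blocks (complete linkage, 500 kb
   cut), and each block is reduced to the representative SNP with the
   smallest Wilks-Λ MANOVA p-value.
3. **Pairwise subnetwork inference.** For every pair of modules, a Gaussian
   Bayesian network over the member genes plus their eQTLs is learned by
   hill climbing under the BGe marginal-likelihood score, with edges into
   eQTLs (and between eQTLs) forbidden. Each learned gene→gene edge
   increments a causation matrix `C`: `c_ij` counts how often gene *i* was
   inferred as a direct upstream regulator of gene *j*.
4. **Random-field rank assembly.** Control potentials
   `P_ij ~ Beta(1 + c_ij, 1 + c_ji)` are enhanced with one-step transitive
   odds through common neighbours, and a global gene ranking minimizing
   orientation errors is found by simulated annealing; every supported pair
   is oriented from the higher-ranked gene down. This recovers orientations
   the simple majority rule (`c_ij` vs `c_ji`) leaves undecided.

A synthetic-data generator with known causal structure (linkage-block
genotypes, linear-Gaussian SEM expression, condition-gated edges, decoy
interactions) and a directional concordance evaluator serve as the test
harness.

## Worked example

```python
from causanet.simulate import default_scenario, evaluate_concordance
from causanet.pipeline import run_steps, PipelineConfig

sc = default_scenario(seed=1)          # 6 chains x 5 genes, 1 cis-eQTL each, n=200
res = run_steps(sc.expr, sc.geno, sc.labels, sc.annotation,
                sc.interactome, PipelineConfig(seed=1))
conc = evaluate_concordance(res.network, sc.reference_edges)
print(len(res.modules), conc.concordant, conc.inverted, round(conc.rate, 3))
```

prints

```
13 21 3 0.875
```

meaning 13 discriminative modules were found and, of the 24 inferred edges
whose gene pair occurs in the generating truth, 21 are oriented correctly
and 3 are inverted — a concordance rate of 87.5%. Rerunning with
`PipelineConfig(seed=1, use_eqtls=False)` drops the rate to 54.2%,
quantifying what the eQTL anchors contribute.

The same steps are available from the shell:

```bash
causanet simulate --seed 1 --out-dir data/
causanet run --config config.yaml          # or: modules / eqtl / subnets / assemble
causanet evaluate --inferred out/network.tsv --reference data/truth_dag.tsv
```

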