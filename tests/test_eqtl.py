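import numpy as np
import pandas as pd
import pytest

from causanet.data_io import ExpressionMatrix, GeneAnnotation, GenotypeMatrix
from causanet.discovery import Module
from causanet.eqtl import (
    EqtlParams,
    SnpBlock,
    cis_candidate_snps,
    cluster_snp_blocks,
    manova_representative,
    map_module_eqtls,
    spls_fit,
    tune_spls,
    two_stage_select,
)


def _geno(snp_pos, n=20, seed=0, dosages=None):
    """GenotypeMatrix from {snp: (chrom, pos)}; random dosages unless given."""
    rng = np.random.default_rng(seed)
    snps = list(snp_pos)
    if dosages is None:
        dosages = rng.binomial(2, 0.4, size=(len(snps), n))
    pos = pd.DataFrame(
        [(s, c, p) for s, (c, p) in snp_pos.items()],
        columns=["snp", "chromosome", "position"],
    ).set_index("snp")
    return GenotypeMatrix(snps, [f"s{i:03d}" for i in range(n)], np.asarray(dosages), pos)


class TestCisCandidates:
    def setup_method(self):
        self.annot = GeneAnnotation(
            pd.DataFrame(
                {"chromosome": ["chr1"], "start": [1_000_000], "end": [1_050_000]},
                index=["gA"],
            )
        )
        self.module = Module(seed="gA", members=["gA"])

    @pytest.mark.parametrize(
        "snp_pos, expected",
        [
            ({"r1": ("chr1", 1_900_000)}, ["r1"]),  # inside downstream window
            ({"r1": ("chr1", 2_100_001)}, []),  # 50,001 bp past the window
            ({"r1": ("chr2", 1_020_000)}, []),  # wrong chromosome
            ({"r1": ("chr1", 1)}, ["r1"]),  # upstream window clipped at zero
        ],
    )
    def test_window_arithmetic(self, snp_pos, expected):
        geno = _geno(snp_pos)
        assert cis_candidate_snps(self.module, self.annot, geno) == expected

    def test_order_and_dedup_across_members(self):
        annot = GeneAnnotation(
            pd.DataFrame(
                {
                    "chromosome": ["chr1", "chr1"],
                    "start": [1_000_000, 1_200_000],
                    "end": [1_050_000, 1_210_000],
                },
                index=["gA", "gB"],
            )
        )
        geno = _geno({"r2": ("chr1", 1_500_000), "r1": ("chr1", 900_000)})
        got = cis_candidate_snps(Module("gA", ["gA", "gB"]), annot, geno)
        assert got == ["r1", "r2"]  # position order, shared hits deduplicated


class TestSplsFit:
    def test_single_component_on_orthonormal_predictors_is_ols(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(50, 2))
        A -= A.mean(axis=0)
        X = np.linalg.qr(A)[0]  # centred orthonormal columns
        y = X @ np.array([2.0, -1.0]) + rng.normal(0, 0.1, 50)
        fit = spls_fit(X, y, eta=0.0, K=1)
        ols = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)[0]
        assert fit.beta.ravel() == pytest.approx(ols, abs=1e-8)
        assert fit.selected == [0, 1]

    def test_recovers_true_predictor_among_many(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.3, size=(100, 100)).astype(float)
        Y = np.column_stack([X[:, 0] + rng.normal(0, 0.1, 100) for _ in range(3)])
        fit = spls_fit(X, Y, eta=0.8, K=1)
        assert 0 in fit.selected

    def test_null_selection_stays_small(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.3, size=(100, 100)).astype(float)
        Y = np.column_stack([X[:, 0] + rng.normal(0, 0.1, 100) for _ in range(3)])
        sizes = []
        for _ in range(25):
            fit = spls_fit(X[rng.permutation(100)], Y, eta=0.8, K=1)
            sizes.append(len(fit.selected))
        assert np.median(sizes) <= 5

    def test_eta_monotone_selection_single_component(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 30))
        Y = X[:, :3] @ rng.normal(size=(3, 2)) + rng.normal(0, 0.5, size=(60, 2))
        sizes = [len(spls_fit(X, Y, eta=e, K=1).selected) for e in (0.0, 0.3, 0.6, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_unit_norm_directions_and_support_consistency(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 10))
        Y = rng.normal(size=(40, 2))
        fit = spls_fit(X, Y, eta=0.5, K=2)
        norms = np.linalg.norm(fit.W, axis=0)
        assert norms == pytest.approx(np.ones_like(norms))
        nonzero_rows = set(np.flatnonzero(np.any(fit.beta != 0, axis=1)))
        assert nonzero_rows == set(fit.selected)

    def test_snp_relabeling_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 12))
        Y = X[:, 4:6] @ np.array([[1.0], [0.8]]) + rng.normal(0, 0.3, size=(50, 1))
        perm = rng.permutation(12)
        base = spls_fit(X, Y, eta=0.6, K=1).selected
        permuted = spls_fit(X[:, perm], Y, eta=0.6, K=1).selected
        assert sorted(perm[permuted]) == base

    def test_parameter_validation(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            spls_fit(X, np.zeros(10), eta=1.0, K=1)
        with pytest.raises(ValueError):
            spls_fit(X, np.zeros(10), eta=0.5, K=4)


class TestTuneSpls:
    def test_strong_single_predictor_prefers_one_component(self):
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.3, size=(100, 100)).astype(float)
        Y = np.column_stack([X[:, 0] + rng.normal(0, 0.1, 100) for _ in range(3)])
        eta, K = tune_spls(X, Y, seed=1)
        assert K == 1

    def test_pure_noise_prefers_sparse_model(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, 0.3, size=(100, 50)).astype(float)
        Y = rng.normal(size=(100, 3))
        eta, _ = tune_spls(X, Y, seed=1)
        assert eta >= 0.5

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            tune_spls(np.zeros((4, 2)), np.zeros(4), folds=5)


class TestSnpBlocks:
    def test_complete_linkage_split(self):
        geno = _geno(
            {"a": ("chr1", 100_000), "b": ("chr1", 200_000), "c": ("chr1", 900_000)}
        )
        blocks = cluster_snp_blocks(["a", "b", "c"], geno)
        members = [b.members for b in blocks]
        assert members == [["a", "b"], ["c"]]

    def test_singleton(self):
        geno = _geno({"a": ("chr1", 100)})
        blocks = cluster_snp_blocks(["a"], geno)
        assert blocks[0].members == ["a"]

    def test_chromosomes_never_merge(self):
        geno = _geno({"a": ("chr1", 100), "b": ("chr2", 100)})
        blocks = cluster_snp_blocks(["a", "b"], geno)
        assert len(blocks) == 2

    def test_chained_positions_respect_complete_linkage(self):
        # pairwise gaps of 400 kb chain, but 100k..900k span exceeds the cut
        geno = _geno(
            {"a": ("chr1", 100_000), "b": ("chr1", 500_000), "c": ("chr1", 900_000)}
        )
        blocks = cluster_snp_blocks(["a", "b", "c"], geno)
        assert all(
            max(geno.position_of(s)[1] for s in b.members)
            - min(geno.position_of(s)[1] for s in b.members)
            <= 500_000
            for b in blocks
        )


class TestManovaRepresentative:
    def test_singleton_block(self):
        geno = _geno({"a": ("chr1", 100)}, n=30, seed=1)
        Y = np.random.default_rng(0).normal(size=(30, 2))
        block = manova_representative(SnpBlock("chr1", ["a"]), Y, geno)
        assert block.representative == "a"

    def test_signal_snp_beats_noise_snp(self):
        rng = np.random.default_rng(2)
        n = 60
        sig = rng.binomial(2, 0.4, n)
        noise = rng.binomial(2, 0.4, n)
        geno = _geno(
            {"sig": ("chr1", 100), "noise": ("chr1", 200)},
            n=n,
            dosages=np.vstack([sig, noise]),
        )
        Y = np.column_stack([sig * 1.0 + rng.normal(0, 0.3, n) for _ in range(3)])
        block = manova_representative(SnpBlock("chr1", ["sig", "noise"]), Y, geno)
        assert block.representative == "sig"
        assert block.wilks_p < 0.01

    def test_monomorphic_block_flagged(self):
        geno = _geno(
            {"a": ("chr1", 500), "b": ("chr1", 100)},
            n=10,
            dosages=np.ones((2, 10), dtype=int),
        )
        block = manova_representative(SnpBlock("chr1", ["a", "b"]), np.zeros((10, 2)), geno)
        assert block.flagged
        assert block.wilks_p == 1.0
        assert block.representative == "b"  # smaller position on total tie


def _two_chrom_fixture(seed=0, n=150):
    """Module of 4 genes; one true eQTL per chromosome among decoy SNPs."""
    rng = np.random.default_rng(seed)
    snp_pos = {}
    dosages = []
    snps = []
    for chrom in ("chr1", "chr2"):
        for k in range(6):
            s = f"{chrom}_r{k}"
            snps.append(s)
            snp_pos[s] = (chrom, 1_000_000 + 600_000 * k)
            dosages.append(rng.binomial(2, 0.4, n))
    geno = _geno(snp_pos, n=n, dosages=np.vstack(dosages))
    q1 = geno.dosages[geno.snp_index("chr1_r0")]
    q2 = geno.dosages[geno.snp_index("chr2_r3")]
    genes = ["gA", "gB", "gC", "gD"]
    vals = np.vstack(
        [
            q1 + rng.normal(0, 0.4, n),
            q1 * 0.8 + rng.normal(0, 0.4, n),
            q2 + rng.normal(0, 0.4, n),
            q2 * 0.8 + rng.normal(0, 0.4, n),
        ]
    )
    expr = ExpressionMatrix(genes, geno.sample_ids, vals)
    annot = GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": ["chr1", "chr1", "chr2", "chr2"],
                "start": [1_100_000, 2_000_000, 2_500_000, 3_000_000],
                "end": [1_110_000, 2_010_000, 2_510_000, 3_010_000],
            },
            index=genes,
        )
    )
    return Module("gA", genes), geno, expr, annot


class TestTwoStageSelect:
    def test_true_eqtl_found_on_each_chromosome(self):
        module, geno, expr, annot = _two_chrom_fixture()
        selected = two_stage_select(module, geno, expr, annot, seed=3)
        assert "chr1_r0" in selected
        assert "chr2_r3" in selected

    def test_empty_candidates_give_empty_selection(self):
        module, geno, expr, _ = _two_chrom_fixture()
        far = GeneAnnotation(
            pd.DataFrame(
                {"chromosome": ["chr9"] * 4, "start": [1] * 4, "end": [2] * 4},
                index=module.members,
            )
        )
        assert two_stage_select(module, geno, expr, far) == []


class TestMapModuleEqtls:
    def test_ld_block_reduced_to_one_representative(self):
        rng = np.random.default_rng(4)
        n = 150
        anchor = rng.binomial(2, 0.4, n)
        flip = rng.random((2, n)) < 0.05
        linked = [np.where(flip[i], rng.binomial(2, 0.4, n), anchor) for i in range(2)]
        dosages = np.vstack([anchor, linked[0], linked[1], rng.binomial(2, 0.4, n)])
        geno = _geno(
            {
                "b0": ("chr1", 1_000_000),
                "b1": ("chr1", 1_100_000),
                "b2": ("chr1", 1_200_000),
                "far": ("chr1", 2_400_000),
            },
            n=n,
            dosages=dosages,
        )
        genes = ["gA", "gB"]
        expr = ExpressionMatrix(
            genes,
            geno.sample_ids,
            np.vstack(
                [anchor + rng.normal(0, 0.4, n), anchor * 0.8 + rng.normal(0, 0.4, n)]
            ),
        )
        annot = GeneAnnotation(
            pd.DataFrame(
                {"chromosome": ["chr1"] * 2, "start": [1_500_000] * 2, "end": [1_510_000] * 2},
                index=genes,
            )
        )
        res = map_module_eqtls(Module("gA", genes), geno, expr, annot, seed=5)
        assert len(res.eqtls) == len(res.blocks)
        assert len([r for r in res.eqtls if r.startswith("b")]) == 1

    def test_distant_true_eqtls_give_two_representatives(self):
        module, geno, expr, annot = _two_chrom_fixture()
        res = map_module_eqtls(module, geno, expr, annot, seed=6)
        chroms = {geno.position_of(r)[0] for r in res.eqtls}
        assert chroms == {"chr1", "chr2"}
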