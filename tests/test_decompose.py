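"""GRM construction, REML estimation, the boundary LRT and the BLUP split."""

import numpy as np
import pandas as pd
import pytest

from cistwas.decompose import (compute_grm, decompose_chromosome, decompose_gene,
                               fit_reml, lrt_cis_p, merge_components)
from cistwas.reml import EigenGRM, restricted_loglik
from cistwas.simulate import SimulationConfig, simulate_genotypes
from conftest import make_panel


def dense_restricted_loglik(y, G, Vg, Ve):
    """Independent dense evaluation of the restricted log-likelihood."""
    n = len(y)
    V = Vg * G + Ve * np.eye(n)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    C = one @ Vi @ one
    beta = (one @ Vi @ y) / C
    r = y - beta
    return -0.5 * ((n - 1) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                   + np.log(C) + r @ Vi @ r)


class TestGRM:
    def test_two_individual_hand_value(self):
        # one variant, dosages (0, 2): p = 0.5, standardized +-sqrt(2)
        panel = make_panel(np.array([[0.0], [2.0]]))
        A = compute_grm(panel).values
        np.testing.assert_allclose(A, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_allele_flip_invariance(self, rng):
        dosage = rng.choice([0.0, 1.0, 2.0], size=(40, 15))
        dosage = dosage[:, dosage.std(axis=0) > 0]
        a = compute_grm(make_panel(dosage)).values
        b = compute_grm(make_panel(2.0 - dosage)).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_identical_individuals_equal_rows(self, rng):
        dosage = rng.choice([0.0, 1.0, 2.0], size=(10, 8))
        dosage[3] = dosage[7]
        dosage = dosage[:, dosage.std(axis=0) > 0]
        A = compute_grm(make_panel(dosage)).values
        np.testing.assert_allclose(A[3], A[7], atol=1e-12)

    def test_zero_variants_error(self):
        empty = make_panel(np.zeros((4, 0)))
        with pytest.raises(ValueError, match="no cis variants"):
            compute_grm(empty)


class TestREML:
    def test_grid_oracle_small_n(self):
        """Fitted (Vg, Ve, loglik) matches a brute-force restricted-likelihood grid."""
        rng = np.random.default_rng(7)
        for trial in range(3):
            n = 6
            Z = rng.standard_normal((n, 12))
            G = Z @ Z.T / 12
            g = np.linalg.cholesky(G + 1e-9 * np.eye(n)) @ rng.standard_normal(n)
            y = g + 0.7 * rng.standard_normal(n)
            fit, eig = fit_reml(y, G)
            yvar = y.var(ddof=1)
            grid = np.linspace(1e-6 * yvar, 3.0 * yvar, 200)
            lls = np.array([[dense_restricted_loglik(y, G, vg, ve) for ve in grid]
                            for vg in grid])
            best = lls.max()
            # the optimizer must not be beaten by the grid...
            assert fit.loglik >= best - 1e-6
            # ...and must agree with the dense likelihood at its own optimum
            assert abs(fit.loglik - dense_restricted_loglik(y, G, fit.Vg, fit.Ve)) < 1e-6
            # grid argmax lies within one grid step of the fitted components
            i, j = np.unravel_index(lls.argmax(), lls.shape)
            step = grid[1] - grid[0]
            assert abs(grid[i] - fit.Vg) <= step + 1e-9
            assert abs(grid[j] - fit.Ve) <= step + 1e-9

    def test_null_truth_small_estimate(self):
        """i.i.d. response on an unrelated panel: Vg near the floor, LRT near 0."""
        rng = np.random.default_rng(11)
        cfg = SimulationConfig(n_individuals=300, n_chromosomes=1,
                               genes_per_chromosome=1,
                               variants_per_gene_window=50,
                               n_subpopulations=1, divergence=0.0,
                               ld_decay=0.0, cis_h2=0.0, seed=5)
        panel, _, _ = simulate_genotypes(cfg)
        grm = compute_grm(panel)
        y = rng.standard_normal(300)
        fit, _ = fit_reml(y, grm)
        assert fit.Vg / (fit.Vg + fit.Ve) < 0.15
        assert 2 * (fit.loglik - fit.loglik_null) < 4.0

    def test_parameter_recovery_h2_half(self):
        """Mean recovered variance proportion near the planted 0.5."""
        ests = []
        for seed in range(12):
            cfg = SimulationConfig(n_individuals=250, n_chromosomes=1,
                                   genes_per_chromosome=1,
                                   variants_per_gene_window=60,
                                   cis_h2=0.5, seed=seed)
            panel, _, ann = simulate_genotypes(cfg)
            from cistwas.simulate import simulate_expression
            rng = np.random.default_rng(1000 + seed)
            expr, _ = simulate_expression(cfg, panel, ann, rng)
            fit, _ = fit_reml(expr.gene("G1_001"), compute_grm(panel))
            ests.append(fit.Vg / (fit.Vg + fit.Ve))
        assert abs(np.mean(ests) - 0.5) < 0.08

    def test_full_likelihood_never_below_null(self, rng):
        Z = rng.standard_normal((20, 5))
        G = Z @ Z.T / 5
        y = rng.standard_normal(20)
        fit, _ = fit_reml(y, G)
        assert fit.loglik >= fit.loglik_null - 1e-6


class TestLRT:
    def test_zero_statistic_gives_half(self):
        assert lrt_cis_p(10.0, 10.0) == 0.5

    def test_five_percent_tail_halved(self):
        # chi2(1) upper 5% point 3.841459 -> mixture p = 0.025
        assert lrt_cis_p(10.0 + 3.841459 / 2, 10.0) == pytest.approx(0.025, rel=1e-5)

    def test_floor(self):
        assert lrt_cis_p(5e5, 0.0) == 1e-300


class TestBLUP:
    @staticmethod
    def _fit_components(y, G, Vg, Ve):
        eig = EigenGRM.build(G, y)
        return decompose_gene(y, eig, Vg, Ve, "g", [f"I{i}" for i in range(len(y))])

    def test_mixed_model_equations_oracle(self, rng):
        """BLUP matches the dense Henderson mixed-model-equations solve, n = 5."""
        n = 5
        Z = rng.standard_normal((n, 10))
        G = Z @ Z.T / 10 + 0.05 * np.eye(n)   # full rank so G^-1 exists
        y = rng.standard_normal(n) + 1.5
        Vg, Ve = 0.8, 0.4
        comp = self._fit_components(y, G, Vg, Ve)
        X = np.ones((n, 1))
        lhs = np.block([[X.T @ X, X.T],
                        [X, np.eye(n) + (Ve / Vg) * np.linalg.inv(G)]])
        rhs = np.concatenate([X.T @ y, y])
        sol = np.linalg.solve(lhs, rhs)
        mu_hat, u_hat = sol[0], sol[1:]
        np.testing.assert_allclose(comp.cis_ec, u_hat, atol=1e-8)
        np.testing.assert_allclose(comp.cis_pred - comp.cis_ec,
                                   np.full(n, mu_hat), atol=1e-8)

    def test_noiseless_limit(self, rng):
        n = 8
        Z = rng.standard_normal((n, 20))
        G = Z @ Z.T / 20 + 0.1 * np.eye(n)
        y = rng.standard_normal(n)
        comp = self._fit_components(y, G, 1.0, 1e-10)
        mu = comp.cis_pred[0] - comp.cis_ec[0]
        np.testing.assert_allclose(comp.cis_ec, y - mu, atol=1e-5)
        assert np.max(np.abs(comp.trans_ec)) < 1e-5

    def test_no_signal_limit(self, rng):
        n = 8
        Z = rng.standard_normal((n, 20))
        G = Z @ Z.T / 20
        y = rng.standard_normal(n)
        comp = self._fit_components(y, G, 1e-12, 1.0)
        assert np.max(np.abs(comp.cis_ec)) < 1e-9
        mu = comp.cis_pred[0] - comp.cis_ec[0]
        np.testing.assert_allclose(comp.trans_ec, y - mu, atol=1e-8)

    def test_shrinkage_bound(self, small_dataset, decomposed):
        """var(cis_ec) never exceeds var(y) for any gene."""
        cis = decomposed["cis"]
        for g in cis.index:
            assert cis.loc[g].var() <= small_dataset.expression.gene(g).var() + 1e-10


class TestChromosomeDriver:
    def test_empty_gene_table(self, small_dataset):
        d = small_dataset
        empty = d.annotation.iloc[0:0]
        vcs, comps = decompose_chromosome(empty, d.panel, d.expression)
        assert vcs == [] and comps == []

    def test_variant_desert_flagged(self, small_dataset):
        d = small_dataset
        genes = d.annotation[d.annotation["chr"] == "1"].iloc[:1].copy()
        genes[["start", "end"]] = (90_000_000, 90_005_000)  # no variants out there
        vcs, comps = decompose_chromosome(genes, d.panel, d.expression,
                                          extend=d.config.extend)
        assert vcs[0].n_cis_variants == 0
        assert vcs[0].cis_p == 1.0
        np.testing.assert_array_equal(comps[0].cis_ec, 0.0)
        y = d.expression.gene(vcs[0].gene_id)
        np.testing.assert_allclose(comps[0].trans_ec, y - y.mean(), atol=1e-10)

    def test_decomposition_identity_all_genes(self, small_dataset, decomposed):
        """cis_ec + trans_ec reproduces the centered expression everywhere."""
        d = small_dataset
        cis, trans, pred = decomposed["cis"], decomposed["trans"], decomposed["pred"]
        for g in cis.index:
            y = d.expression.gene(g)
            mu = (pred.loc[g] - cis.loc[g]).to_numpy()
            assert np.allclose(mu, mu[0])  # fitted mean is a constant shift
            err = np.max(np.abs(cis.loc[g].to_numpy() + trans.loc[g].to_numpy()
                                - (y - mu)))
            assert err < 1e-8

    def test_planted_genes_have_smallest_p(self):
        """Genes with planted cis signal outrank null genes on cis_p."""
        hits = 0
        n_rep = 5
        for seed in range(n_rep):
            h2 = {f"G1_{i:03d}": (0.6 if i <= 5 else 0.0) for i in range(1, 11)}
            cfg = SimulationConfig(n_individuals=200, n_chromosomes=1,
                                   genes_per_chromosome=10,
                                   variants_per_gene_window=12,
                                   cis_h2=h2, seed=100 + seed)
            from cistwas.simulate import simulate_dataset
            d = simulate_dataset(cfg)
            vcs, _ = decompose_chromosome(d.annotation, d.panel, d.expression,
                                          extend=cfg.extend)
            order = sorted(vcs, key=lambda v: v.cis_p)[:5]
            planted = {f"G1_{i:03d}" for i in range(1, 6)}
            if {v.gene_id for v in order} == planted:
                hits += 1
        assert hits >= n_rep - 1


class TestMerge:
    def test_two_chromosomes_concatenated_in_order(self, small_dataset):
        d = small_dataset
        per_chrom = []
        for c in ["2", "1"]:  # deliberately reversed input order
            genes = d.annotation[d.annotation["chr"] == c].reset_index(drop=True)
            vcs, comps = decompose_chromosome(genes, d.panel, d.expression,
                                              extend=d.config.extend)
            per_chrom.append((genes, vcs, comps))
        tables = merge_components(per_chrom)
        assert len(tables["vc"]) == 16
        ann = d.annotation.set_index("Gene")
        keys = [(ann.loc[g, "chr"], ann.loc[g, "start"]) for g in tables["vc"].index]
        assert keys == sorted(keys)

    def test_duplicate_gene_error(self, small_dataset):
        d = small_dataset
        genes = d.annotation[d.annotation["chr"] == "1"].reset_index(drop=True)
        vcs, comps = decompose_chromosome(genes, d.panel, d.expression,
                                          extend=d.config.extend)
        with pytest.raises(ValueError, match="twice"):
            merge_components([(genes, vcs, comps), (genes, vcs, comps)])

    def test_inconsistent_individuals_error(self, small_dataset):
        d = small_dataset
        genes = d.annotation[d.annotation["chr"] == "1"].reset_index(drop=True)
        vcs, comps = decompose_chromosome(genes, d.panel, d.expression,
                                          extend=d.config.extend)
        genes2 = d.annotation[d.annotation["chr"] == "2"].reset_index(drop=True)
        expr2 = d.expression.subset_individuals(d.expression.individual_ids[:-1])
        panel2 = d.panel.subset_individuals(expr2.individual_ids)
        vcs2, comps2 = decompose_chromosome(genes2, panel2, expr2,
                                            extend=d.config.extend)
        with pytest.raises(ValueError, match="individual"):
            merge_components([(genes, vcs, comps), (genes2, vcs2, comps2)])
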