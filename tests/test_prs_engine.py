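"""Polygenic scoring: allele alignment, LD estimation, posterior-mean
weights (closed-form, dense-solve and quadrature oracles), scoring,
hyperparameter selection and LD score regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from polygxe import (
    GenotypePanel,
    SimulationConfig,
    align_alleles,
    estimate_ld,
    ldpred_gibbs_weights,
    ldpred_inf_weights,
    ldsc_h2,
    residualize_covariates,
    score_individuals,
    select_p_by_auc,
    simulate_cohort,
    simulate_panel,
    simulate_sumstats,
)
from polygxe.prs_engine import DEFAULT_P_GRID, LDMatrix, WeightVector


def _toy_panel(dosages, a1=None, a2=None, block=None):
    dosages = np.asarray(dosages)
    M = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(M)],
            "block": block if block is not None else np.zeros(M, dtype=int),
            "block_rho": 0.0,
            "a1": a1 if a1 is not None else ["A"] * M,
            "a2": a2 if a2 is not None else ["G"] * M,
            "freq": dosages.mean(axis=0) / 2.0,
        }
    )
    return GenotypePanel(dosages=dosages.astype(np.int8), variants=variants)


def _toy_sumstats(panel, beta):
    return pd.DataFrame(
        {
            "snp": panel.variants["id"],
            "a1": panel.variants["a1"],
            "a2": panel.variants["a2"],
            "beta": beta,
            "se": 0.01,
            "n": 10_000,
            "freq": panel.variants["freq"],
        }
    )


class TestAlignAlleles:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.panel = _toy_panel(rng.integers(0, 3, size=(10, 3)))
        self.ss = _toy_sumstats(self.panel, [0.1, -0.2, 0.3])

    def test_identical_coding_is_identity(self):
        aligned, report = align_alleles(self.ss, self.panel)
        np.testing.assert_allclose(aligned["beta"], self.ss["beta"])
        assert report["n_flipped"] == 0

    def test_swapped_alleles_negate_effect(self):
        ss = self.ss.copy()
        ss.loc[1, ["a1", "a2"]] = ["G", "A"]
        aligned, report = align_alleles(ss, self.panel)
        assert aligned.loc[1, "beta"] == pytest.approx(0.2)
        assert report["n_flipped"] == 1

    def test_mismatched_pair_dropped_and_counted(self):
        ss = self.ss.copy()
        ss.loc[2, ["a1", "a2"]] = ["A", "C"]
        aligned, report = align_alleles(ss, self.panel)
        assert report["n_mismatch"] == 1
        assert len(aligned) == 2

    def test_ambiguous_pair_dropped_under_flag(self):
        ss = self.ss.copy()
        ss.loc[0, ["a1", "a2"]] = ["A", "T"]
        panel = self.panel
        panel.variants.loc[0, ["a1", "a2"]] = ["A", "T"]
        aligned, report = align_alleles(ss, panel, drop_ambiguous=True)
        assert report["n_ambiguous"] == 1
        kept, report2 = align_alleles(ss, panel, drop_ambiguous=False)
        assert len(kept) == len(aligned) + 1

    def test_zero_overlap_errors(self):
        ss = self.ss.copy()
        ss["snp"] = ["x1", "x2", "x3"]
        with pytest.raises(ValueError, match="overlap"):
            align_alleles(ss, self.panel)


class TestEstimateLd:
    def test_matches_pearson_formula_oracle(self):
        dos = np.array(
            [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2], [1, 0, 1]], dtype=float
        )
        panel = _toy_panel(dos)
        ld = estimate_ld(panel)
        D = ld.blocks[0]
        for i in range(3):
            for j in range(3):
                x, z = dos[:, i], dos[:, j]
                r = np.sum((x - x.mean()) * (z - z.mean())) / (
                    np.sqrt(np.sum((x - x.mean()) ** 2))
                    * np.sqrt(np.sum((z - z.mean()) ** 2))
                )
                assert D[i, j] == pytest.approx(r, abs=1e-12)

    def test_duplicated_variant_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=(50, 1))
        panel = _toy_panel(np.hstack([col, col]))
        ld = estimate_ld(panel)
        assert ld.blocks[0][0, 1] == pytest.approx(1.0)

    def test_cross_block_independence_at_rho_zero(self):
        cfg = SimulationConfig(M=40, n_ref=4000, block_size=20, rho=0.0,
                               master_seed=2)
        panel = simulate_panel(cfg)
        X = panel.dosages.astype(float)
        r = np.corrcoef(X[:, 0], X[:, 39])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(cfg.n_ref)

    def test_zero_variance_variant_named(self):
        dos = np.array([[1, 0], [1, 1], [1, 2]])
        panel = _toy_panel(dos)
        with pytest.raises(ValueError, match="v0"):
            estimate_ld(panel)

    def test_shrinkage_moves_toward_identity(self):
        rng = np.random.default_rng(3)
        panel = _toy_panel(rng.integers(0, 3, size=(100, 4)))
        raw = estimate_ld(panel, shrinkage=0.0).blocks[0]
        shrunk = estimate_ld(panel, shrinkage=0.5).blocks[0]
        np.testing.assert_allclose(shrunk, 0.5 * raw + 0.5 * np.eye(4), atol=1e-12)


class TestLdpredInf:
    def test_identity_ld_closed_form(self):
        M, N, h2 = 100, 10_000, 0.5
        beta = np.linspace(-0.1, 0.1, 5)
        ld = LDMatrix(blocks=[np.eye(5)], block_index=np.zeros(5, dtype=int),
                      variant_ids=[f"v{i}" for i in range(5)])
        ss = pd.DataFrame({"beta": beta})
        w = ldpred_inf_weights(ss, ld, h2=h2, M=M, N=N)
        np.testing.assert_allclose(w.values, beta / (1 + M / (N * h2)), atol=1e-14)
        assert 1 / (1 + 100 / (10_000 * 0.5)) == pytest.approx(1 / 1.02)

    def test_zero_beta_gives_zero_weights(self, sim2000, ld2000):
        _, _, ss, _ = sim2000
        ss0 = ss.copy()
        ss0["beta"] = 0.0
        w = ldpred_inf_weights(ss0, ld2000, h2=0.3, M=2000, N=50_000)
        assert np.all(w.values == 0)

    def test_matches_dense_solve_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((40, 20))
        D = np.corrcoef(A, rowvar=False)
        beta = rng.standard_normal(20) * 0.02
        ld = LDMatrix(blocks=[D], block_index=np.zeros(20, dtype=int),
                      variant_ids=[f"v{i}" for i in range(20)])
        ss = pd.DataFrame({"beta": beta})
        M, N, h2 = 20, 5000, 0.4
        w = ldpred_inf_weights(ss, ld, h2=h2, M=M, N=N)
        oracle = np.linalg.solve(D + (M / (N * h2)) * np.eye(20), beta)
        np.testing.assert_allclose(w.values, oracle, atol=1e-10)


class TestLdpredGibbs:
    def test_null_beta_gives_near_zero_posterior(self):
        ld = LDMatrix(blocks=[np.eye(50)], block_index=np.zeros(50, dtype=int),
                      variant_ids=[f"v{i}" for i in range(50)])
        ss = pd.DataFrame({"beta": np.zeros(50)})
        w = ldpred_gibbs_weights(ss, ld, h2=0.3, p=0.1, M=50, N=10_000,
                                 n_iter=300, burn_in=50, seed=0)
        # posterior mean given causal has sd ~ sqrt(s2); MC SE bound
        assert np.max(np.abs(w.values)) < 5 * np.sqrt(0.3 / (50 * 0.1) / 250)

    def test_single_variant_matches_quadrature_oracle(self):
        h2, p, M, N = 0.3, 0.2, 1000, 20_000
        bhat = 0.015
        ld = LDMatrix(blocks=[np.eye(1)], block_index=np.zeros(1, dtype=int),
                      variant_ids=["v0"])
        ss = pd.DataFrame({"beta": [bhat]})
        n_kept = 4000
        w = ldpred_gibbs_weights(ss, ld, h2=h2, p=p, M=M, N=N,
                                 n_iter=n_kept + 200, burn_in=200, seed=1)

        # quadrature oracle for the 1-D point-normal posterior mean
        sigma2 = h2 / (M * p)
        grid = np.linspace(-0.2, 0.2, 400_001)
        like = norm.pdf(bhat, loc=grid, scale=np.sqrt(1 / N))
        prior = norm.pdf(grid, scale=np.sqrt(sigma2))
        slab = np.trapezoid(like * prior, grid)
        spike = (1 - p) * norm.pdf(bhat, scale=np.sqrt(1 / N))
        p_incl = p * slab / (p * slab + spike)
        mean_slab = np.trapezoid(grid * like * prior, grid) / slab
        oracle = p_incl * mean_slab

        s2 = 1 / (N + 1 / sigma2)
        mc_se = np.sqrt((p_incl * s2 + p_incl * (1 - p_incl) * mean_slab**2)
                        / n_kept)
        assert w.values[0] == pytest.approx(oracle, abs=3 * mc_se)

    def test_seed_reproducible_and_seed_robust(self, sim2000, ld2000):
        _, _, ss, _ = sim2000
        kw = dict(h2=0.3, p=0.1, M=2000, N=50_000, n_iter=200, burn_in=50)
        a = ldpred_gibbs_weights(ss, ld2000, seed=7, **kw)
        b = ldpred_gibbs_weights(ss, ld2000, seed=7, **kw)
        c = ldpred_gibbs_weights(ss, ld2000, seed=8, **kw)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.corrcoef(a.values, c.values)[0, 1] > 0.95

    def test_invalid_hyperparameters_rejected(self, sim2000, ld2000):
        _, _, ss, _ = sim2000
        with pytest.raises(ValueError):
            ldpred_gibbs_weights(ss, ld2000, h2=0.3, p=0.0, M=2000, N=50_000)
        with pytest.raises(ValueError):
            ldpred_gibbs_weights(ss, ld2000, h2=0.3, p=0.5, M=2000, N=50_000,
                                 n_iter=10, burn_in=20)


class TestScoring:
    def test_zero_weights_zero_scores(self, small_sim):
        _, panel, _, _ = small_sim
        w = WeightVector(values=np.zeros(panel.n_variants),
                         variant_ids=list(panel.variants["id"]), method="inf")
        raw, std = score_individuals(panel, w)
        assert np.all(raw == 0) and np.all(std == 0)

    def test_positive_rescaling_leaves_standardized_invariant(self, small_sim):
        _, panel, ss, _ = small_sim
        rng = np.random.default_rng(5)
        vals = rng.standard_normal(panel.n_variants) * 0.01
        w1 = WeightVector(values=vals, variant_ids=list(panel.variants["id"]),
                          method="inf")
        w2 = WeightVector(values=7.3 * vals,
                          variant_ids=list(panel.variants["id"]), method="inf")
        _, z1 = score_individuals(panel, w1)
        _, z2 = score_individuals(panel, w2)
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_hand_dot_product_oracle(self):
        dos = np.array([[0, 1, 2], [2, 0, 1]], dtype=float)
        panel = _toy_panel(dos)
        w = WeightVector(values=np.array([0.5, -1.0, 0.25]),
                         variant_ids=["v0", "v1", "v2"], method="inf")
        raw, _ = score_individuals(panel, w)
        mu, sd = dos.mean(axis=0), dos.std(axis=0)
        expected = ((dos - mu) / sd) @ np.array([0.5, -1.0, 0.25])
        np.testing.assert_allclose(raw, expected, atol=1e-12)

    def test_length_mismatch_rejected(self, small_sim):
        _, panel, _, _ = small_sim
        w = WeightVector(values=np.zeros(3), variant_ids=["a", "b", "c"],
                         method="inf")
        with pytest.raises(ValueError, match="variants"):
            score_individuals(panel, w)


class TestSelectP:
    def test_default_grid(self):
        assert DEFAULT_P_GRID == (1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3, 1.0)

    def test_single_candidate_returned(self, small_sim, rng):
        _, panel, _, _ = small_sim
        w = WeightVector(values=rng.standard_normal(panel.n_variants),
                         variant_ids=list(panel.variants["id"]),
                         method="gibbs", params={"p": 0.1})
        labels = rng.integers(0, 2, panel.n_individuals)
        best, table = select_p_by_auc([w], panel, labels)
        assert best is w and len(table) == 1

    def test_single_class_labels_rejected(self, small_sim):
        _, panel, _, _ = small_sim
        w = WeightVector(values=np.ones(panel.n_variants),
                         variant_ids=list(panel.variants["id"]), method="inf")
        with pytest.raises(ValueError, match="single class"):
            select_p_by_auc([w], panel, np.ones(panel.n_individuals))

    def test_argmax_matches_exhaustive_oracle(self, small_sim, rng):
        from polygxe.accuracy_metrics import auc as auc_fn

        _, panel, _, _ = small_sim
        cands = []
        for i, p in enumerate((0.01, 0.1, 1.0)):
            cands.append(
                WeightVector(values=rng.standard_normal(panel.n_variants),
                             variant_ids=list(panel.variants["id"]),
                             method="gibbs", params={"p": p})
            )
        labels = rng.integers(0, 2, panel.n_individuals)
        best, table = select_p_by_auc(cands, panel, labels)
        oracle = max(
            cands,
            key=lambda c: auc_fn(score_individuals(panel, c)[1], labels),
        )
        assert best is oracle


class TestResidualize:
    def test_orthogonal_covariate_is_noop_after_standardization(self, rng):
        scores = rng.standard_normal(500)
        cov = rng.standard_normal(500)
        s_c = scores - scores.mean()
        cov = cov - cov.mean()
        cov -= (cov @ s_c) / (s_c @ s_c) * s_c  # empirically uncorrelated
        adj = residualize_covariates(scores, cov)
        expected = (scores - scores.mean()) / scores.std(ddof=1)
        np.testing.assert_allclose(adj, expected, atol=1e-8)

    def test_exactly_linear_scores_residualize_to_zero(self, rng):
        cov = rng.standard_normal(100)
        scores = 3.0 + 2.0 * cov
        adj = residualize_covariates(scores, cov)
        assert np.all(adj == 0)

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.standard_normal(50)
        C = rng.standard_normal((50, 2))
        X = np.column_stack([np.ones(50), C])
        bhat = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ bhat
        expected = (resid - resid.mean()) / resid.std(ddof=1)
        np.testing.assert_allclose(residualize_covariates(y, C), expected,
                                   atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        y = rng.standard_normal(30)
        c = rng.standard_normal(30)
        with pytest.raises(ValueError, match="rank"):
            residualize_covariates(y, np.column_stack([c, c]))


class TestLdsc:
    def test_null_chi2_gives_zero_h2_unit_intercept(self, small_sim):
        _, panel, ss, _ = small_sim
        ld = estimate_ld(panel, shrinkage=0.0)
        ss0 = ss.copy()
        ss0["beta"] = ss0["se"]  # chi2 identically 1
        fit = ldsc_h2(ss0, ld, M=panel.n_variants, N=50_000, n_jackknife=5)
        assert fit.h2 == pytest.approx(0.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_doubling_n_halves_h2(self, small_sim):
        _, panel, ss, _ = small_sim
        ld = estimate_ld(panel, shrinkage=0.0)
        f1 = ldsc_h2(ss, ld, M=panel.n_variants, N=25_000, n_jackknife=5)
        f2 = ldsc_h2(ss, ld, M=panel.n_variants, N=50_000, n_jackknife=5)
        assert f2.h2 == pytest.approx(f1.h2 / 2, rel=1e-10)

    def test_too_many_jackknife_blocks_rejected(self, small_sim):
        _, panel, ss, _ = small_sim
        ld = estimate_ld(panel, shrinkage=0.0)
        with pytest.raises(ValueError, match="jackknife"):
            ldsc_h2(ss, ld, M=panel.n_variants, N=50_000, n_jackknife=500)


def test_prs_auc_monotone_in_heritability():
    """Discrimination of the standardized score rises with true h2."""
    aucs = []
    for h2 in (0.05, 0.2, 0.5):
        cfg = SimulationConfig(M=400, n_ref=800, block_size=20, h2=h2,
                               p_causal=1.0, n_case=250, n_control=250,
                               master_seed=41, batch_size=40_000,
                               n_calibration=50_000)
        panel = simulate_panel(cfg)
        ss, truth = simulate_sumstats(panel, cfg)
        cohort = simulate_cohort(cfg, panel=panel, truth=truth)
        ld = estimate_ld(panel, shrinkage=0.01)
        w = ldpred_inf_weights(ss, ld, h2=h2, M=cfg.M, N=cfg.N_gwas)
        from polygxe.accuracy_metrics import auc as auc_fn

        _, z = score_individuals(cohort.genotypes, w)
        aucs.append(auc_fn(z, cohort.data["status"]))
    assert aucs[1] > aucs[0] - 0.02
    assert aucs[2] > aucs[1] - 0.02
    assert aucs[2] > aucs[0]
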