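"""Mixed-model scan, FDR selection and allele effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from napusgwas import association, popgen, sim
from napusgwas.association import (
    allele_effects,
    fdr_select,
    fit_null,
    genomic_inflation,
    scan,
)
from napusgwas.genotypes import GenotypeMatrix


def _random_psd(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n * 2))
    K = A @ A.T / (n * 2)
    return K


class TestFitNull:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(0)
        n = 40
        Q = rng.normal(size=(n, 2))
        y = 1.0 + Q @ [0.5, -0.3] + rng.normal(size=n)
        fit = fit_null(y, Q, np.eye(n))
        X = np.column_stack([np.ones(n), Q])
        beta_ols, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2_ols = res[0] / (n - 3)
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-6)
        assert fit.sigma2_g + fit.sigma2_e == pytest.approx(sigma2_ols, rel=1e-6)

    def test_reml_maximum_beats_grid_oracle(self):
        rng = np.random.default_rng(1)
        n = 20
        K = _random_psd(n, 2)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        y = L @ rng.normal(size=n) + 0.5 * rng.normal(size=n)
        fit = fit_null(y, None, K)
        X = np.ones((n, 1))
        Qf, _ = np.linalg.qr(X, mode="complete")
        T = Qf[:, 1:].T
        lam, V = np.linalg.eigh(T @ K @ T.T)
        eta2 = (V.T @ (T @ y)) ** 2

        def neg2ll(delta):
            w = np.clip(lam, 0, None) + delta
            return (n - 1) * np.log(np.sum(eta2 / w) / (n - 1)) + np.sum(np.log(w))

        grid = 10.0 ** np.linspace(-5, 5, 1000)
        best_grid = min(neg2ll(d) for d in grid)
        assert -2.0 * fit.loglik <= best_grid + 1e-6

    def test_zero_variance_phenotype_rejected(self):
        with pytest.raises(ValueError):
            fit_null(np.ones(10), None, np.eye(10))

    def test_collinear_q_rejected(self):
        rng = np.random.default_rng(3)
        n = 15
        q1 = rng.normal(size=n)
        Q = np.column_stack([q1, 2 * q1])
        with pytest.raises(ValueError, match="singular|collinear"):
            fit_null(rng.normal(size=n), Q, np.eye(n))


class TestScan:
    def test_collapses_to_ols_with_identity_kinship(self):
        rng = np.random.default_rng(4)
        n, m = 60, 100
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(np.int8)
        G = GenotypeMatrix(dos)
        y = rng.normal(size=n) + 0.4 * G.imputed()[:, 0]
        res = scan(G, y, Q=None, K=np.eye(n))
        for j in range(0, m, 7):
            g = G.imputed()[:, j]
            if np.std(g) == 0:
                continue
            flip = g.mean() / 2 > 0.5
            lr = stats.linregress(2 - g if flip else g, y)
            assert res["p_value"].iloc[j] == pytest.approx(lr.pvalue, abs=1e-8)

    def test_contribution_matches_ols_partial_r2(self):
        rng = np.random.default_rng(5)
        n, m = 80, 20
        dos = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
        G = GenotypeMatrix(dos)
        y = rng.normal(size=n)
        res = scan(G, y, Q=None, K=np.eye(n))
        for j in range(m):
            g = G.imputed()[:, j]
            gc = g - g.mean()
            yc = y - y.mean()
            partial_r2 = (gc @ yc) ** 2 / ((gc @ gc) * (yc @ yc))
            assert res["contrib_pct"].iloc[j] == pytest.approx(100 * partial_r2, abs=1e-8)

    def test_contribution_bounded(self, qc_panel, panel_phenotype):
        G, mm = qc_panel
        y, _, _ = panel_phenotype
        res = scan(G, y, K=popgen.compute_kinship(G).to_numpy())
        assert ((res["contrib_pct"] >= 0) & (res["contrib_pct"] <= 100)).all()

    def test_monomorphic_marker_flagged_p_one(self):
        rng = np.random.default_rng(6)
        dos = rng.binomial(2, 0.3, size=(30, 5)).astype(np.int8)
        dos[:, 2] = 1
        G = GenotypeMatrix(dos)
        res = scan(G, rng.normal(size=30), K=np.eye(30))
        assert res["degenerate"].iloc[2]
        assert res["p_value"].iloc[2] == 1.0
        assert len(res) == 5  # m preserved for the FDR step

    def test_p_values_invariant_to_affine_phenotype_rescale(self, qc_panel, panel_phenotype):
        G, mm = qc_panel
        y, _, _ = panel_phenotype
        K = popgen.compute_kinship(G).to_numpy()
        r1 = scan(G, y, K=K)
        r2 = scan(G, 3.0 * y + 7.0, K=K)
        np.testing.assert_allclose(r1["p_value"], r2["p_value"], rtol=1e-6)
        np.testing.assert_allclose(3.0 * r1["beta"], r2["beta"], rtol=1e-5, atol=1e-8)

    def test_planted_qtl_is_top_hit(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = sim.SimConfig(
                n_samples=500, chromosomes=(("A01", 300, 4_000_000),),
                n_subpops=1, fst=0.0, ld_rho=0.3, missing_rate=0.0, seed=seed,
            )
            res = sim.simulate_genotypes(cfg)
            G = res.genotypes
            g = G.imputed()[:, 150]
            rng = np.random.default_rng(1000 + seed)
            # effect sized for ~15% of phenotypic variance
            var_g = np.var(g)
            beta = np.sqrt(0.15 / 0.85 / var_g)
            y = beta * g + rng.normal(size=500)
            out = scan(G, y, K=popgen.compute_kinship(G).to_numpy())
            if int(out["p_value"].idxmin()) == 150:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_exact_mode_agrees_with_p3d_on_small_panel(self):
        rng = np.random.default_rng(8)
        n, m = 40, 12
        dos = rng.binomial(2, 0.35, size=(n, m)).astype(np.int8)
        G = GenotypeMatrix(dos)
        K = _random_psd(n, 9)
        y = rng.normal(size=n)
        p3d = scan(G, y, K=K, mode="p3d")
        exact = scan(G, y, K=K, mode="exact")
        # EMMAX is an approximation; on a null panel the two agree closely
        np.testing.assert_allclose(p3d["p_value"], exact["p_value"], rtol=0.2)


class TestQKCorrection:
    def test_structure_confound_inflates_ols_not_mlm(self):
        cfg = sim.SimConfig(
            n_samples=300, chromosomes=(("A01", 800, 8_000_000),),
            n_subpops=2, fst=0.15, ld_rho=0.3, missing_rate=0.0, seed=17,
        )
        res = sim.simulate_genotypes(cfg)
        G = res.genotypes
        rng = np.random.default_rng(99)
        y = 1.0 * (res.subpops == 1) + rng.normal(size=300)  # confounded phenotype
        naive = scan(G, y, Q=None, K=np.eye(300))
        K = popgen.compute_kinship(G).to_numpy()
        Q = popgen.structure_pca(G, k=2, seed=0).to_numpy()
        qk = scan(G, y, Q=Q, K=K)
        lam_naive = genomic_inflation(naive["p_value"])
        lam_qk = genomic_inflation(qk["p_value"])
        assert lam_naive > lam_qk
        assert 0.8 <= lam_qk <= 1.2


class TestFDRSelect:
    def test_hand_worked_step_up(self):
        sel = fdr_select([1e-6, 1e-4, 0.02, 0.5], q=0.01)
        assert sel.n_selected == 2
        assert sel.p_threshold == pytest.approx(1e-4)
        assert sel.achieved_fdr_pct == pytest.approx(0.02)

    def test_all_above_q_selects_nothing(self):
        sel = fdr_select([0.02, 0.5, 0.9], q=0.01)
        assert sel.n_selected == 0 and sel.p_threshold is None

    def test_matches_benjamini_hochberg_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            m = rng.integers(5, 400)
            p = rng.uniform(1e-12, 1.0, size=m)
            if rng.random() < 0.5:
                p[: m // 4] *= 1e-6  # plant some signal
            sel = fdr_select(p, q=0.05)
            reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert sel.n_selected == reject.sum()
            assert set(sel.selected_ids) == set(np.flatnonzero(reject))

    def test_selected_set_satisfies_fdr_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.uniform(1e-10, 1.0, size=int(rng.integers(3, 200)))
            sel = fdr_select(p, q=0.01)
            if sel.n_selected:
                assert sel.m * sel.p_threshold / sel.n_selected <= 0.01 + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_select([])


class TestAlleleEffects:
    def test_equal_means_zero_reduction(self):
        g = np.array([0, 0, 2, 2, 1, 1])
        y = np.array([3.0, 3.0, 3.0, 3.0, 5.0, 5.0])
        assert allele_effects(g, y)["pct_reduction"] == pytest.approx(0.0)

    def test_fifty_percent_reduction(self):
        g = np.array([0, 0, 0, 2, 2, 2])
        y = np.array([4.0, 4.0, 4.0, 2.0, 2.0, 2.0])
        out = allele_effects(g, y)
        assert out["pct_reduction"] == pytest.approx(50.0)
        assert out["class_means"][0] == 4.0 and out["class_means"][2] == 2.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            allele_effects(np.ones(6), np.arange(6.0))

    def test_empty_homozygote_class_reports_counts(self):
        g = np.array([0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="class"):
            allele_effects(g, np.arange(6.0))
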