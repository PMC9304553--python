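"""Point-normal Gibbs sampler, LD-score h² anchor, and the hyperparameter grid."""

import numpy as np
import pandas as pd
import pytest

import sexprs as sx
from sexprs.exceptions import DegenerateInputError, DomainError
from sexprs.gwas import SummaryStats

from conftest import identity_ld


def make_stats(beta_hat, n, stratum="F", se=None):
    m = len(beta_hat)
    variants = pd.DataFrame(
        {"variant_id": [f"rs{i+1}" for i in range(m)], "chrom": 1,
         "pos": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "G",
         "maf": np.full(m, 0.25), "block_id": np.zeros(m, int)})
    se = np.full(m, 1 / np.sqrt(n)) if se is None else np.asarray(se, float)
    return SummaryStats(variants=variants, beta_hat=np.asarray(beta_hat, float),
                        se=se, pval=np.full(m, 0.5), n=n, stratum=stratum)


def random_block_instance(m, n, rng):
    """Random correlated instance for the ridge oracle."""
    X = rng.standard_normal((4 * m, m)) @ np.linalg.cholesky(
        0.5 * np.eye(m) + 0.5 * np.exp(-np.abs(np.subtract.outer(np.arange(m), np.arange(m))) / 5.0))
    R = np.corrcoef(X, rowvar=False)
    R = (R + 0.02 * np.eye(m)) / 1.02
    np.fill_diagonal(R, 1.0)
    beta = rng.standard_normal(m) * 0.05
    bh = R @ beta + rng.standard_normal(m) / np.sqrt(n)
    return R, bh


class TestH2LDScore:
    def test_recovers_h2_without_ld(self):
        # theoretical oracle: E[chi2] = 1 + n*l*h2/M under the polygenic model
        sizes = {("F", "train"): 6000, ("F", "reference"): 1000}
        panel = sx.simulate_genotype_panel(m_variants=3000, block_size=50, rho=0.0,
                                           cohort_sizes=sizes, seed=31)
        cs = sx.sample_causal_sets(3000, 0.01, 1.0, seed=31)
        arch = sx.draw_effect_sizes(cs, 0.3, 0.3, 1.0, seed=31)
        ph = sx.simulate_phenotypes(panel, arch, seed=31)
        st = sx.run_gwas(panel, ph, "F")
        ld = sx.estimate_ld(panel)
        assert sx.estimate_h2_ldscore(st, ld) == pytest.approx(0.3, abs=0.05)

    def test_null_summary_stats_give_near_zero(self):
        ests = []
        sizes = {("F", "train"): 1000, ("F", "reference"): 500}
        for seed in range(10):
            panel = sx.simulate_genotype_panel(m_variants=500, block_size=25, rho=0.6,
                                               cohort_sizes=sizes, seed=seed)
            cs = sx.sample_causal_sets(500, 0.02, 1.0, seed=seed)
            arch = sx.draw_effect_sizes(cs, 0.0, 0.0, 1.0, seed=seed)
            ph = sx.simulate_phenotypes(panel, arch, seed=seed)
            st = sx.run_gwas(panel, ph, "F")
            ests.append(sx.estimate_h2_ldscore(st, sx.estimate_ld(panel)))
        assert np.mean(ests) <= 0.02

    def test_clamped_to_one(self):
        # chi2 so large the implied slope exceeds 1
        st = make_stats(np.full(100, 0.9), n=10000)
        assert sx.estimate_h2_ldscore(st, identity_ld(100)) == 1.0

    def test_free_intercept_requires_ld_score_variation(self, pipeline):
        with pytest.raises(DegenerateInputError):
            sx.estimate_h2_ldscore(make_stats(np.zeros(50), 1000), identity_ld(50),
                                   intercept="free")
        est = sx.estimate_h2_ldscore(pipeline["stats"]["F"], pipeline["ld"],
                                     intercept="free")
        assert 0.001 <= est <= 1.0


class TestGibbsPointNormal:
    def test_infinitesimal_no_ld_closed_form(self):
        # p=1, identity LD: weights = beta_hat * n*sigma2/(n*sigma2 + 1)
        n, m, h2 = 5000, 60, 0.4
        rng = np.random.default_rng(0)
        bh = rng.standard_normal(m) * 0.1
        st = make_stats(bh, n)
        wv = sx.gibbs_pointnormal(st, identity_ld(m, 20), p=1.0, h2=h2,
                                  n_iter=300, burn_in=50, seed=1)
        sigma2 = h2 / m
        expect = bh * n * sigma2 / (n * sigma2 + 1)
        assert np.max(np.abs(wv.weights - expect)) < 1e-3

    def test_matches_ridge_oracle_on_random_blocks(self):
        # p=1 posterior mean equals the ridge solution
        # (R + M/(n*h2) I)^-1 beta_hat; brute-force linear solve oracle
        rng = np.random.default_rng(42)
        n, m, h2 = 20000, 50, 0.5
        for trial in range(10):
            R, bh = random_block_instance(m, n, rng)
            st = make_stats(bh, n)
            ld = sx.LDBlockMatrix(blocks=[((0, m), R)], source_n=n, ridge_eps=0.02)
            wv = sx.gibbs_pointnormal(st, ld, p=1.0, h2=h2, n_iter=2000,
                                      burn_in=500, seed=trial)
            oracle = np.linalg.solve(R + m / (n * h2) * np.eye(m), bh)
            assert np.max(np.abs(wv.weights - oracle)) < 5e-3

    def test_null_stats_fully_shrunk_at_small_p(self):
        st = make_stats(np.zeros(100), n=10000)
        wv = sx.gibbs_pointnormal(st, identity_ld(100), p=1e-4, h2=0.1,
                                  n_iter=300, burn_in=50, seed=2)
        assert np.max(np.abs(wv.weights)) < 1e-4

    def test_sparse_mode_produces_exact_zeros(self, pipeline):
        st, ld = pipeline["stats"]["F"], pipeline["ld"]
        dense = sx.gibbs_pointnormal(st, ld, p=0.01, h2=0.3, sparse=False,
                                     n_iter=200, burn_in=50, seed=3)
        sparse = sx.gibbs_pointnormal(st, ld, p=0.01, h2=0.3, sparse=True,
                                      n_iter=200, burn_in=50, seed=3)
        assert np.sum(sparse.weights == 0) >= np.sum(dense.weights == 0)
        assert np.sum(sparse.weights == 0) > 0

    def test_unusable_variants_get_zero_weight(self):
        se = np.full(30, 0.01)
        se[5] = np.inf
        st = make_stats(np.full(30, 0.05), n=10000, se=se)
        wv = sx.gibbs_pointnormal(st, identity_ld(30), p=1.0, h2=0.3,
                                  n_iter=200, burn_in=50, seed=4)
        assert wv.weights[5] == 0.0

    def test_monotone_shrinkage(self, pipeline):
        # mean |weight| grows with polygenicity p (more variants admitted to
        # the slab), and, at p=1 where inclusion plays no role, with h2
        # (weaker shrinkage of every effect)
        st, ld = pipeline["stats"]["ALL"], pipeline["ld"]
        mean_abs_p = []
        for p in [1e-3, 1e-2, 1e-1, 1.0]:
            wv = sx.gibbs_pointnormal(st, ld, p=p, h2=0.3, n_iter=200, burn_in=50, seed=5)
            mean_abs_p.append(np.mean(np.abs(wv.weights)))
        mean_abs_h2 = []
        for h2 in [0.1, 0.2, 0.4]:
            wv = sx.gibbs_pointnormal(st, ld, p=1.0, h2=h2, n_iter=200, burn_in=50, seed=5)
            mean_abs_h2.append(np.mean(np.abs(wv.weights)))
        viol = sum(a > b * 1.001 for a, b in zip(mean_abs_p[:-1], mean_abs_p[1:]))
        viol += sum(a > b * 1.001 for a, b in zip(mean_abs_h2[:-1], mean_abs_h2[1:]))
        assert viol <= 1  # one grid-adjacent Monte-Carlo violation allowed

    def test_domain_errors(self, pipeline):
        st, ld = pipeline["stats"]["F"], pipeline["ld"]
        with pytest.raises(DomainError):
            sx.gibbs_pointnormal(st, ld, p=0.0, h2=0.3)
        with pytest.raises(DomainError):
            sx.gibbs_pointnormal(st, ld, p=0.5, h2=1.5)
        with pytest.raises(DomainError):
            sx.gibbs_pointnormal(st, ld, p=0.5, h2=0.3, n_iter=50, burn_in=50)


class TestGrid:
    def test_default_grid_has_102_distinct_cells(self, pipeline):
        st, ld = pipeline["stats"]["F"], pipeline["ld"]
        grid = sx.HyperGridPN(h2_anchor=0.3)
        assert len(grid) == 102
        wvs = sx.fit_grid_pn(st, ld, grid=grid, n_iter=60, burn_in=20, seed=6)
        tags = {(w.hyperparams["p"], w.hyperparams["h2"], w.hyperparams["sparse"])
                for w in wvs}
        assert len(wvs) == 102 and len(tags) == 102

    def test_single_cell_grid(self, pipeline):
        st, ld = pipeline["stats"]["F"], pipeline["ld"]
        grid = sx.HyperGridPN(h2_anchor=0.3, p_values=np.array([0.1]),
                              h2_multipliers=(1.0,), sparse_options=(False,))
        wvs = sx.fit_grid_pn(st, ld, grid=grid, n_iter=60, burn_in=20, seed=6)
        assert len(wvs) == 1

    def test_grid_determinism(self, pipeline):
        st, ld = pipeline["stats"]["F"], pipeline["ld"]
        grid = sx.HyperGridPN(h2_anchor=0.3, p_values=np.array([0.01, 1.0]),
                              h2_multipliers=(1.0,), sparse_options=(False, True))
        a = sx.fit_grid_pn(st, ld, grid=grid, n_iter=60, burn_in=20, seed=7)
        b = sx.fit_grid_pn(st, ld, grid=grid, n_iter=60, burn_in=20, seed=7)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.weights, wb.weights)

    def test_h2_cells_clamped(self):
        grid = sx.HyperGridPN(h2_anchor=0.9)
        h2s = {h2 for _, h2, _, _ in grid.cells()}
        assert max(h2s) == 1.0


class TestWeightIO:
    def test_round_trip(self, pipeline, tmp_path):
        st, ld = pipeline["stats"]["F"], pipeline["ld"]
        wv = sx.gibbs_pointnormal(st, ld, p=0.1, h2=0.3, n_iter=60, burn_in=20, seed=8)
        path = tmp_path / "weights.tsv"
        sx.write_weights(wv, path)
        back = sx.read_weights(path)
        assert np.allclose(back.weights, wv.weights, atol=1e-9)
        assert back.method == "pointnormal"
        assert list(back.variant_id) == list(wv.variant_id)
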