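"""Scoring, validation tuning, linear combination, and the 11-PRS panel."""

import numpy as np
import pytest

import sexprs as sx
from sexprs.evaluate import PRSBuildConfig, _pairwise_r2
from sexprs.exceptions import AlignmentError, ConfigurationError
from sexprs.pointnormal import WeightVector


def wv_from(panel, weights, method="manual"):
    return WeightVector(weights=np.asarray(weights, float),
                        variant_id=panel.variants["variant_id"].to_numpy(),
                        a1=panel.variants["a1"].to_numpy(),
                        method=method, stratum_source="ALL", hyperparams={}, seed=0)


class TestScore:
    def test_zero_weights_zero_scores(self, pipeline):
        panel = pipeline["panel"]
        prof = sx.score(panel, wv_from(panel, np.zeros(panel.n_variants)), "test")
        assert np.all(prof.scores == 0)

    def test_true_weights_reach_heritability_without_ld(self, noldpanel):
        # scoring with the true effects bounds R^2 near h2 = 0.3
        panel, arch, pheno = noldpanel["panel"], noldpanel["arch"], noldpanel["pheno"]
        prof = sx.score(panel, wv_from(panel, arch.beta_f), "test")
        r2 = sx.evaluate_r2(prof, pheno, sex="F")
        assert r2 == pytest.approx(0.3, abs=0.08)

    def test_allele_flip_invariance(self, pipeline):
        panel = pipeline["panel"]
        rng = np.random.default_rng(1)
        w = rng.standard_normal(panel.n_variants) * 0.01
        direct = sx.score(panel, wv_from(panel, w), "test")
        flipped_wv = WeightVector(
            weights=-w,
            variant_id=panel.variants["variant_id"].to_numpy(),
            a1=panel.variants["a2"].to_numpy(),  # other allele, negated weight
            method="manual", stratum_source="ALL", hyperparams={}, seed=0)
        flipped = sx.score(panel, flipped_wv, "test")
        assert np.allclose(direct.scores, flipped.scores)

    def test_unresolvable_alleles_rejected(self, pipeline):
        panel = pipeline["panel"]
        bad = WeightVector(weights=np.ones(panel.n_variants),
                           variant_id=panel.variants["variant_id"].to_numpy(),
                           a1=np.array(["T"] * panel.n_variants),
                           method="manual", stratum_source="ALL", hyperparams={}, seed=0)
        with pytest.raises(AlignmentError):
            sx.score(panel, bad, "test")


class TestSelectBest:
    def test_single_candidate_returned(self, pipeline):
        panel, pheno = pipeline["panel"], pipeline["pheno"]
        only = wv_from(panel, pipeline["arch"].beta_f)
        assert sx.select_best([only], panel, pheno, sex="F") is only

    def test_true_effects_dominate_null_candidates(self, pipeline):
        panel, pheno, arch = pipeline["panel"], pipeline["pheno"], pipeline["arch"]
        rng = np.random.default_rng(2)
        truth = wv_from(panel, arch.beta_f)
        nulls = [wv_from(panel, rng.standard_normal(panel.n_variants) * 1e-4)
                 for _ in range(3)]
        assert sx.select_best(nulls + [truth], panel, pheno, sex="F") is truth

    def test_tie_breaks_to_first(self, pipeline):
        panel, pheno, arch = pipeline["panel"], pipeline["pheno"], pipeline["arch"]
        a = wv_from(panel, arch.beta_f)
        b = wv_from(panel, arch.beta_f.copy())
        assert sx.select_best([a, b], panel, pheno, sex="F") is a

    def test_empty_candidates_rejected(self, pipeline):
        with pytest.raises(ConfigurationError):
            sx.select_best([], pipeline["panel"], pipeline["pheno"], sex="F")


class TestFitCombination:
    def test_noise_profile_gets_negligible_weight(self, pipeline):
        panel, pheno, arch = pipeline["panel"], pipeline["pheno"], pipeline["arch"]
        prs_f = sx.score(panel, wv_from(panel, arch.beta_f), "validation")
        rng = np.random.default_rng(3)
        noise = sx.score(panel, wv_from(panel, np.zeros(panel.n_variants)), "validation")
        noise.scores = rng.standard_normal(noise.scores.size)
        fit = sx.fit_combination(prs_f, noise, pheno, sex="F")
        solo = sx.fit_combination(prs_f, prs_f, pheno, sex="F")  # collinear fallback
        assert abs(fit.validation_r2 - solo.validation_r2) < 0.01

    def test_perfect_profile_recovers_scale(self, pipeline):
        panel, pheno = pipeline["panel"], pipeline["pheno"]
        rows = np.flatnonzero(panel.mask(cohort="validation"))
        prs_f = sx.score(panel, wv_from(panel, np.zeros(panel.n_variants)), "validation")
        prs_f.scores = 0.5 * np.asarray(pheno.values)[rows]
        rng = np.random.default_rng(4)
        prs_m = sx.score(panel, wv_from(panel, np.zeros(panel.n_variants)), "validation")
        prs_m.scores = rng.standard_normal(rows.size)
        fit = sx.fit_combination(prs_f, prs_m, pheno, sex="F")
        assert fit.validation_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.w_f == pytest.approx(2.0, abs=1e-6)

    def test_combination_dominates_components(self, pipeline):
        # OLS projection property: combined validation R^2 >= each component's
        panel, pheno, arch = pipeline["panel"], pipeline["pheno"], pipeline["arch"]
        prs_f = sx.score(panel, wv_from(panel, arch.beta_f), "validation")
        prs_m = sx.score(panel, wv_from(panel, arch.beta_m), "validation")
        for sex in ("F", "M"):
            fit = sx.fit_combination(prs_f, prs_m, pheno, sex=sex)
            rows = np.flatnonzero(panel.mask(cohort="validation"))
            sub = panel.sex[rows] == sex
            y = np.asarray(pheno.values)[rows][sub]
            for prof in (prs_f, prs_m):
                r2 = float(np.corrcoef(prof.scores[sub], y)[0, 1] ** 2)
                assert fit.validation_r2 >= r2 - 1e-12

    def test_collinear_profiles_fall_back(self, pipeline, caplog):
        panel, pheno, arch = pipeline["panel"], pipeline["pheno"], pipeline["arch"]
        prs_f = sx.score(panel, wv_from(panel, arch.beta_f), "validation")
        prs_m = sx.score(panel, wv_from(panel, arch.beta_f * 2.0), "validation")
        fit = sx.fit_combination(prs_f, prs_m, pheno, sex="F")
        assert fit.w_m == 0.0


class TestPairwiseR2:
    def test_matches_per_pair_lstsq_oracle(self):
        rng = np.random.default_rng(9)
        n, kf, km = 400, 5, 4
        Sf = rng.standard_normal((n, kf))
        Sm = rng.standard_normal((n, km))
        y = Sf[:, 0] * 0.5 + Sm[:, 1] * 0.3 + rng.standard_normal(n)
        r2, wf, wm = _pairwise_r2(Sf, Sm, y)
        for i in range(kf):
            for j in range(km):
                X = np.column_stack([np.ones(n), Sf[:, i], Sm[:, j]])
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                fit = X @ coef
                oracle = np.corrcoef(fit, y)[0, 1] ** 2
                assert r2[i, j] == pytest.approx(oracle, abs=1e-10)
                assert wf[i, j] == pytest.approx(coef[1], abs=1e-8)


class TestEvaluateR2:
    def test_perfect_and_sign_flipped_scores(self, pipeline):
        panel, pheno = pipeline["panel"], pipeline["pheno"]
        prof = sx.score(panel, wv_from(panel, np.zeros(panel.n_variants)), "test")
        y = np.asarray(pheno.values)[prof.rows]
        prof.scores = y.copy()
        assert sx.evaluate_r2(prof, pheno) == pytest.approx(1.0)
        prof.scores = -y
        assert sx.evaluate_r2(prof, pheno) == pytest.approx(1.0)

    def test_independent_score_near_zero(self, pipeline):
        panel, pheno = pipeline["panel"], pipeline["pheno"]
        prof = sx.score(panel, wv_from(panel, np.zeros(panel.n_variants)), "test")
        rng = np.random.default_rng(11)
        prof.scores = rng.standard_normal(prof.scores.size)
        assert sx.evaluate_r2(prof, pheno, sex="F") < 0.02

    def test_zero_variance_score_warns_and_returns_zero(self, pipeline):
        panel, pheno = pipeline["panel"], pipeline["pheno"]
        prof = sx.score(panel, wv_from(panel, np.zeros(panel.n_variants)), "test")
        with pytest.warns(UserWarning):
            assert sx.evaluate_r2(prof, pheno, sex="F") == 0.0


@pytest.fixture(scope="module")
def built(pipeline):
    cfg = PRSBuildConfig(n_iter=150, burn_in=50, seed=13)
    return sx.build_all_prs(pipeline["panel"], pipeline["stats"]["F"],
                            pipeline["stats"]["M"], pipeline["stats"]["ALL"],
                            pipeline["ld"], pipeline["pheno"], cfg)


class TestBuildAllPRS:
    def test_full_inputs_yield_exactly_eleven_prs(self, built):
        assert set(built) == set(sx.PRS_NAMES)
        assert len(built) == 11
        for name, per_sex in built.items():
            assert set(per_sex) == {"F", "M"}

    def test_missing_stratum_degrades_gracefully(self, pipeline):
        cfg = PRSBuildConfig(n_iter=60, burn_in=20, seed=13)
        out = sx.build_all_prs(pipeline["panel"], pipeline["stats"]["F"], None,
                               pipeline["stats"]["ALL"], pipeline["ld"],
                               pipeline["pheno"], cfg)
        assert set(out) == {"PRScs-f", "LDpred2-f", "PRScs-all", "LDpred2-all"}

    def test_determinism(self, pipeline, built):
        cfg = PRSBuildConfig(n_iter=150, burn_in=50, seed=13)
        again = sx.build_all_prs(pipeline["panel"], pipeline["stats"]["F"],
                                 pipeline["stats"]["M"], pipeline["stats"]["ALL"],
                                 pipeline["ld"], pipeline["pheno"], cfg)
        for name in built:
            for sex in ("F", "M"):
                assert np.array_equal(built[name][sex]["scores"],
                                      again[name][sex]["scores"])

    def test_greedy_search_mode_runs(self, pipeline):
        cfg = PRSBuildConfig(n_iter=60, burn_in=20, seed=13, mult_search="greedy")
        out = sx.build_all_prs(pipeline["panel"], pipeline["stats"]["F"],
                               pipeline["stats"]["M"], pipeline["stats"]["ALL"],
                               pipeline["ld"], pipeline["pheno"], cfg)
        assert set(out) == set(sx.PRS_NAMES)
        sel = out["LDpred2-mult"]["F"]["selected"]
        assert {"f", "m", "w_f", "w_m"} <= set(sel)
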