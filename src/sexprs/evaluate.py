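"""Scoring, validation tuning, score combination, and the 11-PRS panel.

The tuning protocol mirrors standard PRS practice: every candidate weight
vector from a method's hyperparameter grid is scored on the *validation*
cohort, restricted to individuals of the sex being predicted, and the
candidate with the highest squared correlation with the phenotype wins.
Combined sex-specific scores ("-mult") regress the validation phenotype on
the female- and male-derived scores jointly; by default the component
hyperparameters and the combination weights are searched simultaneously over
all grid-cell pairs.  Test phenotypes enter only through ``evaluate_r2``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cs import DEFAULT_PHI_GRID, fit_grid_cs
from .exceptions import AlignmentError, ConfigurationError
from .gwas import SummaryStats
from .panel import GenotypePanel, LDBlockMatrix, column_moments, standardized_matmat, standardized_matvec
from .pointnormal import HyperGridPN, WeightVector, estimate_h2_ldscore, fit_grid_pn

logger = logging.getLogger(__name__)

PRS_NAMES = (
    "PRScs-f", "PRScs-m", "PRScs-all", "PRScs-mult",
    "LDpred2-f", "LDpred2-m", "LDpred2-all", "LDpred2-mult",
    "PRScsx-f", "PRScsx-m", "PRScsx-mult",
)


@dataclass
class PRSProfile:
    """Per-individual scores for one cohort, with weight provenance.

    ``rows`` are the panel row indices of the scored individuals, in panel
    order, so profiles can be matched back to phenotypes.
    """

    scores: np.ndarray
    weight_provenance: WeightVector | None
    cohort: str
    sex: np.ndarray | None = None
    rows: np.ndarray | None = None


@dataclass
class CombinationFit:
    """Validated linear combination of a female- and a male-derived score."""

    intercept: float
    w_f: float
    w_m: float
    validation_r2: float


def _aligned_signed_weights(panel: GenotypePanel, weights: WeightVector) -> np.ndarray:
    """Map weight entries onto panel variant order, flipping sign on a1/a2 swap."""
    v = panel.variants
    pos = pd.Index(v["variant_id"])
    idx = pos.get_indexer(weights.variant_id)
    if np.any(idx < 0):
        missing = np.asarray(weights.variant_id)[idx < 0][:5]
        raise AlignmentError(f"weight variants absent from panel: {missing.tolist()}")
    a1 = v["a1"].to_numpy()[idx]
    a2 = v["a2"].to_numpy()[idx]
    sign = np.where(weights.a1 == a1, 1.0, np.where(weights.a1 == a2, -1.0, np.nan))
    if np.any(np.isnan(sign)):
        bad = np.asarray(weights.variant_id)[np.isnan(sign)][:5]
        raise AlignmentError(f"unresolvable allele orientation for: {bad.tolist()}")
    out = np.zeros(panel.n_variants)
    out[idx] = weights.weights * sign
    return out


def score(panel: GenotypePanel, weights: WeightVector, cohort: str = "test") -> PRSProfile:
    """PRS = sum over variants of standardized dosage times weight.

    Dosages are standardized with the scored cohort's own per-variant mean and
    SD; weights whose effect allele matches the panel's other allele are
    sign-flipped.
    """
    rows = np.flatnonzero(panel.mask(cohort=cohort))
    if rows.size == 0:
        raise ConfigurationError(f"cohort '{cohort}' is empty")
    w = _aligned_signed_weights(panel, weights)
    mean, sd = column_moments(panel.dosages, rows)
    s = standardized_matvec(panel.dosages, w, rows, mean, sd)
    return PRSProfile(scores=s, weight_provenance=weights, cohort=cohort,
                      sex=panel.sex[rows], rows=rows)


def _score_matrix(panel: GenotypePanel, candidates: list, cohort: str) -> np.ndarray:
    """Scores of many candidates at once: (n_cohort, n_candidates)."""
    rows = np.flatnonzero(panel.mask(cohort=cohort))
    W = np.column_stack([_aligned_signed_weights(panel, wv) for wv in candidates])
    mean, sd = column_moments(panel.dosages, rows)
    return standardized_matmat(panel.dosages, W, rows, mean, sd)


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def evaluate_r2(prs: PRSProfile, pheno, sex: str | None = None) -> float:
    """Squared Pearson correlation of score and phenotype on a sex-filtered cohort.

    Zero-variance scores return 0.0 with a warning (convention).
    """
    if prs.rows is None or prs.sex is None:
        raise ConfigurationError("PRSProfile lacks row/sex bookkeeping; build it with score()")
    mask = np.ones(prs.scores.size, dtype=bool) if sex is None else prs.sex == sex
    y = np.asarray(pheno.values)[prs.rows][mask]
    x = prs.scores[mask]
    if np.std(x) == 0:
        warnings.warn("zero-variance PRS; returning R^2 = 0", stacklevel=2)
        return 0.0
    return _r2(x, y)


def select_best(candidates: list, panel: GenotypePanel, pheno, sex: str,
                cohort: str = "validation") -> WeightVector:
    """Best candidate by squared correlation on the sex-filtered validation cohort.

    Ties break to the first candidate in grid order.
    """
    if not candidates:
        raise ConfigurationError("no candidates to select from")
    rows = np.flatnonzero(panel.mask(cohort=cohort, sex=sex))
    if rows.size == 0:
        raise ConfigurationError(f"no {sex} individuals in cohort '{cohort}'")
    S = _score_matrix(panel, candidates, cohort)
    sub = panel.sex[np.flatnonzero(panel.mask(cohort=cohort))] == sex
    y = np.asarray(pheno.values)[rows]
    r2s = np.array([_r2(S[sub, k], y) for k in range(S.shape[1])])
    return candidates[int(np.argmax(r2s))]


def fit_combination(prs_f: PRSProfile, prs_m: PRSProfile, pheno,
                    sex: str | None = None) -> CombinationFit:
    """OLS of the validation phenotype on (1, score_f, score_m), sex-filtered.

    Weights are unconstrained in sign.  Near-collinear profiles fall back to a
    single-profile fit (the female-derived one), logged.
    """
    if prs_f.cohort != prs_m.cohort or not np.array_equal(prs_f.rows, prs_m.rows):
        raise ConfigurationError("profiles must cover the same individuals")
    sub = np.ones(prs_f.scores.size, dtype=bool) if sex is None else prs_f.sex == sex
    y = np.asarray(pheno.values)[prs_f.rows][sub]
    f = prs_f.scores[sub]
    m = prs_m.scores[sub]
    if np.std(f) > 0 and np.std(m) > 0 and abs(np.corrcoef(f, m)[0, 1]) > 1 - 1e-10:
        logger.warning("collinear sex-specific profiles; falling back to single-profile fit")
        X = np.column_stack([np.ones_like(f), f])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        fit = X @ coef
        return CombinationFit(intercept=float(coef[0]), w_f=float(coef[1]), w_m=0.0,
                              validation_r2=_r2(fit, y))
    X = np.column_stack([np.ones_like(f), f, m])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = X @ coef
    return CombinationFit(intercept=float(coef[0]), w_f=float(coef[1]), w_m=float(coef[2]),
                          validation_r2=_r2(fit, y))


def _pairwise_r2(Sf: np.ndarray, Sm: np.ndarray, y: np.ndarray):
    """Validation R^2 of the two-predictor OLS for every (f-cell, m-cell) pair.

    Closed form from centered cross-products; returns (R2 matrix, w_f, w_m).
    Degenerate pairs (singular normal equations) fall back to the better
    single predictor.
    """
    yc = y - y.mean()
    F = Sf - Sf.mean(axis=0)
    M = Sm - Sm.mean(axis=0)
    syy = float(yc @ yc)
    Sff = (F * F).sum(axis=0)
    Smm = (M * M).sum(axis=0)
    Sfm = F.T @ M
    Sfy = F.T @ yc
    Smy = M.T @ yc
    det = Sff[:, None] * Smm[None, :] - Sfm**2
    with np.errstate(divide="ignore", invalid="ignore"):
        wf = (Smm[None, :] * Sfy[:, None] - Sfm * Smy[None, :]) / det
        wm = (Sff[:, None] * Smy[None, :] - Sfm * Sfy[:, None]) / det
        ess = wf * Sfy[:, None] + wm * Smy[None, :]
        r2 = ess / syy
    # singular pairs: best single-predictor R^2
    r2f = np.where(Sff > 0, Sfy**2 / np.where(Sff > 0, Sff, 1.0) / syy, 0.0)
    r2m = np.where(Smm > 0, Smy**2 / np.where(Smm > 0, Smm, 1.0) / syy, 0.0)
    bad = ~np.isfinite(r2) | (np.abs(det) < 1e-12 * np.maximum(Sff[:, None] * Smm[None, :], 1e-300))
    single = np.maximum(r2f[:, None], np.broadcast_to(r2m[None, :], r2.shape))
    r2 = np.where(bad, single, r2)
    wf = np.where(bad, np.where(r2f[:, None] >= r2m[None, :], 1.0, 0.0), wf)
    wm = np.where(bad, np.where(r2f[:, None] >= r2m[None, :], 0.0, 1.0), wm)
    return r2, wf, wm


@dataclass
class PRSBuildConfig:
    """Knobs for the 11-PRS build: grids, chain lengths, search mode."""

    phi_grid: tuple = DEFAULT_PHI_GRID
    pn_grid: HyperGridPN | None = None
    n_iter: int = 500
    burn_in: int = 100
    mult_search: str = "joint"  # or "greedy"
    seed: int = 0


def build_all_prs(panel: GenotypePanel, stats_f: SummaryStats | None,
                  stats_m: SummaryStats | None, stats_all: SummaryStats | None,
                  ld: LDBlockMatrix, pheno, config: PRSBuildConfig | None = None) -> dict:
    """Construct the full 11-PRS panel, tuned per target sex.

    Returns a mapping ``name -> {target_sex -> dict}`` where each entry holds
    the test-cohort score vector (``"scores"``), the test-sex labels, and the
    selected hyperparameters (``"selected"``).  PRS names involving a missing
    stratum are omitted with a log message.
    """
    config = config or PRSBuildConfig()
    strata = {"f": stats_f, "m": stats_m, "all": stats_all}
    present = {k: v for k, v in strata.items() if v is not None}
    for k in strata:
        if strata[k] is None:
            logger.warning("stratum '%s' summary statistics missing; dependent PRSs omitted", k)

    rows_val = np.flatnonzero(panel.mask(cohort="validation"))
    rows_test = np.flatnonzero(panel.mask(cohort="test"))
    sex_val = panel.sex[rows_val]
    sex_test = panel.sex[rows_test]
    y_val = np.asarray(pheno.values)[rows_val]

    # -- fit candidate grids -------------------------------------------
    candidates: dict[str, list] = {}
    for key, st in present.items():
        grid = config.pn_grid or HyperGridPN(h2_anchor=estimate_h2_ldscore(st, ld))
        candidates[f"LDpred2-{key}"] = fit_grid_pn(
            st, ld, grid=grid, n_iter=config.n_iter, burn_in=config.burn_in,
            seed=config.seed)
        candidates[f"PRScs-{key}"] = fit_grid_cs(
            st, ld, phi_grid=config.phi_grid, n_iter=config.n_iter,
            burn_in=config.burn_in, seed=config.seed)
    if stats_f is not None and stats_m is not None:
        pairs = fit_grid_cs((stats_f, stats_m), ld, phi_grid=config.phi_grid,
                            coupled=True, n_iter=config.n_iter,
                            burn_in=config.burn_in, seed=config.seed)
        candidates["PRScsx-f"] = [p[0] for p in pairs]
        candidates["PRScsx-m"] = [p[1] for p in pairs]

    # -- score all candidates on validation and test once --------------
    val_scores = {k: _score_matrix(panel, v, "validation") for k, v in candidates.items()}
    test_scores = {k: _score_matrix(panel, v, "test") for k, v in candidates.items()}

    def _tune_single(name: str, target: str):
        S = val_scores[name]
        sub = sex_val == target
        r2s = np.array([_r2(S[sub, k], y_val[sub]) for k in range(S.shape[1])])
        k = int(np.argmax(r2s))
        return {
            "scores": test_scores[name][:, k],
            "sex": sex_test,
            "selected": dict(candidates[name][k].hyperparams),
            "validation_r2": float(r2s[k]),
        }

    def _tune_mult(base: str, target: str):
        nf, nm = f"{base}-f", f"{base}-m"
        Sf_val, Sm_val = val_scores[nf], val_scores[nm]
        sub = sex_val == target
        yv = y_val[sub]
        if config.mult_search == "joint":
            r2, wf, wm = _pairwise_r2(Sf_val[sub], Sm_val[sub], yv)
            kf, km = np.unravel_index(int(np.argmax(r2)), r2.shape)
            w_f, w_m = float(wf[kf, km]), float(wm[kf, km])
            vr2 = float(r2[kf, km])
        else:  # greedy: tune each sex-specific PRS first, then combine
            r2f = np.array([_r2(Sf_val[sub, k], yv) for k in range(Sf_val.shape[1])])
            r2m = np.array([_r2(Sm_val[sub, k], yv) for k in range(Sm_val.shape[1])])
            kf, km = int(np.argmax(r2f)), int(np.argmax(r2m))
            f, mcol = Sf_val[sub, kf], Sm_val[sub, km]
            X = np.column_stack([np.ones_like(f), f, mcol])
            coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
            w_f, w_m = float(coef[1]), float(coef[2])
            vr2 = _r2(X @ coef, yv)
        combined_test = w_f * test_scores[nf][:, kf] + w_m * test_scores[nm][:, km]
        return {
            "scores": combined_test,
            "sex": sex_test,
            "selected": {
                "f": dict(candidates[nf][int(kf)].hyperparams),
                "m": dict(candidates[nm][int(km)].hyperparams),
                "w_f": w_f, "w_m": w_m,
            },
            "validation_r2": vr2,
        }

    out: dict[str, dict] = {}
    for target in ("F", "M"):
        for base in ("PRScs", "LDpred2"):
            for key in ("f", "m", "all"):
                name = f"{base}-{key}"
                if name in candidates:
                    out.setdefault(name, {})[target] = _tune_single(name, target)
            if f"{base}-f" in candidates and f"{base}-m" in candidates:
                out.setdefault(f"{base}-mult", {})[target] = _tune_mult(base, target)
        if "PRScsx-f" in candidates:
            for key in ("f", "m"):
                out.setdefault(f"PRScsx-{key}", {})[target] = _tune_single(f"PRScsx-{key}", target)
            out.setdefault("PRScsx-mult", {})[target] = _tune_mult("PRScsx", target)
    return out
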