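"""Point-normal (spike-and-slab) summary-statistics Gibbs sampler.

This is the classical LDpred-family model: each standardized effect is zero
with probability 1-p and N(0, h2/(M*p)) with probability p.  Given GWAS
marginal estimates ``beta_hat`` and a block LD matrix R, the sampler sweeps
variants within each block, forms the LD-residualized marginal estimate,
computes the posterior inclusion probability and slab moments in closed form,
and samples the joint effect.  The reported weight is the post-burn-in average
of the per-iteration posterior mean (dense mode) or of the sampled effects
with rarely-included variants zeroed (sparse mode).

A grid of (p, h2 multiplier, sparse) hyperparameters mirrors standard
practice: 17 log-spaced polygenicity values in [1e-5, 1], h2 at
{0.7, 1, 1.4} times an LD-score-regression anchor, and both dense and sparse
variants, i.e. 102 candidate weight vectors per set of summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from numba import njit

from .exceptions import DegenerateInputError, DomainError, SolverError
from .gwas import SummaryStats
from .panel import LDBlockMatrix

__all__ = [
    "HyperGridPN",
    "WeightVector",
    "estimate_h2_ldscore",
    "gibbs_pointnormal",
    "fit_grid_pn",
    "write_weights",
    "read_weights",
]

DIVERGENCE_BOUND = 10.0


@dataclass
class WeightVector:
    """Posterior-mean per-variant PRS weights with provenance.

    Weights are on the per-standardized-genotype scale; zero wherever the
    input summary statistics were unusable (se = +inf).
    """

    weights: np.ndarray
    variant_id: np.ndarray
    a1: np.ndarray
    method: str
    stratum_source: str
    hyperparams: dict
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise DomainError("weights must be finite")
        if not self.method or not self.stratum_source:
            raise DomainError("provenance fields must be non-empty")


def write_weights(wv: WeightVector, path, nonzero_only: bool = False) -> None:
    """Weight-file TSV, header SNP A1 WEIGHT METHOD PARAMS."""
    params = ";".join(f"{k}={v}" for k, v in sorted(wv.hyperparams.items()))
    df = pd.DataFrame(
        {"SNP": wv.variant_id, "A1": wv.a1, "WEIGHT": wv.weights,
         "METHOD": wv.method, "PARAMS": params}
    )
    if nonzero_only:
        df = df[df["WEIGHT"] != 0.0]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_weights(path) -> WeightVector:
    df = pd.read_csv(path, sep="\t")
    from .exceptions import FormatError

    if list(df.columns) != ["SNP", "A1", "WEIGHT", "METHOD", "PARAMS"]:
        raise FormatError(f"weight file columns must be SNP A1 WEIGHT METHOD PARAMS, got {list(df.columns)}")
    params = {}
    if len(df) and isinstance(df["PARAMS"].iloc[0], str):
        for kv in df["PARAMS"].iloc[0].split(";"):
            if "=" in kv:
                k, v = kv.split("=", 1)
                params[k] = v
    return WeightVector(
        weights=df["WEIGHT"].to_numpy(float),
        variant_id=df["SNP"].to_numpy(str),
        a1=df["A1"].to_numpy(str),
        method=str(df["METHOD"].iloc[0]) if len(df) else "unknown",
        stratum_source="ALL",
        hyperparams=params,
        seed=-1,
    )


@dataclass
class HyperGridPN:
    """Hyperparameter grid for the point-normal sampler."""

    h2_anchor: float
    p_values: np.ndarray = field(default_factory=lambda: np.logspace(-5, 0, 17))
    h2_multipliers: tuple = (0.7, 1.0, 1.4)
    sparse_options: tuple = (False, True)

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if np.any(self.p_values <= 0) or np.any(self.p_values > 1):
            raise DomainError("p values must lie in (0, 1]")
        if np.any(np.diff(self.p_values) <= 0):
            raise DomainError("p values must be strictly increasing")
        if any(m <= 0 for m in self.h2_multipliers):
            raise DomainError("h2 multipliers must be positive")

    def cells(self):
        """Deterministic grid order: p slowest, then multiplier, then sparse."""
        for p in self.p_values:
            for mult in self.h2_multipliers:
                h2 = float(np.clip(mult * self.h2_anchor, 1e-4, 1.0))
                for sparse in self.sparse_options:
                    yield float(p), h2, bool(sparse), float(mult)

    def __len__(self) -> int:
        return len(self.p_values) * len(self.h2_multipliers) * len(self.sparse_options)


def estimate_h2_ldscore(stats: SummaryStats, ld: LDBlockMatrix,
                        intercept: str = "fixed") -> float:
    """LD-score-regression heritability anchor.

    Under the polygenic model E[chi2_j] = 1 + n * l_j * h2 / M with l_j the
    within-block LD score.  ``intercept="fixed"`` pins the intercept at 1 (no
    confounding exists in simulated data) and estimates h2 as the
    through-origin slope of (chi2 - 1) on n*l/M; ``intercept="free"`` fits an
    unconstrained line, which requires genuine variation in the LD scores.
    The estimate is clamped to [0.001, 1].
    """
    if len(stats.beta_hat) != ld.n_variants:
        raise DomainError("summary statistics and LD matrix are not aligned")
    ell = ld.ld_scores()
    ok = stats.usable
    chi2 = stats.chi2()[ok]
    x = stats.n * ell[ok] / len(stats.beta_hat)
    if intercept == "fixed":
        denom = float(x @ x)
        if denom == 0:
            raise DegenerateInputError("all LD scores are zero")
        slope = float(x @ (chi2 - 1.0)) / denom
    elif intercept == "free":
        if np.ptp(ell[ok]) < 1e-9 or np.var(x) == 0:
            raise DegenerateInputError("LD scores are constant; free-intercept fit undefined")
        xc = x - x.mean()
        slope = float(xc @ (chi2 - chi2.mean())) / float(xc @ xc)
    else:
        raise DomainError("intercept must be 'fixed' or 'free'")
    return float(np.clip(slope, 0.001, 1.0))


@njit(cache=False)
def _pn_block_chain(R, bh, n, p, sigma_c2, n_iter, burn_in, seed):
    """Gibbs chain for one LD block.

    Returns (mean posterior-mean, mean sampled effect, mean inclusion prob,
    diverged flag).
    """
    np.random.seed(seed)
    m = R.shape[0]
    gamma = np.zeros(m)
    rvec = np.zeros(m)  # running R @ gamma, rank-1 updated on each accepted move
    sum_pm = np.zeros(m)
    sum_g = np.zeros(m)
    sum_pi = np.zeros(m)
    kept = 0
    inv_n = 1.0 / n
    s1 = sigma_c2 + inv_n      # marginal slab variance of beta_hat
    shrink = n * sigma_c2 / (n * sigma_c2 + 1.0)
    tau = np.sqrt(sigma_c2 / (n * sigma_c2 + 1.0))
    log_ratio_const = 0.0
    if p < 1.0:
        log_ratio_const = np.log(1.0 - p) - np.log(p) + 0.5 * (np.log(s1) - np.log(inv_n))
    for it in range(n_iter):
        for j in range(m):
            # LD-residualized marginal estimate
            btilde = bh[j] - (rvec[j] - gamma[j])
            mu = shrink * btilde
            if p >= 1.0:
                pi = 1.0
            else:
                # log spike density minus log slab density, folded with prior odds
                z = 0.5 * btilde * btilde * (1.0 / inv_n - 1.0 / s1)
                logit = log_ratio_const - z
                if logit > 35.0:
                    pi = 0.0
                elif logit < -35.0:
                    pi = 1.0
                else:
                    pi = 1.0 / (1.0 + np.exp(logit))
            if np.random.random() < pi:
                new = mu + tau * np.random.normal()
            else:
                new = 0.0
            d = new - gamma[j]
            if d != 0.0:
                for k in range(m):
                    rvec[k] += R[j, k] * d
            gamma[j] = new
            if not np.isfinite(new):
                return sum_pm, sum_g, sum_pi, True
            if np.abs(new) > DIVERGENCE_BOUND:
                return sum_pm, sum_g, sum_pi, True
            if it >= burn_in:
                sum_pm[j] += pi * mu
                sum_g[j] += gamma[j]
                sum_pi[j] += pi
        if it >= burn_in:
            kept += 1
    if kept > 0:
        sum_pm /= kept
        sum_g /= kept
        sum_pi /= kept
    return sum_pm, sum_g, sum_pi, False


def _extra_ridge(R: np.ndarray, eps: float) -> np.ndarray:
    out = (R + eps * np.eye(R.shape[0])) / (1.0 + eps)
    np.fill_diagonal(out, 1.0)
    return out


def gibbs_pointnormal(stats: SummaryStats, ld: LDBlockMatrix, p: float, h2: float,
                      sparse: bool = False, n_iter: int = 500, burn_in: int = 100,
                      seed: int = 0, sparse_threshold: float = 0.1) -> WeightVector:
    """Posterior-mean weights under the point-normal prior.

    Dense mode averages the per-iteration posterior mean pi*mu; sparse mode
    averages the sampled effects and zeroes variants whose posterior inclusion
    frequency falls below ``sparse_threshold``, yielding exact zeros.

    A divergence guard (|effect| > 10 on the standardized scale) restarts a
    block once with the LD ridge doubled, then raises :class:`SolverError`.
    """
    if not (0 < p <= 1):
        raise DomainError("p must lie in (0, 1]")
    if not (0 < h2 <= 1):
        raise DomainError("h2 must lie in (0, 1]")
    if n_iter <= burn_in:
        raise DomainError("n_iter must exceed burn_in")
    m = ld.n_variants
    if len(stats.beta_hat) != m:
        raise DomainError("summary statistics and LD matrix are not aligned")
    bh = np.where(stats.usable, stats.beta_hat, 0.0)
    sigma_c2 = h2 / (m * p)
    n = float(stats.n)

    block_seeds = np.random.SeedSequence([int(seed), 0x90B5]).generate_state(len(ld.blocks))
    weights = np.zeros(m)
    for bi, ((lo, hi), R) in enumerate(ld.blocks):
        bseed = int(block_seeds[bi] % np.uint32(2**31))
        pm, g, pi, diverged = _pn_block_chain(
            np.ascontiguousarray(R), bh[lo:hi], n, p, sigma_c2, n_iter, burn_in, bseed)
        if diverged:
            boost = 2.0 * (ld.ridge_eps if ld.ridge_eps > 0 else 0.01)
            pm, g, pi, diverged = _pn_block_chain(
                _extra_ridge(R, boost), bh[lo:hi], n, p, sigma_c2, n_iter, burn_in, bseed)
            if diverged:
                raise SolverError(f"point-normal Gibbs diverged on block {bi} even after extra ridge")
        if sparse:
            g = np.where(pi < sparse_threshold, 0.0, g)
            weights[lo:hi] = g
        else:
            weights[lo:hi] = pm
    weights[~stats.usable] = 0.0
    return WeightVector(
        weights=weights,
        variant_id=stats.variants["variant_id"].to_numpy(),
        a1=stats.variants["a1"].to_numpy(),
        method="pointnormal",
        stratum_source=stats.stratum,
        hyperparams={"p": p, "h2": h2, "sparse": sparse},
        seed=int(seed),
    )


def fit_grid_pn(stats: SummaryStats, ld: LDBlockMatrix, grid: HyperGridPN | None = None,
                n_iter: int = 500, burn_in: int = 100, seed: int = 0) -> list:
    """One WeightVector per grid cell, in deterministic grid order."""
    if grid is None:
        grid = HyperGridPN(h2_anchor=estimate_h2_ldscore(stats, ld))
    out = []
    for ci, (p, h2, sparse, mult) in enumerate(grid.cells()):
        wv = gibbs_pointnormal(stats, ld, p=p, h2=h2, sparse=sparse,
                               n_iter=n_iter, burn_in=burn_in,
                               seed=int(np.random.SeedSequence([int(seed), ci]).generate_state(1)[0] % 2**31))
        wv.hyperparams["h2_multiplier"] = mult
        out.append(wv)
    return out
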