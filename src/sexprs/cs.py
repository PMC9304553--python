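"""Continuous-shrinkage summary-statistics Gibbs samplers.

Single-stratum sampler (``gibbs_cs``): standardized effects carry a
global-local scale-mixture prior beta_j ~ N(0, phi * psi_j), with local scales
psi_j given a three-parameter-beta mixing density implemented through the
conditionals

* beta | psi  ~ MVN per LD block with precision n * (R + diag(1/(phi*psi)))
* psi_j | .   ~ GIG(a - 1/2, 2*delta_j, n * beta_j^2 / phi)
* delta_j | . ~ Gamma(a + b, rate = psi_j + 1)

with Strawderman-Berger shapes a=1, b=1/2 by default and residual variance
fixed at 1 (phenotypes in this pipeline are standardized).  The global
shrinkage phi is tuned over a grid on the validation cohort.

Coupled two-stratum sampler (``gibbs_csx_coupled``): female and male effects
are updated independently given a *single shared* local scale psi_j per
variant, which pools evidence across sexes in its GIG update,
psi_j ~ GIG(a - 1, 2*delta_j, (n_f*beta_fj^2 + n_m*beta_mj^2)/phi).  This is
the cross-population coupling idea applied with the two sexes as populations.

All conditionals are block-local, so each LD block runs its full chain in one
numba-compiled call (Cholesky factorization and triangular solves inlined).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._gig import CLAMP_HI, CLAMP_LO, _gig_one
from .exceptions import AlignmentError, DomainError, SolverError
from .gwas import SummaryStats
from .panel import LDBlockMatrix
from .pointnormal import WeightVector

__all__ = ["gibbs_cs", "gibbs_csx_coupled", "fit_grid_cs", "DEFAULT_PHI_GRID"]

DEFAULT_PHI_GRID = (1e-6, 1e-4, 1e-2, 1.0)


def _check_aligned(stats: SummaryStats, ld: LDBlockMatrix) -> None:
    if len(stats.beta_hat) != ld.n_variants:
        raise DomainError("summary statistics and LD matrix are not aligned")


@njit(cache=False)
def _chol_in_place(A):
    """Lower Cholesky of A, returned in a fresh array; False if not PD."""
    m = A.shape[0]
    L = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=False)
def _sample_mvn(L, bh, n, z):
    """Draw beta ~ N(A^-1 bh, (1/n) A^-1) given A = L L^T and z ~ N(0, I)."""
    m = L.shape[0]
    # forward substitution: L u = bh
    u = np.empty(m)
    for i in range(m):
        s = bh[i]
        for k in range(i):
            s -= L[i, k] * u[k]
        u[i] = s / L[i, i]
    # back substitution for the mean (L^T mu = u) and the noise (L^T e = z)
    mu = np.empty(m)
    e = np.empty(m)
    sqrt_n = np.sqrt(n)
    for i in range(m - 1, -1, -1):
        s1 = u[i]
        s2 = z[i]
        for k in range(i + 1, m):
            s1 -= L[k, i] * mu[k]
            s2 -= L[k, i] * e[k]
        mu[i] = s1 / L[i, i]
        e[i] = s2 / L[i, i]
    return mu + e / sqrt_n


@njit(cache=False)
def _cs_block_chain(R, bh, n, phi, a, b, n_iter, burn_in, seed):
    """Full single-stratum chain for one LD block; returns (mean beta, ok)."""
    np.random.seed(seed)
    m = R.shape[0]
    psi = np.ones(m)
    out = np.zeros(m)
    A = np.empty((m, m))
    kept = 0
    for it in range(n_iter):
        for i in range(m):
            for j in range(m):
                A[i, j] = R[i, j]
            d = phi * psi[i]
            if d < CLAMP_LO:
                d = CLAMP_LO
            elif d > CLAMP_HI:
                d = CLAMP_HI
            A[i, i] += 1.0 / d
        L, ok = _chol_in_place(A)
        if not ok:
            return out, False
        z = np.empty(m)
        for i in range(m):
            z[i] = np.random.normal()
        beta = _sample_mvn(L, bh, n, z)
        for j in range(m):
            delta = np.random.gamma(a + b, 1.0 / (psi[j] + 1.0))
            aj = 2.0 * delta
            bj = n * beta[j] * beta[j] / phi
            aj = min(max(aj, CLAMP_LO), CLAMP_HI)
            bj = min(max(bj, CLAMP_LO), CLAMP_HI)
            psi[j] = _gig_one(a - 0.5, aj, bj)
        if it >= burn_in:
            out += beta
            kept += 1
    return out / kept, True


@njit(cache=False)
def _csx_block_chain(R, bh1, bh2, n1, n2, phi, a, b, n_iter, burn_in, z1, z2, seed):
    """Coupled two-stratum chain for one LD block with shared local scales.

    The per-stratum Gaussian innovations ``z1``/``z2`` are supplied by the
    caller (keyed to each stratum's data); the shared shrinkage draws use the
    internal stream seeded with ``seed``.  This makes the sampler exactly
    equivariant: swapping the two inputs swaps the outputs bit for bit, and
    identical inputs give identical outputs.
    """
    np.random.seed(seed)
    m = R.shape[0]
    psi = np.ones(m)
    out1 = np.zeros(m)
    out2 = np.zeros(m)
    A = np.empty((m, m))
    kept = 0
    for it in range(n_iter):
        for i in range(m):
            for j in range(m):
                A[i, j] = R[i, j]
            d = phi * psi[i]
            if d < CLAMP_LO:
                d = CLAMP_LO
            elif d > CLAMP_HI:
                d = CLAMP_HI
            A[i, i] += 1.0 / d
        L, ok = _chol_in_place(A)
        if not ok:
            return out1, out2, False
        beta1 = _sample_mvn(L, bh1, n1, z1[it])
        beta2 = _sample_mvn(L, bh2, n2, z2[it])
        for j in range(m):
            delta = np.random.gamma(a + b, 1.0 / (psi[j] + 1.0))
            aj = 2.0 * delta
            bj = (n1 * beta1[j] * beta1[j] + n2 * beta2[j] * beta2[j]) / phi
            aj = min(max(aj, CLAMP_LO), CLAMP_HI)
            bj = min(max(bj, CLAMP_LO), CLAMP_HI)
            psi[j] = _gig_one(a - 1.0, aj, bj)
        if it >= burn_in:
            out1 += beta1
            out2 += beta2
            kept += 1
    return out1 / kept, out2 / kept, True


def _stratum_stream_key(stats: SummaryStats) -> int:
    """Stable digest of a stratum's data, used to key its innovation stream."""
    import zlib

    h = zlib.crc32(np.ascontiguousarray(stats.beta_hat).tobytes())
    h = zlib.crc32(str(stats.n).encode(), h)
    h = zlib.crc32(stats.stratum.encode(), h)
    return int(h) & 0x7FFFFFFF


def _block_seeds(seed: int, tag: int, n_blocks: int) -> np.ndarray:
    return np.random.SeedSequence([int(seed), tag]).generate_state(n_blocks) % np.uint32(2**31)


def gibbs_cs(stats: SummaryStats, ld: LDBlockMatrix, phi: float,
             n_iter: int = 500, burn_in: int = 100, seed: int = 0,
             a: float = 1.0, b: float = 0.5) -> WeightVector:
    """Posterior-mean weights under the continuous shrinkage prior."""
    if phi <= 0:
        raise DomainError("phi must be positive")
    if n_iter <= burn_in:
        raise DomainError("n_iter must exceed burn_in")
    _check_aligned(stats, ld)
    m = ld.n_variants
    bh = np.where(stats.usable, stats.beta_hat, 0.0)
    n = float(stats.n)
    seeds = _block_seeds(seed, 0xC5, len(ld.blocks))
    weights = np.zeros(m)
    for bi, ((lo, hi), R) in enumerate(ld.blocks):
        w, ok = _cs_block_chain(np.ascontiguousarray(R), bh[lo:hi], n, float(phi),
                                float(a), float(b), n_iter, burn_in, int(seeds[bi]))
        if not ok:
            raise SolverError(f"CS sampler: Cholesky failed on block {bi}")
        weights[lo:hi] = w
    weights[~stats.usable] = 0.0
    return WeightVector(
        weights=weights,
        variant_id=stats.variants["variant_id"].to_numpy(),
        a1=stats.variants["a1"].to_numpy(),
        method="cs",
        stratum_source=stats.stratum,
        hyperparams={"phi": phi, "a": a, "b": b},
        seed=int(seed),
    )


def gibbs_csx_coupled(stats_f: SummaryStats, stats_m: SummaryStats, ld: LDBlockMatrix,
                      phi: float, n_iter: int = 500, burn_in: int = 100, seed: int = 0,
                      a: float = 1.0, b: float = 0.5):
    """Coupled two-stratum sampler sharing local shrinkage across sexes.

    Returns ``(WeightVector first-input, WeightVector second-input)``; with a
    fixed seed, swapping the inputs exactly swaps the outputs.
    """
    if phi <= 0:
        raise DomainError("phi must be positive")
    if n_iter <= burn_in:
        raise DomainError("n_iter must exceed burn_in")
    _check_aligned(stats_f, ld)
    _check_aligned(stats_m, ld)
    ids_f = stats_f.variants["variant_id"].to_numpy()
    ids_m = stats_m.variants["variant_id"].to_numpy()
    if not np.array_equal(ids_f, ids_m):
        bad = np.flatnonzero(ids_f != ids_m)[:10]
        raise AlignmentError(
            f"variant sets differ between strata at rows {bad.tolist()}: "
            f"{ids_f[bad].tolist()} vs {ids_m[bad].tolist()}")
    m = ld.n_variants
    bh_f = np.where(stats_f.usable, stats_f.beta_hat, 0.0)
    bh_m = np.where(stats_m.usable, stats_m.beta_hat, 0.0)
    seeds = _block_seeds(seed, 0xC5E, len(ld.blocks))
    key_f = _stratum_stream_key(stats_f)
    key_m = _stratum_stream_key(stats_m)
    w_f = np.zeros(m)
    w_m = np.zeros(m)
    for bi, ((lo, hi), R) in enumerate(ld.blocks):
        # innovations keyed to each stratum's data, not its argument position
        rng_f = np.random.default_rng(np.random.SeedSequence([int(seed), 0x21, key_f, bi]))
        rng_m = np.random.default_rng(np.random.SeedSequence([int(seed), 0x21, key_m, bi]))
        z_f = rng_f.standard_normal((n_iter, hi - lo))
        z_m = rng_m.standard_normal((n_iter, hi - lo))
        wf, wm, ok = _csx_block_chain(
            np.ascontiguousarray(R), bh_f[lo:hi], bh_m[lo:hi],
            float(stats_f.n), float(stats_m.n), float(phi), float(a), float(b),
            n_iter, burn_in, z_f, z_m, int(seeds[bi]))
        if not ok:
            raise SolverError(f"coupled CS sampler: Cholesky failed on block {bi}")
        w_f[lo:hi] = wf
        w_m[lo:hi] = wm
    w_f[~stats_f.usable] = 0.0
    w_m[~stats_m.usable] = 0.0
    out = []
    for stats_s, w in ((stats_f, w_f), (stats_m, w_m)):
        out.append(WeightVector(
            weights=w,
            variant_id=stats_s.variants["variant_id"].to_numpy(),
            a1=stats_s.variants["a1"].to_numpy(),
            method="csx",
            stratum_source=stats_s.stratum,
            hyperparams={"phi": phi, "a": a, "b": b},
            seed=int(seed),
        ))
    return out[0], out[1]


def fit_grid_cs(stats, ld: LDBlockMatrix, phi_grid=DEFAULT_PHI_GRID, coupled: bool = False,
                n_iter: int = 500, burn_in: int = 100, seed: int = 0,
                a: float = 1.0, b: float = 0.5) -> list:
    """One WeightVector (or coupled pair) per global-shrinkage value.

    ``stats`` is a single SummaryStats for the single-stratum sampler, or a
    ``(stats_f, stats_m)`` pair when ``coupled=True``.
    """
    if len(phi_grid) == 0:
        raise DomainError("phi_grid must be non-empty")
    out = []
    for gi, phi in enumerate(phi_grid):
        cell_seed = int(np.random.SeedSequence([int(seed), 0xF1, gi]).generate_state(1)[0] % 2**31)
        if coupled:
            out.append(gibbs_csx_coupled(stats[0], stats[1], ld, phi=float(phi),
                                         n_iter=n_iter, burn_in=burn_in, seed=cell_seed,
                                         a=a, b=b))
        else:
            out.append(gibbs_cs(stats, ld, phi=float(phi), n_iter=n_iter,
                                burn_in=burn_in, seed=cell_seed, a=a, b=b))
    return out
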