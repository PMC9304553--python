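"""Sex-specific genetic architectures and quantitative phenotypes.

Effect sizes live on the standardized-genotype scale, so the per-sex SNP
heritability is simply the sum of squared effects; each sex's effect vector is
rescaled after sampling so that sum(beta^2) equals the configured h² exactly.
Shared causal variants get effects from a bivariate normal with cross-sex
correlation ``rg``; sex-only causal variants get independent univariate
effects with that sex's per-variant variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, InfeasibleArchitectureError
from .panel import GenotypePanel

__all__ = [
    "CausalSets",
    "GeneticArchitecture",
    "PhenotypeVector",
    "sample_causal_sets",
    "draw_effect_sizes",
    "simulate_phenotypes",
]


@dataclass
class CausalSets:
    """Disjoint index sets of shared and sex-only causal variants."""

    shared: np.ndarray
    female_only: np.ndarray
    male_only: np.ndarray
    m_variants: int

    def __post_init__(self) -> None:
        self.shared = np.sort(np.asarray(self.shared, dtype=np.int64))
        self.female_only = np.sort(np.asarray(self.female_only, dtype=np.int64))
        self.male_only = np.sort(np.asarray(self.male_only, dtype=np.int64))
        all_idx = np.concatenate([self.shared, self.female_only, self.male_only])
        if np.unique(all_idx).size != all_idx.size:
            raise DomainError("causal sets must be pairwise disjoint")
        if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= self.m_variants):
            raise DomainError("causal indices out of range")

    @property
    def female(self) -> np.ndarray:
        return np.sort(np.concatenate([self.shared, self.female_only]))

    @property
    def male(self) -> np.ndarray:
        return np.sort(np.concatenate([self.shared, self.male_only]))


@dataclass
class GeneticArchitecture:
    """Per-sex true effect vectors with their generating parameters."""

    beta_f: np.ndarray
    beta_m: np.ndarray
    h2_f: float
    h2_m: float
    rg: float
    causal: CausalSets

    def to_frame(self, variants: pd.DataFrame) -> pd.DataFrame:
        """TSV-ready table: variant_id, beta_f, beta_m, causal_class."""
        cls = np.full(self.causal.m_variants, "none", dtype="U6")
        cls[self.causal.female_only] = "F"
        cls[self.causal.male_only] = "M"
        cls[self.causal.shared] = "shared"
        return pd.DataFrame(
            {
                "variant_id": variants["variant_id"].to_numpy(),
                "beta_f": self.beta_f,
                "beta_m": self.beta_m,
                "causal_class": cls,
            }
        )


@dataclass
class PhenotypeVector:
    """Observed phenotype and its latent genetic component, per individual."""

    values: np.ndarray
    genetic_component: np.ndarray
    sex: np.ndarray


def sample_causal_sets(m_variants: int, p_causal: float, shared_fraction: float,
                       seed: int = 0) -> CausalSets:
    """Draw shared and sex-only causal index sets.

    The per-sex causal count is ``round(p_causal * m_variants)``; of these,
    ``round(shared_fraction * m_c)`` are shared between the sexes and the rest
    are private to each sex, all sampled without replacement.
    """
    if not (0 <= shared_fraction <= 1):
        raise DomainError("shared_fraction must lie in [0, 1]")
    m_c = int(round(p_causal * m_variants))
    if m_c < 1:
        raise InfeasibleArchitectureError(
            f"p_causal={p_causal} gives {m_c} causal variants; need >= 1")
    n_shared = int(round(shared_fraction * m_c))
    n_only = m_c - n_shared
    need = n_shared + 2 * n_only
    if need > m_variants:
        raise InfeasibleArchitectureError(
            f"need {need} distinct causal variants but panel has {m_variants}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA5]))
    picked = rng.choice(m_variants, size=need, replace=False)
    return CausalSets(
        shared=picked[:n_shared],
        female_only=picked[n_shared:n_shared + n_only],
        male_only=picked[n_shared + n_only:],
        m_variants=m_variants,
    )


def draw_effect_sizes(causal: CausalSets, h2_f: float, h2_m: float, rg: float,
                      seed: int = 0) -> GeneticArchitecture:
    """Sample per-sex true effects with cross-sex genetic correlation ``rg``.

    Shared variants draw (beta_f, beta_m) from a bivariate normal with
    variances h2_s / m_s and covariance rg * sigma_f * sigma_m; |rg| = 1 is
    handled analytically (beta_m proportional to beta_f) rather than through a
    singular Cholesky.  Each sex's vector is then rescaled so that
    sum(beta^2) == h2 exactly.
    """
    if not (0 <= h2_f <= 1 and 0 <= h2_m <= 1):
        raise DomainError("heritabilities must lie in [0, 1]")
    if not (-1 <= rg <= 1):
        raise DomainError("rg must lie in [-1, 1]")
    m = causal.m_variants
    m_f = causal.female.size
    m_m = causal.male.size
    sigma_f = np.sqrt(h2_f / m_f) if m_f else 0.0
    sigma_m = np.sqrt(h2_m / m_m) if m_m else 0.0

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE7A]))
    beta_f = np.zeros(m)
    beta_m = np.zeros(m)

    k = causal.shared.size
    if k:
        if abs(rg) == 1.0:
            z = rng.standard_normal(k)
            bf = sigma_f * z
            bm = np.sign(rg) * sigma_m * z
        else:
            L = np.linalg.cholesky(np.array([[1.0, rg], [rg, 1.0]]))
            z = rng.standard_normal((k, 2)) @ L.T
            bf = sigma_f * z[:, 0]
            bm = sigma_m * z[:, 1]
        beta_f[causal.shared] = bf
        beta_m[causal.shared] = bm
    if causal.female_only.size:
        beta_f[causal.female_only] = sigma_f * rng.standard_normal(causal.female_only.size)
    if causal.male_only.size:
        beta_m[causal.male_only] = sigma_m * rng.standard_normal(causal.male_only.size)

    for beta, h2 in ((beta_f, h2_f), (beta_m, h2_m)):
        ss = float(beta @ beta)
        if h2 > 0 and ss > 0:
            beta *= np.sqrt(h2 / ss)
        else:
            beta[:] = 0.0
    return GeneticArchitecture(beta_f=beta_f, beta_m=beta_m, h2_f=h2_f, h2_m=h2_m,
                               rg=rg, causal=causal)


def simulate_phenotypes(panel: GenotypePanel, arch: GeneticArchitecture,
                        seed: int = 0) -> PhenotypeVector:
    """Generate y = g + e with per-sex heritability.

    The genetic component of individual i of sex s is the sum over causal
    variants of the per-sex standardized dosage times the true effect;
    environmental noise is N(0, 1 - h2_s), so the within-sex phenotypic
    variance is 1 in expectation.
    """
    if arch.causal.m_variants != panel.n_variants:
        raise DomainError("architecture and panel disagree on n_variants")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF30]))
    n = panel.n_individuals
    g = np.zeros(n)
    y = np.zeros(n)
    for s, beta, h2 in (("F", arch.beta_f, arch.h2_f), ("M", arch.beta_m, arch.h2_m)):
        if h2 > 1:
            raise DomainError("h2 must not exceed 1")
        rows = np.flatnonzero(panel.sex == s)
        if rows.size == 0:
            continue
        nz = np.flatnonzero(beta)
        if nz.size:
            G = panel.dosages[np.ix_(rows, nz)].astype(np.float64)
            mu = G.mean(axis=0)
            sd = G.std(axis=0)
            sd[sd == 0] = 1.0
            g[rows] = ((G - mu) / sd) @ beta[nz]
        eps = rng.standard_normal(rows.size) * np.sqrt(max(1.0 - h2, 0.0))
        y[rows] = g[rows] + eps
    return PhenotypeVector(values=y, genetic_component=g, sex=panel.sex.copy())
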