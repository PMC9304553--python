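"""Synthetic genotype panels with block linkage disequilibrium.

Genotypes are simulated from a Gaussian-copula model: within each LD block a
latent AR(1) Gaussian process with autocorrelation ``rho`` is thresholded at
the per-variant minor-allele-frequency quantile to produce one haplotype;
dosages are the sum of two independent haplotypes.  This gives controllable,
locally realistic LD (adjacent-variant genotype correlation close to the
latent ``rho``) without any external reference data.

Individuals carry a sex label (``F``/``M``) and a cohort label
(``train`` / ``validation`` / ``test`` / ``reference`` / ``unassigned``); the
cohorts are pairwise disjoint by construction.  The ``reference`` cohort plays
the role of an external LD reference panel: LD matrices consumed by the PRS
samplers are estimated there, out-of-sample from the GWAS training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .exceptions import ConfigurationError, DegenerateInputError, DomainError, InsufficientSamplesError

SEXES = ("F", "M")
COHORTS = ("train", "validation", "test", "reference")
UNASSIGNED = "unassigned"

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2", "maf", "block_id"]


def validate_variants(variants: pd.DataFrame, maf_floor: float = 0.0) -> None:
    """Check the structural invariants of a variant table.

    Raises :class:`DomainError` on duplicate ids, MAF outside
    (``maf_floor``, 0.5], non-increasing positions within a chromosome, or a
    decreasing block id.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise DomainError(f"variant table missing columns: {missing}")
    if variants["variant_id"].duplicated().any():
        raise DomainError("variant_id values must be unique")
    maf = variants["maf"].to_numpy()
    if np.any(maf < maf_floor) or np.any(maf > 0.5) or np.any(maf <= 0):
        raise DomainError(f"maf must lie in ({maf_floor}, 0.5]")
    for _, sub in variants.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise DomainError("positions must be strictly increasing within a chromosome")
    blk = variants["block_id"].to_numpy()
    if np.any(np.diff(blk) < 0):
        raise DomainError("block_id must be non-decreasing along the table")


def variants_to_bim(variants: pd.DataFrame, path) -> None:
    """Export a PLINK-style .bim-like TSV (chrom, id, 0, pos, a1, a2)."""
    out = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "variant_id": variants["variant_id"],
            "cm": 0,
            "pos": variants["pos"],
            "a1": variants["a1"],
            "a2": variants["a2"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# chunked helpers over the int8 dosage matrix


def column_moments(dosages: np.ndarray, rows: np.ndarray | None = None, chunk: int = 2048):
    """Per-variant mean and SD (ddof=0) over the selected rows, chunked.

    Returns float64 arrays; SD of a constant column is 0.
    """
    G = dosages if rows is None else dosages[rows]
    n, m = G.shape
    mean = np.empty(m)
    sd = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        block = G[:, lo:hi].astype(np.float64)
        mean[lo:hi] = block.mean(axis=0)
        sd[lo:hi] = block.std(axis=0)
    return mean, sd


def standardized_crossprod(dosages: np.ndarray, y: np.ndarray, rows: np.ndarray,
                           mean: np.ndarray, sd: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Compute z_j . y for every variant j without materializing Z.

    ``z`` is the column-standardized dosage ``(g - mean_j) / sd_j`` over the
    selected rows; columns with sd == 0 return 0.
    """
    G = dosages[rows]
    m = G.shape[1]
    out = np.zeros(m)
    ysum = float(y.sum())
    safe = sd > 0
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        raw = G[:, lo:hi].astype(np.float64).T @ y
        out[lo:hi] = raw - mean[lo:hi] * ysum
    out[safe] /= sd[safe]
    out[~safe] = 0.0
    return out


def standardized_matvec(dosages: np.ndarray, w: np.ndarray, rows: np.ndarray,
                        mean: np.ndarray, sd: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Compute Z @ w over the selected rows (Z column-standardized), chunked."""
    G = dosages[rows]
    n, m = G.shape
    safe = sd > 0
    wn = np.where(safe, w / np.where(safe, sd, 1.0), 0.0)
    out = np.zeros(n)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        out += G[:, lo:hi].astype(np.float64) @ wn[lo:hi]
    return out - float(mean @ wn)


def standardized_matmat(dosages: np.ndarray, W: np.ndarray, rows: np.ndarray,
                        mean: np.ndarray, sd: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Compute Z @ W for a weight matrix W (m x k), chunked over variants."""
    G = dosages[rows]
    n = G.shape[0]
    k = W.shape[1]
    safe = sd > 0
    Wn = np.where(safe[:, None], W / np.where(safe, sd, 1.0)[:, None], 0.0)
    out = np.zeros((n, k))
    m = G.shape[1]
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        out += G[:, lo:hi].astype(np.float64) @ Wn[lo:hi]
    return out - mean @ Wn


# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant metadata and individual labels.

    Attributes
    ----------
    dosages
        ``(n_individuals, n_variants)`` int8 matrix of counts of ``a1``.
    variants
        Variant table with columns ``variant_id, chrom, pos, a1, a2, maf,
        block_id``.
    sex
        Per-individual label in ``{"F", "M"}``.
    cohort
        Per-individual label; cohorts partition the individuals.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sex: np.ndarray
    cohort: np.ndarray

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype="U1")
        self.cohort = np.asarray(self.cohort, dtype="U16")
        if self.dosages.shape[0] != self.sex.shape[0] or self.sex.shape[0] != self.cohort.shape[0]:
            raise DomainError("dosages, sex and cohort must agree on n_individuals")
        if self.dosages.shape[1] != len(self.variants):
            raise DomainError("dosages and variant table must agree on n_variants")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def mask(self, cohort: str | None = None, sex: str | None = None) -> np.ndarray:
        """Boolean individual mask for a cohort and/or sex filter."""
        m = np.ones(self.n_individuals, dtype=bool)
        if cohort is not None:
            m &= self.cohort == cohort
        if sex is not None:
            m &= self.sex == sex
        return m

    def cohort_counts(self) -> pd.Series:
        return pd.Series(self.cohort).groupby([self.sex, self.cohort]).size()

    # -- persistence ---------------------------------------------------

    def to_hdf5(self, path) -> None:
        """Persist the panel in a single HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("dosages", data=self.dosages, compression="gzip")
            f.create_dataset("sex", data=self.sex.astype("S1"))
            f.create_dataset("cohort", data=self.cohort.astype("S16"))
            grp = f.create_group("variants")
            for col in VARIANT_COLUMNS:
                vals = self.variants[col].to_numpy()
                if vals.dtype.kind in "OU":
                    vals = vals.astype("S32")
                grp.create_dataset(col, data=vals)

    @classmethod
    def from_hdf5(cls, path) -> "GenotypePanel":
        import h5py

        with h5py.File(path, "r") as f:
            dos = f["dosages"][:]
            sex = f["sex"][:].astype("U1")
            cohort = f["cohort"][:].astype("U16")
            cols = {}
            for col in VARIANT_COLUMNS:
                vals = f["variants"][col][:]
                if vals.dtype.kind == "S":
                    vals = vals.astype("U32")
                cols[col] = vals
        return cls(dos, pd.DataFrame(cols), sex, cohort)


@dataclass
class LDBlockMatrix:
    """Block-diagonal LD (genotype correlation) matrix.

    ``blocks`` is an ordered list of ``((start, stop), R)`` pairs whose index
    ranges tile ``0..m`` without gaps; every ``R`` is symmetric with unit
    diagonal after ridge regularization.
    """

    blocks: list
    source_n: int
    ridge_eps: float = 0.0

    @property
    def n_variants(self) -> int:
        return self.blocks[-1][0][1] if self.blocks else 0

    def validate(self) -> None:
        expect = 0
        for (lo, hi), R in self.blocks:
            if lo != expect:
                raise DomainError("LD block ranges must tile the variants without gaps")
            expect = hi
            if R.shape != (hi - lo, hi - lo):
                raise DomainError("LD block shape mismatch")
            if not np.allclose(R, R.T, atol=1e-10):
                raise DomainError("LD block must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise DomainError("LD block must have unit diagonal")

    def ld_scores(self) -> np.ndarray:
        """Per-variant LD score l_j = sum_k r^2_jk within the block (incl. self)."""
        out = np.empty(self.n_variants)
        for (lo, hi), R in self.blocks:
            out[lo:hi] = (R**2).sum(axis=1)
        return out

    def to_dense(self) -> np.ndarray:
        m = self.n_variants
        out = np.zeros((m, m))
        for (lo, hi), R in self.blocks:
            out[lo:hi, lo:hi] = R
        return out


# ---------------------------------------------------------------------------


def _simulate_haplotype_block(rng: np.random.Generator, n: int, thresholds: np.ndarray,
                              rho: float) -> np.ndarray:
    """One haplotype for one LD block: thresholded latent AR(1) Gaussian."""
    b = thresholds.shape[0]
    eps = rng.standard_normal((n, b)).astype(np.float32)
    if rho != 0.0:
        scale = np.float32(np.sqrt(1.0 - rho * rho))
        rho32 = np.float32(rho)
        for j in range(1, b):
            eps[:, j] = rho32 * eps[:, j - 1] + scale * eps[:, j]
    return eps < thresholds.astype(np.float32)


def simulate_genotype_panel(m_variants: int, block_size: int = 50, rho: float = 0.6,
                            maf_low: float = 0.05, maf_high: float = 0.5,
                            cohort_sizes: dict | None = None, seed: int = 0,
                            chrom: int = 1) -> GenotypePanel:
    """Simulate an LD-structured dosage panel with sex-labeled cohorts.

    Parameters
    ----------
    m_variants
        Number of biallelic variants (all coded A/G, 1 kb apart on one
        pseudo-chromosome).
    block_size
        Variants per LD block; the last block may be short.
    rho
        Latent AR(1) autocorrelation within a block, in [0, 1).
    maf_low, maf_high
        Per-variant MAFs are drawn uniformly on ``[maf_low, maf_high]``;
        bounds must lie in (0, 0.5].
    cohort_sizes
        Mapping ``(sex, cohort) -> count`` with sex in ``{"F","M"}`` and
        cohort in ``{"train","validation","test","reference"}``.  Every count
        provided must be positive.
    seed
        Seed for all randomness (MAFs, haplotypes).
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise DomainError("maf bounds must satisfy 0 < maf_low <= maf_high <= 0.5")
    if not (0 <= rho < 1):
        raise DomainError("rho must lie in [0, 1)")
    if m_variants < 1 or block_size < 1:
        raise ConfigurationError("m_variants and block_size must be positive")
    if cohort_sizes is None:
        cohort_sizes = {(s, c): 100 for s in SEXES for c in ("train", "validation", "test")}
    sex_labels = []
    cohort_labels = []
    for (s, c), count in sorted(cohort_sizes.items()):
        if s not in SEXES or c not in COHORTS:
            raise ConfigurationError(f"unknown sex/cohort key: {(s, c)}")
        if count <= 0:
            raise ConfigurationError(f"cohort size for {(s, c)} must be positive, got {count}")
        sex_labels.append(np.full(count, s))
        cohort_labels.append(np.full(count, c))
    sex = np.concatenate(sex_labels)
    cohort = np.concatenate(cohort_labels)
    n = sex.shape[0]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EC5]))
    maf = rng.uniform(maf_low, maf_high, size=m_variants)
    thresholds = sp_stats.norm.ppf(maf)

    block_id = np.arange(m_variants) // block_size
    dosages = np.empty((n, m_variants), dtype=np.int8)
    for b in range(block_id[-1] + 1):
        lo, hi = b * block_size, min((b + 1) * block_size, m_variants)
        h1 = _simulate_haplotype_block(rng, n, thresholds[lo:hi], rho)
        h2 = _simulate_haplotype_block(rng, n, thresholds[lo:hi], rho)
        dosages[:, lo:hi] = h1.astype(np.int8) + h2.astype(np.int8)

    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m_variants)],
            "chrom": chrom,
            "pos": np.arange(1, m_variants + 1) * 1000,
            "a1": "A",
            "a2": "G",
            "maf": maf,
            "block_id": block_id,
        }
    )
    return GenotypePanel(dosages, variants, sex, cohort)


def split_cohorts(panel: GenotypePanel, spec: dict, seed: int = 0) -> GenotypePanel:
    """Reassign cohort labels; disjoint by construction, deterministic by seed.

    ``spec`` maps ``(sex, cohort) -> count``.  Individuals of each sex are
    permuted once and dealt into cohorts in a fixed cohort order; leftovers
    are labeled ``unassigned``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B117]))
    new_cohort = np.full(panel.n_individuals, UNASSIGNED, dtype="U16")
    for s in SEXES:
        idx = np.flatnonzero(panel.sex == s)
        wanted = {c: int(spec.get((s, c), 0)) for c in COHORTS}
        if any(v < 0 for v in wanted.values()):
            raise ConfigurationError("cohort counts must be non-negative")
        total = sum(wanted.values())
        if total > idx.size:
            raise InsufficientSamplesError(
                f"sex {s}: requested {total} individuals, only {idx.size} available")
        perm = rng.permutation(idx)
        at = 0
        for c in COHORTS:
            new_cohort[perm[at:at + wanted[c]]] = c
            at += wanted[c]
    return GenotypePanel(panel.dosages, panel.variants, panel.sex.copy(), new_cohort)


def estimate_ld(panel: GenotypePanel, cohort: str = "reference",
                ridge_eps: float = 0.01) -> LDBlockMatrix:
    """Per-block sample genotype correlation, ridge-regularized.

    The sample correlation matrix of each block is computed on the chosen
    cohort, then ``ridge_eps`` is added to the diagonal and the matrix is
    renormalized back to unit diagonal (i.e. shrunk by ``1/(1+ridge_eps)``
    off the diagonal).  Zero-variance variants get zero off-diagonal LD.
    """
    if ridge_eps < 0:
        raise DomainError("ridge_eps must be non-negative")
    rows = np.flatnonzero(panel.mask(cohort=cohort))
    if rows.size < 2:
        raise DegenerateInputError(f"cohort '{cohort}' has {rows.size} individuals; need >= 2")
    block_id = panel.variants["block_id"].to_numpy()
    blocks = []
    for b in np.unique(block_id):
        cols = np.flatnonzero(block_id == b)
        lo, hi = int(cols[0]), int(cols[-1]) + 1
        G = panel.dosages[np.ix_(rows, cols)].astype(np.float64)
        G -= G.mean(axis=0)
        sd = G.std(axis=0)
        ok = sd > 0
        G[:, ok] /= sd[ok]
        R = (G.T @ G) / rows.size
        R[~ok, :] = 0.0
        R[:, ~ok] = 0.0
        np.fill_diagonal(R, 1.0)
        R = (R + ridge_eps * np.eye(R.shape[0])) / (1.0 + ridge_eps)
        R = 0.5 * (R + R.T)
        np.fill_diagonal(R, 1.0)
        blocks.append(((lo, hi), R))
    return LDBlockMatrix(blocks=blocks, source_n=int(rows.size), ridge_eps=ridge_eps)
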