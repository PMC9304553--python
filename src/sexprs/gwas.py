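"""Per-variant GWAS by ordinary least squares, stratified by sex.

Synthetic cohorts contain unrelated individuals with no population structure,
so plain OLS on standardized dosages is the correct association model.  The
phenotype is first residualized on the covariates (an intercept always; a sex
indicator for the sex-agnostic analysis) and rescaled to unit variance, so the
reported effects are on the standardized-genotype / unit-phenotype scale that
all downstream shrinkage samplers assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .exceptions import ConfigurationError, FormatError
from .panel import GenotypePanel, column_moments, standardized_crossprod

STRATA = ("F", "M", "ALL")

SUMSTATS_COLUMNS = ["CHR", "SNP", "BP", "A1", "A2", "MAF", "BETA", "SE", "P", "N"]


@dataclass
class SummaryStats:
    """Marginal per-variant association estimates for one stratum.

    ``beta_hat`` is on the per-standardized-genotype scale; ``se`` is +inf for
    variants with zero dosage variance in the stratum (excluded downstream);
    ``n`` is the stratum sample size.
    """

    variants: pd.DataFrame
    beta_hat: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    n: int
    stratum: str

    @property
    def usable(self) -> np.ndarray:
        return np.isfinite(self.se)

    def chi2(self) -> np.ndarray:
        out = np.zeros_like(self.beta_hat)
        ok = self.usable
        out[ok] = (self.beta_hat[ok] / self.se[ok]) ** 2
        return out


def run_gwas(panel: GenotypePanel, pheno, stratum: str,
             covariate_set: frozenset | set = frozenset({"sex"}),
             cohort: str = "train") -> SummaryStats:
    """Sex-specific or sex-agnostic marginal OLS association scan.

    Parameters
    ----------
    stratum
        ``"F"`` or ``"M"`` for a sex-specific scan on that sex only, ``"ALL"``
        for the pooled scan (with a sex-indicator covariate when ``"sex"`` is
        in ``covariate_set``).
    cohort
        Cohort the scan runs on (the training set in the benchmark).
    """
    if stratum not in STRATA:
        raise ConfigurationError(f"stratum must be one of {STRATA}")
    sex = None if stratum == "ALL" else stratum
    rows = np.flatnonzero(panel.mask(cohort=cohort, sex=sex))
    if rows.size == 0:
        raise ConfigurationError(f"no individuals in cohort '{cohort}' for stratum {stratum}")
    y = np.asarray(pheno.values, dtype=np.float64)[rows]

    # residualize on covariates (intercept always)
    X = [np.ones(rows.size)]
    if stratum == "ALL" and "sex" in covariate_set:
        X.append((panel.sex[rows] == "M").astype(np.float64))
    X = np.column_stack(X)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd_y = resid.std()
    if sd_y == 0:
        raise ConfigurationError("phenotype has zero variance in the stratum")
    resid /= sd_y

    n = rows.size
    n_cov = X.shape[1] - 1
    df = n - 1 - n_cov
    if df < 1:
        raise ConfigurationError("not enough samples for the covariate set")

    mean, sd = column_moments(panel.dosages, rows)
    zz = np.full(panel.n_variants, float(n))  # sum z^2 for standardized columns
    zy = standardized_crossprod(panel.dosages, resid, rows, mean, sd)
    ok = sd > 0

    beta = np.zeros(panel.n_variants)
    se = np.full(panel.n_variants, np.inf)
    pval = np.ones(panel.n_variants)
    beta[ok] = zy[ok] / zz[ok]
    yy = float(resid @ resid)
    rss = yy - beta[ok] * zy[ok]
    sigma2 = np.maximum(rss, 0.0) / df
    se[ok] = np.sqrt(sigma2 / zz[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf)
    pval[ok] = np.clip(2.0 * sp_stats.t.sf(np.abs(tstat), df), np.finfo(float).tiny, 1.0)
    return SummaryStats(variants=panel.variants, beta_hat=beta, se=se, pval=pval,
                        n=n, stratum=stratum)


# ---------------------------------------------------------------------------
# exchange format: tab-delimited, header CHR SNP BP A1 A2 MAF BETA SE P N


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write the tab-delimited exchange format (10 significant digits)."""
    v = stats.variants
    df = pd.DataFrame(
        {
            "CHR": v["chrom"].to_numpy(),
            "SNP": v["variant_id"].to_numpy(),
            "BP": v["pos"].to_numpy(),
            "A1": v["a1"].to_numpy(),
            "A2": v["a2"].to_numpy(),
            "MAF": v["maf"].to_numpy(),
            "BETA": stats.beta_hat,
            "SE": stats.se,
            "P": stats.pval,
            "N": stats.n,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path, stratum: str = "ALL") -> SummaryStats:
    """Read the exchange format, validating header order and cell types.

    The scalar sample size is the maximum of the per-row N column.  Allele
    cells must be single characters in ACGT.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != SUMSTATS_COLUMNS:
        for i, col in enumerate(SUMSTATS_COLUMNS):
            if i >= len(header) or header[i] != col:
                raise FormatError(
                    f"summary-statistics header mismatch at column {i + 1}: "
                    f"expected '{col}', found '{header[i] if i < len(header) else '<missing>'}'")
        raise FormatError("summary-statistics header has extra columns")
    try:
        df = pd.read_csv(
            path, sep="\t",
            dtype={"CHR": np.int64, "SNP": str, "BP": np.int64, "A1": str, "A2": str,
                   "MAF": np.float64, "BETA": np.float64, "SE": np.float64,
                   "P": np.float64, "N": np.float64},
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"could not parse summary statistics: {exc}") from exc
    for col in ("A1", "A2"):
        bad = ~df[col].str.fullmatch("[ACGT]").fillna(False)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(f"invalid allele in column {col} at line {line}")
    variants = pd.DataFrame(
        {
            "variant_id": df["SNP"].to_numpy(),
            "chrom": df["CHR"].to_numpy(),
            "pos": df["BP"].to_numpy(),
            "a1": df["A1"].to_numpy(),
            "a2": df["A2"].to_numpy(),
            "maf": df["MAF"].to_numpy(),
            "block_id": np.zeros(len(df), dtype=np.int64),
        }
    )
    return SummaryStats(
        variants=variants,
        beta_hat=df["BETA"].to_numpy(),
        se=df["SE"].to_numpy(),
        pval=df["P"].to_numpy(),
        n=int(df["N"].max()),
        stratum=stratum,
    )
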