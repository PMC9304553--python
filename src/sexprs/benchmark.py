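"""Scenario grid orchestration, aggregation, and strategy recommendation.

``run_scenario`` executes the full pipeline per replicate — simulate panel,
draw architecture, generate phenotypes, run the three GWAS, build the 11-PRS
panel, evaluate test R² per sex — and aggregates across-replicate medians and
standard deviations.  ``recommend_strategy`` encodes the decision rules the
benchmark supports: which PRS strategy to prefer given genetic correlation,
per-sex sample sizes and heritabilities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import draw_effect_sizes, sample_causal_sets, simulate_phenotypes
from .evaluate import PRSBuildConfig, build_all_prs, _r2
from .exceptions import ConfigurationError
from .gwas import run_gwas
from .panel import estimate_ld, simulate_genotype_panel

logger = logging.getLogger(__name__)

STRATEGIES = (
    "sex-agnostic-LDpred2",
    "sex-agnostic-PRScs",
    "combined-LDpred2",
    "combined-PRScsx",
)


@dataclass
class ScenarioSpec:
    """One cell of the benchmark grid."""

    n_train_f: int
    n_train_m: int
    n_val_f: int = 1000
    n_val_m: int = 1000
    n_test_f: int = 1000
    n_test_m: int = 1000
    n_reference: int = 2000
    h2_f: float = 0.3
    h2_m: float = 0.3
    rg: float = 1.0
    p_causal: float = 0.001
    shared_fraction: float = 1.0
    m_variants: int = 10000
    block_size: int = 50
    rho: float = 0.6
    maf_low: float = 0.05
    maf_high: float = 0.5
    replicates: int = 10
    base_seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        counts = (self.n_train_f, self.n_train_m, self.n_val_f, self.n_val_m,
                  self.n_test_f, self.n_test_m, self.n_reference)
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all cohort counts must be positive")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not self.name:
            self.name = (f"n{self.n_train_f}/{self.n_train_m}"
                         f"_rg{self.rg}_h2{self.h2_f}/{self.h2_m}")

    def cohort_sizes(self) -> dict:
        half_ref = self.n_reference // 2
        return {
            ("F", "train"): self.n_train_f, ("M", "train"): self.n_train_m,
            ("F", "validation"): self.n_val_f, ("M", "validation"): self.n_val_m,
            ("F", "test"): self.n_test_f, ("M", "test"): self.n_test_m,
            ("F", "reference"): half_ref, ("M", "reference"): self.n_reference - half_ref,
        }

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class BenchmarkResult:
    """Tidy per-replicate R² table plus median/SD aggregates."""

    r2: pd.DataFrame          # columns: scenario, replicate, prs, sex, r2
    medians: pd.DataFrame     # index (scenario, prs), columns = sex
    sds: pd.DataFrame
    failures: list = field(default_factory=list)

    @staticmethod
    def aggregate(r2: pd.DataFrame):
        med = r2.pivot_table(index=["scenario", "prs"], columns="sex", values="r2",
                             aggfunc="median")
        sd = r2.pivot_table(index=["scenario", "prs"], columns="sex", values="r2",
                            aggfunc=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        return med, sd

    @classmethod
    def from_records(cls, records: list, failures: list | None = None) -> "BenchmarkResult":
        r2 = pd.DataFrame.from_records(records, columns=["scenario", "replicate", "prs", "sex", "r2"])
        med, sd = cls.aggregate(r2)
        return cls(r2=r2, medians=med, sds=sd, failures=failures or [])


def run_replicate(spec: ScenarioSpec, seed: int, config: PRSBuildConfig | None = None) -> dict:
    """One end-to-end replicate; returns {prs -> {sex -> test R²}}."""
    panel = simulate_genotype_panel(
        m_variants=spec.m_variants, block_size=spec.block_size, rho=spec.rho,
        maf_low=spec.maf_low, maf_high=spec.maf_high,
        cohort_sizes=spec.cohort_sizes(), seed=seed)
    causal = sample_causal_sets(spec.m_variants, spec.p_causal, spec.shared_fraction, seed=seed)
    arch = draw_effect_sizes(causal, spec.h2_f, spec.h2_m, spec.rg, seed=seed)
    pheno = simulate_phenotypes(panel, arch, seed=seed)
    ld = estimate_ld(panel, cohort="reference")
    stats = {s: run_gwas(panel, pheno, stratum=s) for s in ("F", "M", "ALL")}
    cfg = config or PRSBuildConfig()
    cfg.seed = seed
    prs_map = build_all_prs(panel, stats["F"], stats["M"], stats["ALL"], ld, pheno, cfg)

    rows_test = np.flatnonzero(panel.mask(cohort="test"))
    y_test = np.asarray(pheno.values)[rows_test]
    out: dict[str, dict[str, float]] = {}
    for name, per_sex in prs_map.items():
        out[name] = {}
        for sex, entry in per_sex.items():
            sub = entry["sex"] == sex
            out[name][sex] = _r2(entry["scores"][sub], y_test[sub])
    return out


def run_scenario(spec: ScenarioSpec, config: PRSBuildConfig | None = None,
                 budget_cells: float = 5e9) -> BenchmarkResult:
    """Run all replicates of a scenario and aggregate.

    Replicate r uses seed ``base_seed + r``; replicates are independent given
    their seeds, so any execution order yields the same aggregates.  A
    scenario fails only if more than half its replicates fail.
    """
    max_n = max(spec.n_train_f + spec.n_train_m, spec.n_val_f + spec.n_val_m)
    if spec.m_variants * max_n > budget_cells:
        logger.warning("scenario '%s' exceeds the desk-scale budget "
                       "(%d variants x %d individuals); expect long runtimes",
                       spec.name, spec.m_variants, max_n)
    records = []
    failures = []
    for r in range(spec.replicates):
        seed = spec.base_seed + r
        try:
            rep = run_replicate(spec, seed, config)
        except Exception as exc:  # recorded, scenario continues
            logger.error("replicate %d of scenario '%s' failed: %s", r, spec.name, exc)
            failures.append({"scenario": spec.name, "replicate": r, "error": repr(exc)})
            continue
        for prs, per_sex in rep.items():
            for sex, r2 in per_sex.items():
                records.append((spec.name, r, prs, sex, r2))
    if len(failures) > spec.replicates / 2:
        raise RuntimeError(f"scenario '{spec.name}': {len(failures)}/{spec.replicates} replicates failed")
    return BenchmarkResult.from_records(records, failures)


def run_scenarios(specs: list, config: PRSBuildConfig | None = None) -> BenchmarkResult:
    """Run several scenarios and concatenate their results."""
    results = [run_scenario(s, config) for s in specs]
    r2 = pd.concat([r.r2 for r in results], ignore_index=True)
    med, sd = BenchmarkResult.aggregate(r2)
    failures = [f for r in results for f in r.failures]
    return BenchmarkResult(r2=r2, medians=med, sds=sd, failures=failures)


@dataclass
class RecommendThresholds:
    """Interpretable cut-offs for the strategy flow chart.

    The verbal rules behind the flow chart never pin down numbers; these
    defaults are configurable interpretations: ``low_rg`` below which sexes
    are treated as genetically distinct, ``high_rg`` above which they are
    effectively identical, ``large_n`` per-sex training size at which
    continuous-shrinkage methods overtake the point-normal grid, ``small_n``
    below which pooling all samples dominates everything, ``unbalanced_ratio``
    the sample-size ratio that triggers the unbalanced branch, and
    ``h2_ratio`` the heritability ratio treated as a real sex difference.
    """

    low_rg: float = 0.8
    high_rg: float = 0.95
    large_n: int = 100_000
    small_n: int = 10_000
    unbalanced_ratio: float = 5.0
    h2_ratio: float = 2.0


def recommend_strategy(rg: float, n_f: int, n_m: int, h2_f: float, h2_m: float,
                       target_sex: str = "F",
                       thresholds: RecommendThresholds | None = None) -> str:
    """Recommended PRS strategy for one prediction target.

    Decision rules, in order: (1) small training samples -> pooled
    (sex-agnostic) LDpred2, since sample size dominates sex differences;
    (2) strongly unequal heritability -> combined sex-specific LDpred2 for the
    higher-h² sex, sex-agnostic LDpred2 for the lower; (3) very unbalanced
    sample sizes with low rg -> combined PRScsx for the smaller sex (it
    borrows strength from the larger), combined LDpred2 for the larger;
    (4) balanced and very large n -> sex-agnostic PRScs when rg ~ 1, combined
    PRScsx otherwise; (5) balanced mid-size n -> combined LDpred2 when rg is
    low, else sex-agnostic LDpred2.
    """
    t = thresholds or RecommendThresholds()
    if target_sex not in ("F", "M"):
        raise ConfigurationError("target_sex must be 'F' or 'M'")
    n_min, n_max = min(n_f, n_m), max(n_f, n_m)
    n_target = n_f if target_sex == "F" else n_m
    h2_target = h2_f if target_sex == "F" else h2_m
    h2_other = h2_m if target_sex == "F" else h2_f

    if n_min < t.small_n and n_max < t.small_n:
        return "sex-agnostic-LDpred2"
    if h2_other > 0 and max(h2_target, h2_other) / max(min(h2_target, h2_other), 1e-12) >= t.h2_ratio:
        return "combined-LDpred2" if h2_target >= h2_other else "sex-agnostic-LDpred2"
    if n_min > 0 and n_max / n_min >= t.unbalanced_ratio:
        if rg < t.low_rg and n_min >= t.small_n:
            return "combined-PRScsx" if n_target == n_min else "combined-LDpred2"
        return "sex-agnostic-LDpred2"
    # balanced branch
    if n_min >= t.large_n:
        return "sex-agnostic-PRScs" if rg >= t.high_rg else "combined-PRScsx"
    if rg < t.low_rg:
        return "combined-LDpred2"
    return "sex-agnostic-LDpred2"


PRS_GROUPS = {
    "Combined": ("PRScs-mult", "LDpred2-mult", "PRScsx-mult"),
    "Female-specific": ("PRScs-f", "LDpred2-f", "PRScsx-f"),
    "Male-specific": ("PRScs-m", "LDpred2-m", "PRScsx-m"),
    "Sex-agnostic": ("PRScs-all", "LDpred2-all"),
}


def render_report(result: BenchmarkResult, out_prefix: str) -> tuple:
    """Write a summary TSV and a machine-readable JSON of all cells.

    The TSV has one row per PRS (grouped Combined / Female-specific /
    Male-specific / Sex-agnostic) and one ``median (SD)`` cell per
    (scenario, test sex) column; per-column ranks (1 = best median) are
    emitted in the JSON.
    """
    if result.r2.empty:
        raise ConfigurationError("cannot render an empty benchmark result")
    med, sd = result.medians, result.sds
    scenarios = med.index.get_level_values("scenario").unique()
    sexes = list(med.columns)

    rows = []
    json_cells = []
    for group, names in PRS_GROUPS.items():
        for prs in names:
            row = {"group": group, "prs": prs}
            for sc in scenarios:
                for sex in sexes:
                    try:
                        m = med.loc[(sc, prs), sex]
                        s = sd.loc[(sc, prs), sex]
                    except KeyError:
                        continue
                    if pd.isna(m):
                        continue
                    col = f"{sc}|{sex}"
                    row[col] = f"{m:.4f} ({s:.4f})"
                    json_cells.append({"scenario": sc, "prs": prs, "sex": sex,
                                       "median": float(m), "sd": float(s)})
            if len(row) > 2:
                rows.append(row)
    table = pd.DataFrame(rows)
    # ranks within each (scenario, sex) column: 1 = largest median
    cells = pd.DataFrame(json_cells)
    cells["rank"] = cells.groupby(["scenario", "sex"])["median"].rank(
        ascending=False, method="min").astype(int)
    tsv_path = f"{out_prefix}.tsv"
    json_path = f"{out_prefix}.json"
    table.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(cells.to_dict(orient="records"), fh, indent=1)
    return tsv_path, json_path
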