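"""Genotype quality control: SNP and animal filters, mean-dosage imputation.

Stage order is fixed: SNP call rate -> MAF -> HWE -> LD prune ->
animal call rate -> animal heterozygosity -> imputation. MAF is
computed on genotyped entries only, before imputation. Missing
genotypes are imputed to twice the observed allele frequency (mean
dosage); model-based imputation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mbgp.data import GenotypeMatrix

LD_WINDOW = 100  # SNPs, in map order


@dataclass
class QCThresholds:
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-15
    ld_r2_max: float = 0.99
    animal_call_rate_min: float = 0.90
    het_max: float = 0.5

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class QCReport:
    """Per-stage removal bookkeeping; counts reconcile exactly."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, axis: str, removed: dict, before: int) -> None:
        self.stages.append({
            "stage": stage, "axis": axis, "removed": dict(removed),
            "n_before": before, "n_removed": len(removed),
            "n_after": before - len(removed),
        })

    def removed_ids(self, stage: str) -> list:
        for s in self.stages:
            if s["stage"] == stage:
                return sorted(s["removed"])
        raise KeyError(stage)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            for item, stat in s["removed"].items():
                rows.append({"stage": s["stage"], "axis": s["axis"],
                             "id": item, "statistic": stat})
        return pd.DataFrame(rows, columns=["stage", "axis", "id", "statistic"])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{k: s[k] for k in
                              ("stage", "axis", "n_before", "n_removed", "n_after")}
                             for s in self.stages])


def snp_call_rate(genotypes: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing entries per SNP."""
    if genotypes.n_animals < 1:
        raise ValueError("need at least one animal")
    return 1.0 - np.isnan(genotypes.dosages).mean(axis=0)


def animal_call_rate(genotypes: GenotypeMatrix) -> np.ndarray:
    if genotypes.n_snps < 1:
        raise ValueError("need at least one SNP")
    return 1.0 - np.isnan(genotypes.dosages).mean(axis=1)


def minor_allele_frequency(genotypes: GenotypeMatrix) -> np.ndarray:
    """MAF per SNP from genotyped entries only."""
    p = np.nanmean(genotypes.dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def hwe_exact_or_chisq(counts) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    proportions computed from the sample allele frequency.

    Monomorphic SNPs return p = 1 (no test possible).
    """
    n_aa, n_ab, n_bb = counts
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped animal")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = np.array([n * p ** 2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    X = genotypes.dosages
    out = np.empty(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        col = X[:, j]
        col = col[~np.isnan(col)]
        counts = (int((col == 2).sum()), int((col == 1).sum()),
                  int((col == 0).sum()))
        out[j] = hwe_exact_or_chisq(counts) if sum(counts) else 1.0
    return out


def _imputed_columns(X: np.ndarray) -> np.ndarray:
    means = np.nanmean(X, axis=0)
    out = X.copy()
    nan = np.isnan(out)
    out[nan] = np.broadcast_to(means, X.shape)[nan]
    return out


def ld_prune(genotypes: GenotypeMatrix, r2_max: float = 0.99,
             window: int = LD_WINDOW) -> list[str]:
    """Greedy LD prune in map order within a sliding window.

    Walking SNPs left to right, a SNP is dropped when its squared
    correlation with any retained SNP among the previous ``window``
    positions exceeds ``r2_max`` (the later SNP of the pair is the one
    dropped). Correlations are computed on mean-imputed dosages.
    """
    X = _imputed_columns(genotypes.dosages)
    sd = X.std(axis=0)
    Xc = (X - X.mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        Xs = np.where(sd > 0, Xc / sd, 0.0)
    n = X.shape[0]
    kept: list[int] = []
    for j in range(genotypes.n_snps):
        recent = [k for k in kept if j - k <= window]
        if recent and sd[j] > 0:
            r = Xs[:, recent].T @ Xs[:, j] / n
            if np.any(np.minimum(r ** 2, 1.0) > r2_max):
                continue
        kept.append(j)
    return [genotypes.snp_ids[j] for j in kept]


def heterozygosity(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-animal fraction of non-missing genotypes equal to 1."""
    X = genotypes.dosages
    het = (X == 1.0).sum(axis=1)
    called = (~np.isnan(X)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, het / called, 0.0)


def animal_filters(genotypes: GenotypeMatrix,
                   thresholds: QCThresholds | None = None) -> dict[str, tuple]:
    """Animals failing call rate or heterozygosity, with the statistic."""
    thresholds = thresholds or QCThresholds()
    cr = animal_call_rate(genotypes)
    het = heterozygosity(genotypes)
    removed = {}
    for i, a in enumerate(genotypes.animal_ids):
        if cr[i] < thresholds.animal_call_rate_min:
            removed[a] = ("call_rate", float(cr[i]))
        elif het[i] > thresholds.het_max:
            removed[a] = ("heterozygosity", float(het[i]))
    return removed


def impute_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Set each missing entry to the SNP's mean observed dosage (2p).

    Preserves per-SNP mean dosage exactly; errors on SNPs with no
    observed genotypes (those should have been filtered).
    """
    out = genotypes.copy()
    X = out.dosages
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [out.snp_ids[j] for j in np.where(all_missing)[0]]
        raise ValueError(f"SNPs with all genotypes missing: {bad[:5]}")
    out.dosages = _imputed_columns(X)
    return out


def run_qc(genotypes: GenotypeMatrix,
           thresholds: QCThresholds | None = None,
           ld_window: int = LD_WINDOW) -> tuple[GenotypeMatrix, QCReport]:
    """Apply all filters in the fixed stage order, then impute.

    Returns the clean matrix and a report recording every removal with
    the offending statistic.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    g = genotypes

    cr = snp_call_rate(g)
    removed = {g.snp_ids[j]: float(cr[j]) for j in
               np.where(cr < thresholds.snp_call_rate_min)[0]}
    report.add("snp_call_rate", "snp", removed, g.n_snps)
    g = g.subset(snp_ids=[s for s in g.snp_ids if s not in removed])

    maf = minor_allele_frequency(g)
    removed = {g.snp_ids[j]: float(maf[j]) for j in
               np.where(maf < thresholds.maf_min)[0]}
    report.add("maf", "snp", removed, g.n_snps)
    g = g.subset(snp_ids=[s for s in g.snp_ids if s not in removed])

    pvals = hwe_pvalues(g)
    removed = {g.snp_ids[j]: float(pvals[j]) for j in
               np.where(pvals < thresholds.hwe_p_min)[0]}
    report.add("hwe", "snp", removed, g.n_snps)
    g = g.subset(snp_ids=[s for s in g.snp_ids if s not in removed])

    kept = set(ld_prune(g, thresholds.ld_r2_max, window=ld_window))
    removed = {s: 1.0 for s in g.snp_ids if s not in kept}
    report.add("ld_prune", "snp", removed, g.n_snps)
    g = g.subset(snp_ids=[s for s in g.snp_ids if s in kept])

    bad = animal_filters(g, thresholds)
    cr_removed = {a: stat for a, (kind, stat) in bad.items()
                  if kind == "call_rate"}
    report.add("animal_call_rate", "animal", cr_removed, g.n_animals)
    g = g.subset(animal_ids=[a for a in g.animal_ids if a not in cr_removed])

    # recompute on surviving animals so the two stages stay disjoint
    bad = animal_filters(g, thresholds)
    het_removed = {a: stat for a, (kind, stat) in bad.items()
                   if kind == "heterozygosity"}
    report.add("animal_heterozygosity", "animal", het_removed, g.n_animals)
    g = g.subset(animal_ids=[a for a in g.animal_ids if a not in het_removed])

    if g.n_snps == 0 or g.n_animals == 0:
        raise ValueError("no SNPs or animals survive quality control")
    return impute_missing(g), report
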