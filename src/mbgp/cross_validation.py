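"""Across-sire-family cross-validation with accuracy, bias and
relatedness statistics broken down by sire breed.

Cohort-A sire families are shuffled and packed whole into validation
subsets of roughly the target size; cohort B is never validated and is
added to every reference set. Validation phenotypes are removed from
every model fit (including the fixed-effect adjustment step), which is
asserted on every fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mbgp.data import GenotypeMatrix, Pedigree, RelationshipMatrix
from mbgp.mixed_models import (Adjuster, MMESolver, ModelSpec, build_design,
                               reml_fit)
from mbgp import bayesr as bayesr_mod
from mbgp.relationships import relatedness_to_reference

METHODS = ("BLUP", "GBLUP", "BayesR")
SIRE_BREED_GROUPS = ("MER", "BL", "PD", "WS")
MIN_CELL_N = 10  # breed-group cells smaller than this are flagged unreliable


@dataclass
class CVDesign:
    subsets: list  # list of lists of cohort-A animal ids
    always_reference: list  # cohort-B animal ids, never validated
    target_subset_size: int
    seed: int

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def reference_for(self, fold_index: int) -> list:
        ref: list = []
        for k, subset in enumerate(self.subsets):
            if k != fold_index:
                ref.extend(subset)
        ref.extend(self.always_reference)
        return ref


@dataclass
class CVData:
    """Everything a fold needs: records, kernels and genotypes."""

    phenotypes: pd.DataFrame
    pedigree: Pedigree
    relationships: dict  # {"A": RelationshipMatrix, "G": RelationshipMatrix}
    genotypes: GenotypeMatrix | None = None  # needed for BayesR
    breed_composition: object = None


def make_subsets(pedigree: Pedigree, target_size: int = 500,
                 seed: int = 0) -> CVDesign:
    """Pack whole cohort-A sire families into validation subsets.

    Families are shuffled with ``seed`` and appended greedily; a subset
    is closed as soon as its size reaches ``target_size`` (so the first
    family crossing the target stays in that subset). The last subset
    may be small. No family is ever split.
    """
    cohort_a = pedigree.cohort("A")
    cohort_a = cohort_a[(cohort_a["sire_family"] != "")
                        & (cohort_a["role"] == "progeny")]
    families = cohort_a.groupby("sire_family")["animal_id"].apply(list)
    if len(families) < 2:
        raise ValueError("cohort A must contain at least 2 sire families")
    too_big = families[families.apply(len) > 2 * target_size]
    if len(too_big):
        raise ValueError(
            f"sire family {too_big.index[0]!r} has {len(too_big.iloc[0])} "
            f"progeny (> 2x target size {target_size}); increase target_size")
    rng = np.random.default_rng(seed)
    order = list(families.index)
    rng.shuffle(order)
    subsets: list[list] = []
    current: list = []
    for fam in order:
        current.extend(families[fam])
        if len(current) >= target_size:
            subsets.append(current)
            current = []
    if current:
        subsets.append(current)
    cohort_b = pedigree.cohort("B")
    cohort_b = cohort_b[(cohort_b["sire_family"] != "")
                        & (cohort_b["role"] == "progeny")]
    return CVDesign(subsets=subsets,
                    always_reference=cohort_b["animal_id"].tolist(),
                    target_subset_size=target_size, seed=seed)


def _assert_no_leakage(validation_ids, fitted_record_ids) -> None:
    leaked = set(validation_ids) & set(fitted_record_ids)
    if leaked:
        raise RuntimeError(
            f"leakage: validation phenotypes in fitted design: "
            f"{sorted(leaked)[:5]}")


def run_fold(design: CVDesign, fold_index: int, method: str, data: CVData,
             spec: ModelSpec, vc=None, bayesr_config=None,
             cache: dict | None = None) -> pd.DataFrame:
    """Fit one method with fold ``fold_index`` held out; return per-
    validation-animal predictions (columns ``g_hat``, ``a_hat``).

    ``vc`` fixes variance components (skipping per-fold REML).
    ``cache`` (a dict) reuses the MME factorisation of a fold/method
    across calls on the same design — only the phenotype values may
    change between calls.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    validation_ids = list(design.subsets[fold_index])
    vset = set(validation_ids)
    reference = data.phenotypes[~data.phenotypes["animal_id"].isin(vset)]
    _assert_no_leakage(validation_ids, reference["animal_id"])

    out = pd.DataFrame(index=validation_ids)
    out["g_hat"] = 0.0
    out["a_hat"] = 0.0

    if method in ("BLUP", "GBLUP"):
        key = (fold_index, method)
        if cache is not None and key in cache:
            solver, record_ids = cache[key]
            ref_indexed = reference.set_index("animal_id")
            y = ref_indexed.loc[record_ids, spec.response].to_numpy(dtype=float)
            solutions = solver.solve(y)
        else:
            dsg = build_design(reference, spec,
                               relationships=data.relationships,
                               breed_composition=data.breed_composition)
            _assert_no_leakage(validation_ids, dsg.record_ids)
            if vc is None:
                vc = reml_fit(dsg)
            solver = MMESolver(dsg, vc)
            solutions = solver.solve()
            if cache is not None:
                cache[key] = (solver, dsg.record_ids)
        for name, kind in spec.random_terms:
            if kind == "G":
                out["g_hat"] = solutions.random_effects[name].reindex(
                    validation_ids).to_numpy()
            elif kind == "A":
                out["a_hat"] = solutions.random_effects[name].reindex(
                    validation_ids).to_numpy()
    else:  # BayesR
        if data.genotypes is None:
            raise ValueError("BayesR folds need genotypes in CVData")
        if bayesr_config is None:
            raise ValueError("BayesR folds need a BayesRConfig")
        adj = Adjuster(reference, spec,
                       breed_composition=data.breed_composition)
        _assert_no_leakage(validation_ids, adj.design.record_ids)
        ystar_ref = adj.apply(reference)
        ref_geno = data.genotypes.subset(animal_ids=list(ystar_ref.index))
        posterior, _ = bayesr_mod.run_chains(ystar_ref.to_numpy(), ref_geno,
                                             bayesr_config)
        val_geno = data.genotypes.subset(animal_ids=validation_ids)
        gebv = (val_geno.dosages - posterior.col_means) @ posterior.mean_effect
        out["g_hat"] = gebv
    return out


def accuracy(predictions, observed, h: float) -> float:
    """Pearson correlation of predictions with observations, divided by
    ``h`` (square root of the model-1 heritability).

    Values above 1 are reported as computed. Returns NaN (with a
    warning) when the predictions have zero variance.
    """
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(predictions) | np.isnan(observed))
    predictions, observed = predictions[ok], observed[ok]
    if len(predictions) < 3:
        raise ValueError("need at least 3 paired records")
    if h <= 0:
        raise ValueError("h must be positive")
    if predictions.std() == 0 or observed.std() == 0:
        warnings.warn("zero-variance predictions or observations; "
                      "accuracy undefined")
        return float("nan")
    r = np.corrcoef(predictions, observed)[0, 1]
    return float(r / h)


def bias_regression(observed, predictions) -> tuple[float, float]:
    """OLS regression of observed on predicted: (slope, intercept).

    Slope 1 indicates calibrated (unbiased) predictions.
    """
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(predictions) | np.isnan(observed))
    predictions, observed = predictions[ok], observed[ok]
    if len(predictions) < 3:
        raise ValueError("need at least 3 paired records")
    var = predictions.var()
    if var == 0:
        warnings.warn("zero-variance predictions; bias undefined")
        return float("nan"), float("nan")
    slope = np.cov(observed, predictions, ddof=1)[0, 1] / \
        predictions.var(ddof=1)
    intercept = observed.mean() - slope * predictions.mean()
    return float(slope), float(intercept)


def split_by_sire_breed(fold_ids, pedigree: Pedigree) -> dict:
    """Assign each validation animal to its sire's breed group.

    A non-founder sire's breed is resolved through its paternal line
    (sires of purebred lines). Returns {"ALL": all ids, "MER": [...],
    ...}; animals whose sire has another breed (or no known breed)
    appear in ALL only.
    """
    sire_of = dict(zip(pedigree.table["animal_id"], pedigree.table["sire_id"]))
    breed_of = dict(zip(pedigree.table["animal_id"],
                        pedigree.table["founder_breed"]))

    def patriline_breed(animal: str) -> str:
        seen = set()
        while animal in breed_of and animal not in seen:
            if breed_of[animal]:
                return breed_of[animal]
            seen.add(animal)
            animal = sire_of.get(animal, "0")
        return ""

    groups: dict[str, list] = {"ALL": list(fold_ids)}
    for g in SIRE_BREED_GROUPS:
        groups[g] = []
    for animal in fold_ids:
        breed = patriline_breed(sire_of.get(animal, "0"))
        if breed in SIRE_BREED_GROUPS:
            groups[breed].append(animal)
    return groups


def evaluate_fold(predictions: pd.DataFrame, observed: dict,
                  fold_ids, pedigree: Pedigree, h: float,
                  G: RelationshipMatrix | None = None,
                  reference_ids=None) -> list[dict]:
    """Accuracy/bias/relatedness rows for one fold's predictions.

    ``observed`` maps response-type name ("phenotype"/"adjusted") to a
    Series indexed by animal id. Prediction types: "g" uses g_hat,
    "g+a" adds the polygenic solution.
    """
    groups = split_by_sire_breed(fold_ids, pedigree)
    related = None
    if G is not None and reference_ids is not None:
        related = relatedness_to_reference(
            G, fold_ids, [a for a in reference_ids
                          if a in set(G.ids)]).set_index("animal_id")
    rows = []
    # "g" only exists for genomic methods; pedigree BLUP yields a_hat
    # alone and is scored as its single combined prediction
    pred_types = {"g+a": predictions["g_hat"] + predictions["a_hat"]}
    if predictions["g_hat"].abs().max() > 0:
        pred_types["g"] = predictions["g_hat"]
    for response, obs in observed.items():
        for pred_name, pred in pred_types.items():
            for group, ids in groups.items():
                if not ids:
                    continue
                p = pred.reindex(ids)
                o = obs.reindex(ids)
                row = {"response": response, "prediction": pred_name,
                       "breed_group": group, "n": int(len(ids)),
                       "reliable": len(ids) >= MIN_CELL_N}
                try:
                    row["accuracy"] = accuracy(p, o, h)
                    row["slope"], row["intercept"] = bias_regression(o, p)
                except ValueError as err:
                    row.update(accuracy=float("nan"), slope=float("nan"),
                               intercept=float("nan"), reason=str(err))
                if related is not None:
                    sub = related.reindex(ids)
                    row["mean_sq"] = float(sub["mean_sq"].mean())
                    row["top10_mean"] = float(sub["top10_mean"].mean())
                rows.append(row)
    return rows


def run_cv(data: CVData, design: CVDesign, spec_by_method: dict, h: float,
           methods=("BLUP", "GBLUP"), vc_by_method: dict | None = None,
           bayesr_config=None, cache: dict | None = None) -> pd.DataFrame:
    """Run every fold for the requested methods; tidy results, one row
    per subset x method x response x prediction-type x breed group."""
    vc_by_method = vc_by_method or {}
    G = data.relationships.get("G")
    all_rows = []
    pheno = data.phenotypes.set_index("animal_id")
    for fold in range(design.n_subsets):
        fold_ids = list(design.subsets[fold])
        reference_ids = design.reference_for(fold)
        ref_records = data.phenotypes[
            ~data.phenotypes["animal_id"].isin(set(fold_ids))]
        for method in methods:
            spec = spec_by_method[method]
            preds = run_fold(design, fold, method, data, spec,
                             vc=vc_by_method.get(method),
                             bayesr_config=bayesr_config, cache=cache)
            adj = Adjuster(ref_records, spec,
                           breed_composition=data.breed_composition)
            observed = {
                "phenotype": pheno[spec.response].reindex(fold_ids),
                "adjusted": adj.apply(
                    data.phenotypes[
                        data.phenotypes["animal_id"].isin(set(fold_ids))]),
            }
            rows = evaluate_fold(preds, observed, fold_ids, data.pedigree, h,
                                 G=G, reference_ids=reference_ids)
            for row in rows:
                row.update(subset=fold, method=method)
            all_rows.extend(rows)
    return pd.DataFrame(all_rows)


def summarise(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of accuracy and slope across subsets for
    each method x response x prediction x breed group."""
    if results["subset"].nunique() < 2:
        raise ValueError("need at least 2 subsets to summarise")
    keys = ["method", "response", "prediction", "breed_group"]
    grouped = results.groupby(keys)

    def _se(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    out = grouped.agg(
        n_subsets=("subset", "nunique"),
        mean_accuracy=("accuracy", "mean"),
        se_accuracy=("accuracy", _se),
        mean_slope=("slope", "mean"),
        se_slope=("slope", _se),
    ).reset_index()
    return out
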