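"""Pedigree (A), genomic (G) and breed-composition (Q) matrices."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from mbgp.data import (UNKNOWN_PARENT, BreedComposition, GenotypeMatrix,
                       Pedigree, RelationshipMatrix)


def build_nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a(i,i) = 1 + 0.5 a(s,d); a(i,j) = 0.5 (a(j,s) + a(j,d)) for earlier
    j, with unknown parents contributing zero. Requires the pedigree to
    be topologically sorted (enforced by :class:`Pedigree`).
    """
    table = pedigree.table
    ids = table["animal_id"].tolist()
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = table["sire_id"].values
    dams = table["dam_id"].values
    for i in range(n):
        s = index.get(sires[i], -1) if sires[i] != UNKNOWN_PARENT else -1
        d = index.get(dams[i], -1) if dams[i] != UNKNOWN_PARENT else -1
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(ids=ids, values=A, kind="A")


def inbreeding_coefficients(A: RelationshipMatrix) -> np.ndarray:
    if A.kind != "A":
        raise ValueError("inbreeding requires a pedigree relationship matrix")
    return np.diag(A.values) - 1.0


def build_nrm_inverse(pedigree: Pedigree,
                      A: RelationshipMatrix | None = None) -> np.ndarray:
    """Direct A-inverse via Henderson's rules with inbreeding.

    O(n) assembly given the inbreeding coefficients (taken from the
    diagonal of A, computed if not supplied).
    """
    if A is None:
        A = build_nrm(pedigree)
    F = inbreeding_coefficients(A)
    table = pedigree.table
    ids = table["animal_id"].tolist()
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    Ainv = np.zeros((n, n))
    for i, (s_id, d_id) in enumerate(zip(table["sire_id"], table["dam_id"])):
        s = index[s_id] if s_id != UNKNOWN_PARENT else -1
        d = index[d_id] if d_id != UNKNOWN_PARENT else -1
        if s >= 0 and d >= 0:
            dvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            dvar = 0.75 - 0.25 * F[p]
        else:
            dvar = 1.0
        alpha = 1.0 / dvar
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= alpha / 2
                Ainv[p, i] -= alpha / 2
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += alpha / 4
    return Ainv


def build_grm(genotypes: GenotypeMatrix, freq_min: float = 0.005,
              variant: str = "yang") -> RelationshipMatrix:
    """Genomic relationship matrix from a complete dosage matrix.

    Allele frequencies are observed frequencies pooled over all
    genotyped animals (no within-breed adjustment). SNPs with pooled
    frequency below ``freq_min`` (or above 1 - ``freq_min``) are
    excluded.

    variant="yang": off-diagonals are the mean over SNPs of
    (x_i - 2p)(x_j - 2p) / (2p(1-p)); the diagonal uses the distinct
    estimator 1 + mean of (x^2 - (1+2p)x + 2p^2) / (2p(1-p)).

    variant="vanraden": G = Z Z' / m with Z the per-SNP standardised
    dosages (same for diagonal and off-diagonal); used for the
    SNP-BLUP equivalence route.
    """
    X = genotypes.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed before building G")
    p = X.mean(axis=0) / 2.0
    keep = (p >= freq_min) & (p <= 1.0 - freq_min)
    X = X[:, keep]
    p = p[keep]
    if X.shape[1] == 0:
        raise ValueError("no SNPs left after frequency exclusion")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic SNP survived frequency exclusion")
    m = X.shape[1]
    het = 2.0 * p * (1.0 - p)
    Z = (X - 2.0 * p) / np.sqrt(het)
    G = Z @ Z.T / m
    if variant == "yang":
        diag = 1.0 + ((X ** 2 - (1.0 + 2.0 * p) * X + 2.0 * p ** 2) / het
                      ).mean(axis=1)
        np.fill_diagonal(G, diag)
    elif variant != "vanraden":
        raise ValueError(f"unknown GRM variant {variant!r}")
    return RelationshipMatrix(ids=list(genotypes.animal_ids), values=G, kind="G")


def breed_composition_from_pedigree(pedigree: Pedigree) -> BreedComposition:
    """Breed fractions: founders are unit vectors on their labelled breed;
    every non-founder is the average of its parents' fractions."""
    table = pedigree.table
    ids = table["animal_id"].tolist()
    index = {a: i for i, a in enumerate(ids)}
    breeds = sorted({b for b in table["founder_breed"] if b})
    bidx = {b: k for k, b in enumerate(breeds)}
    n = len(ids)
    Q = np.zeros((n, len(breeds)))
    for i, row in enumerate(table.itertuples(index=False)):
        if row.sire_id == UNKNOWN_PARENT and row.dam_id == UNKNOWN_PARENT:
            if not row.founder_breed:
                raise ValueError(f"founder {row.animal_id!r} has no breed label")
            Q[i, bidx[row.founder_breed]] = 1.0
        else:
            if row.sire_id == UNKNOWN_PARENT or row.dam_id == UNKNOWN_PARENT:
                raise ValueError(
                    f"animal {row.animal_id!r} has exactly one known parent")
            Q[i] = 0.5 * (Q[index[row.sire_id]] + Q[index[row.dam_id]])
    return BreedComposition(ids=ids, breed_names=breeds, breed_fractions=Q)


def relatedness_to_reference(G: RelationshipMatrix, validation_ids,
                             reference_ids) -> pd.DataFrame:
    """Per validation animal: mean squared relationship to the reference
    set and mean of the 10 largest relationships."""
    validation_ids = list(validation_ids)
    reference_ids = list(reference_ids)
    if set(validation_ids) & set(reference_ids):
        raise ValueError("validation and reference ids must be disjoint")
    k = 10
    if len(reference_ids) < k:
        warnings.warn("reference smaller than 10; top-k uses all available")
        k = len(reference_ids)
    block = G.submatrix(validation_ids, reference_ids)
    mean_sq = (block ** 2).mean(axis=1)
    top = np.sort(block, axis=1)[:, -k:]
    return pd.DataFrame({"animal_id": validation_ids, "mean_sq": mean_sq,
                         "top10_mean": top.mean(axis=1)})
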