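"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

#: Fixed-effect factor columns carried on the pedigree table.
FACTOR_COLUMNS = ("sex", "birth_type", "rearing_type", "site", "birth_year",
                  "slaughter_group")


@dataclass
class GenotypeMatrix:
    """Animals x SNP dosage matrix with a marker map.

    Dosages are 0/1/2 counts of the alternate allele stored as float;
    missing genotypes are ``np.nan``.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        n, m = self.dosages.shape
        if n != len(self.animal_ids):
            raise ValueError(
                f"dosage rows ({n}) != number of animal ids ({len(self.animal_ids)})")
        if m != len(self.snp_ids):
            raise ValueError(
                f"dosage columns ({m}) != number of snp ids ({len(self.snp_ids)})")
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("marker map length does not match snp ids")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def animal_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.animal_ids)}

    def subset(self, animal_ids=None, snp_ids=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given animals and/or SNPs."""
        rows = np.arange(self.n_animals)
        cols = np.arange(self.n_snps)
        if animal_ids is not None:
            idx = self.animal_index()
            rows = np.array([idx[a] for a in animal_ids], dtype=int)
        if snp_ids is not None:
            sidx = {s: j for j, s in enumerate(self.snp_ids)}
            cols = np.array([sidx[s] for s in snp_ids], dtype=int)
        return GenotypeMatrix(
            animal_ids=[self.animal_ids[i] for i in rows],
            snp_ids=[self.snp_ids[j] for j in cols],
            chrom=self.chrom[cols],
            pos=self.pos[cols],
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            snp_ids=list(self.snp_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            dosages=self.dosages.copy(),
        )


@dataclass
class Pedigree:
    """Pedigree records with founder breed labels and fixed-effect factors.

    ``table`` columns: animal_id, sire_id, dam_id (``"0"`` = unknown),
    generation, founder_breed (empty for non-founders), sex, cohort
    ("A"/"B"), sire_family, and the factor columns in
    :data:`FACTOR_COLUMNS`. Rows are topologically sorted: parents
    precede offspring.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal_id", "sire_id", "dam_id", "generation",
                    "founder_breed", "sex", "cohort", "sire_family"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        if "role" not in self.table.columns:
            # founder / parent / progeny; only progeny carry phenotypes
            self.table = self.table.copy()
            self.table["role"] = np.where(
                self.table["sire_id"] == UNKNOWN_PARENT, "founder", "progeny")
        self._validate_order()

    def _validate_order(self) -> None:
        seen: set[str] = set()
        for row in self.table.itertuples(index=False):
            for parent in (row.sire_id, row.dam_id):
                if parent != UNKNOWN_PARENT and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {row.animal_id!r} does not precede it "
                        "(cycle or unsorted pedigree)")
            seen.add(row.animal_id)

    @property
    def animal_ids(self) -> list[str]:
        return self.table["animal_id"].tolist()

    @property
    def n_animals(self) -> int:
        return len(self.table)

    def founders(self) -> pd.DataFrame:
        t = self.table
        return t[(t["sire_id"] == UNKNOWN_PARENT) & (t["dam_id"] == UNKNOWN_PARENT)]

    def cohort(self, label: str) -> pd.DataFrame:
        return self.table[self.table["cohort"] == label]

    def progeny(self) -> pd.DataFrame:
        """Phenotyped-generation animals (members of a sire family)."""
        return self.table[self.table["role"] == "progeny"]

    def sire_of(self) -> dict[str, str]:
        return dict(zip(self.table["animal_id"], self.table["sire_id"]))


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix (pedigree A or genomic G)."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "A" or "G"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}

    def submatrix(self, row_ids, col_ids) -> np.ndarray:
        idx = self.index()
        r = [idx[a] for a in row_ids]
        c = [idx[a] for a in col_ids]
        return self.values[np.ix_(r, c)]


@dataclass
class BreedComposition:
    """Per-animal breed fractions derived from founder labels."""

    ids: list[str]
    breed_names: list[str]
    breed_fractions: np.ndarray  # animals x breeds, rows sum to 1

    def __post_init__(self) -> None:
        self.breed_fractions = np.asarray(self.breed_fractions, dtype=float)
        if self.breed_fractions.shape != (len(self.ids), len(self.breed_names)):
            raise ValueError("breed fraction shape mismatch")
        sums = self.breed_fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("breed fractions must sum to 1 per animal")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.breed_fractions, index=self.ids,
                            columns=self.breed_names)


@dataclass
class TrueValues:
    """Simulation ground truth for parameter-recovery tests."""

    snp_ids: list[str]
    marker_effects: np.ndarray
    marker_class: np.ndarray  # 1..4
    breeding_values: pd.Series = field(default=None)  # indexed by animal_id
    breed_effects: dict = field(default_factory=dict)
    fixed_effects: dict = field(default_factory=dict)
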