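"""Synthetic multi-breed data generation.

Generates a two-cohort pedigree (cohort A: many small sire families
sampled widely; cohort B: few large sire families), drops genotypes
through it from breed-specific founder allele frequencies, draws marker
effects from a four-component mixture, and builds phenotypes with fixed
effects, breed effects and a heritability-controlled residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mbgp.data import UNKNOWN_PARENT, GenotypeMatrix, Pedigree, TrueValues

DEFAULT_BREEDS = ("MER", "BL", "PD", "WS", "TXL", "SUF")

#: Default cohort-A sire breed mix: Merino-dominated with meat-breed sires.
DEFAULT_SIRE_BREED_PROPS = {
    "MER": 0.40, "BL": 0.15, "PD": 0.20, "WS": 0.15, "TXL": 0.05, "SUF": 0.05,
}

CLASS_VARIANCE_MULTIPLIERS = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class BreedModel:
    """Founder allele frequencies for a set of diverged breeds."""

    breed_names: list[str]
    fst: float
    ancestral_freqs: np.ndarray
    breed_freqs: np.ndarray  # breeds x SNPs

    @property
    def n_breeds(self) -> int:
        return len(self.breed_names)

    @property
    def n_snp(self) -> int:
        return self.ancestral_freqs.shape[0]

    def freqs_for(self, breed: str) -> np.ndarray:
        return self.breed_freqs[self.breed_names.index(breed)]


@dataclass
class SimConfig:
    """Knobs for the synthetic dataset generator."""

    n_snp: int = 1000
    n_chromosomes: int = 5
    morgans_per_chr: float = 1.0
    breed_names: tuple = DEFAULT_BREEDS
    fst: float = 0.1
    sire_breed_props: dict = field(default_factory=lambda: dict(DEFAULT_SIRE_BREED_PROPS))
    dam_breed: str = "MER"
    n_grandsires_A: int = 6  # sires come in paternal half-sib groups
    n_sires_A: int = 25
    family_size_A: int = 40
    n_sires_B: int = 20
    family_size_B: int = 100
    h2: float = 0.3
    h2_covariate: float = 0.59
    prop_classes: tuple = (0.95, 0.03, 0.015, 0.005)
    sigma_g2: float = 1.0
    polygenic_frac: float = 0.1
    mu: float = 10.0
    breed_effect_sd: float = 0.5
    fixed_effect_sds: dict = field(default_factory=lambda: {
        "sex": 0.3, "birth_type": 0.2, "rearing_type": 0.2,
        "contemporary_group": 0.4, "age_of_dam": 0.1,
    })
    age_effect: float = 0.01
    n_sites_A: int = 4
    n_sites_B: int = 1
    n_years: int = 2
    n_slaughter_groups: int = 3
    missing_rate: float = 0.0
    include_fixed_effects: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not math.isclose(sum(self.prop_classes), 1.0, abs_tol=1e-9):
            raise ValueError("prop_classes must sum to 1")
        if len(self.prop_classes) != 4:
            raise ValueError("prop_classes must have length 4")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if self.n_snp % self.n_chromosomes != 0:
            raise ValueError("n_snp must divide evenly across chromosomes")
        if self.family_size_A < 1 or self.family_size_B < 1:
            raise ValueError("sire families must be non-empty")
        if self.n_sires_A < 1 or self.n_sires_B < 1:
            raise ValueError("need at least one sire per cohort")


def simulate_breed_frequencies(n_snp: int, n_breeds: int, fst: float, seed: int,
                               breed_names=None) -> BreedModel:
    """Draw per-breed allele frequencies around shared ancestral ones.

    Balding-Nichols model: for ancestral frequency p the breed frequency
    is Beta(p(1-F)/F, (1-p)(1-F)/F), giving between-breed variance
    F*p*(1-p). ``fst = 0`` returns the ancestral frequencies unchanged.
    """
    if not 0.0 <= fst <= 0.5:
        raise ValueError(f"fst must be in [0, 0.5], got {fst}")
    if n_snp < 1:
        raise ValueError("n_snp must be >= 1")
    if n_breeds < 2:
        raise ValueError("need n_breeds >= 2 to exercise breed regression")
    if breed_names is None:
        breed_names = [f"B{i + 1}" for i in range(n_breeds)]
    breed_names = list(breed_names)
    if len(breed_names) != n_breeds:
        raise ValueError("breed_names length must equal n_breeds")

    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.1, 0.9, size=n_snp)
    if fst == 0.0:
        breed_freqs = np.tile(ancestral, (n_breeds, 1))
    else:
        scale = (1.0 - fst) / fst
        a = ancestral * scale
        b = (1.0 - ancestral) * scale
        breed_freqs = rng.beta(a, b, size=(n_breeds, n_snp))
        breed_freqs = np.clip(breed_freqs, 1e-6, 1.0 - 1e-6)
    return BreedModel(breed_names=breed_names, fst=fst,
                      ancestral_freqs=ancestral, breed_freqs=breed_freqs)


def _assign_factors(rng: np.random.Generator, n: int, cohort: str,
                    config: SimConfig) -> dict:
    sites = ([f"A{i + 1}" for i in range(config.n_sites_A)] if cohort == "A"
             else [f"B{i + 1}" for i in range(config.n_sites_B)])
    return {
        "sex": rng.choice(["M", "F"], size=n),
        "birth_type": rng.choice([1, 2, 3], size=n, p=[0.3, 0.55, 0.15]),
        "rearing_type": rng.choice([1, 2], size=n, p=[0.45, 0.55]),
        "site": rng.choice(sites, size=n),
        "birth_year": rng.choice(np.arange(2007, 2007 + config.n_years), size=n),
        "slaughter_group": rng.choice(np.arange(1, config.n_slaughter_groups + 1),
                                      size=n),
    }


def simulate_pedigree(config: SimConfig, breed_model: BreedModel) -> Pedigree:
    """Build the two-cohort pedigree with crossbred and purebred matings.

    Cohort A sires descend from a small set of purebred grandsires drawn
    from ``sire_breed_props`` (Merino plus meat breeds), so sires form
    paternal half-sib groups and families stay genetically connected
    across validation subsets. Cohort B uses ``n_sires_B`` founder sires
    with large progeny groups. All dams are founders of ``dam_breed``,
    one dam per progeny.
    """
    config.validate()
    for breed in config.sire_breed_props:
        if breed not in breed_model.breed_names:
            raise ValueError(f"sire breed {breed!r} not in breed model")
    if config.dam_breed not in breed_model.breed_names:
        raise ValueError(f"dam breed {config.dam_breed!r} not in breed model")

    rng = np.random.default_rng(config.seed + 1)
    rows: list[dict] = []

    def add_animal(animal_id, sire_id, dam_id, generation, breed, sex,
                   cohort, role, sire_family="", factors=None, k=0) -> None:
        row = {
            "animal_id": animal_id, "sire_id": sire_id, "dam_id": dam_id,
            "generation": generation, "founder_breed": breed, "sex": sex,
            "cohort": cohort, "sire_family": sire_family, "role": role,
            "birth_type": 0, "rearing_type": 0, "site": "",
            "birth_year": 0, "slaughter_group": 0,
        }
        if factors is not None:
            row.update(birth_type=int(factors["birth_type"][k]),
                       rearing_type=int(factors["rearing_type"][k]),
                       site=factors["site"][k],
                       birth_year=int(factors["birth_year"][k]),
                       slaughter_group=int(factors["slaughter_group"][k]))
        rows.append(row)

    breeds = list(config.sire_breed_props)
    probs = np.array([config.sire_breed_props[b] for b in breeds], dtype=float)
    probs = probs / probs.sum()

    plan = []  # (cohort, sire_id, family_size)
    # grandsire layer: each grandsire heads a purebred half-sib sire group
    n_gs = max(1, min(config.n_grandsires_A, config.n_sires_A))
    gs_breeds = [rng.choice(breeds, p=probs) for _ in range(n_gs)]
    for g, breed in enumerate(gs_breeds):
        add_animal(f"A_GS{g + 1}", UNKNOWN_PARENT, UNKNOWN_PARENT, 0, breed,
                   "M", "A", "founder")
    for s in range(config.n_sires_A):
        g = s % n_gs
        gdam_id = f"A_GD{s + 1}"
        add_animal(gdam_id, UNKNOWN_PARENT, UNKNOWN_PARENT, 0, gs_breeds[g],
                   "F", "A", "founder")
        sire_id = f"A_S{s + 1}"
        add_animal(sire_id, f"A_GS{g + 1}", gdam_id, 1, "", "M", "A",
                   "parent", sire_family=f"A_GS{g + 1}")
        size = max(1, int(rng.poisson(config.family_size_A)))
        plan.append(("A", sire_id, size))
    for s in range(config.n_sires_B):
        sire_id = f"B_S{s + 1}"
        add_animal(sire_id, UNKNOWN_PARENT, UNKNOWN_PARENT, 0,
                   rng.choice(breeds, p=probs), "M", "B", "founder")
        plan.append(("B", sire_id, config.family_size_B))

    dam_counter = 0
    progeny_counter = 0
    for cohort, sire_id, size in plan:
        if size < 1:
            raise ValueError(f"sire family {sire_id} would be empty")
        factors = _assign_factors(rng, size, cohort, config)
        generation = 2 if cohort == "A" else 1
        for k in range(size):
            dam_counter += 1
            dam_id = f"D{dam_counter}"
            add_animal(dam_id, UNKNOWN_PARENT, UNKNOWN_PARENT, 0,
                       config.dam_breed, "F", cohort, "founder")
            progeny_counter += 1
            add_animal(f"{cohort}{progeny_counter}", sire_id, dam_id,
                       generation, "", factors["sex"][k], cohort, "progeny",
                       sire_family=sire_id, factors=factors, k=k)
    return Pedigree(table=pd.DataFrame(rows))


@dataclass
class GeneDropResult:
    genotypes: GenotypeMatrix
    haplotypes: np.ndarray  # animals x 2 x SNPs, int8
    chrom_bounds: list  # (start, stop) column slices per chromosome


def _snp_map(n_snp: int, n_chromosomes: int, morgans_per_chr: float):
    per_chr = n_snp // n_chromosomes
    chrom = np.repeat(np.arange(1, n_chromosomes + 1), per_chr)
    gpos = np.tile(np.linspace(0.0, morgans_per_chr, per_chr, endpoint=False)
                   + morgans_per_chr / (2 * per_chr), n_chromosomes)
    pos = np.round(gpos * 1e8).astype(np.int64) + 1  # 1 Morgan ~ 100 Mb
    return chrom, gpos, pos


def gene_drop(pedigree: Pedigree, breed_model: BreedModel, n_chromosomes: int,
              morgans_per_chr: float, seed: int) -> GeneDropResult:
    """Drop founder haplotypes through the pedigree with recombination.

    Founder haplotypes are Bernoulli draws from the founder's breed
    frequencies. Each meiosis places a Poisson(``morgans_per_chr``)
    number of crossovers uniformly on the chromosome (Haldane map, no
    interference). With ``morgans_per_chr = 0`` every transmitted
    chromosome is an exact copy of one parental haplotype.
    """
    n_snp = breed_model.n_snp
    if n_snp % n_chromosomes != 0:
        raise ValueError("n_snp must divide evenly across chromosomes")
    chrom, gpos, pos = _snp_map(n_snp, n_chromosomes, morgans_per_chr)
    per_chr = n_snp // n_chromosomes
    bounds = [(c * per_chr, (c + 1) * per_chr) for c in range(n_chromosomes)]
    chr_gpos = gpos[:per_chr]

    rng = np.random.default_rng(seed)
    table = pedigree.table
    index = {a: i for i, a in enumerate(table["animal_id"])}
    n = len(table)
    haps = np.zeros((n, 2, n_snp), dtype=np.int8)

    def gamete(parent_haps: np.ndarray) -> np.ndarray:
        out = np.empty(n_snp, dtype=np.int8)
        for start, stop in bounds:
            k = rng.poisson(morgans_per_chr)
            first = rng.integers(2)
            if k == 0:
                out[start:stop] = parent_haps[first, start:stop]
            else:
                xpos = np.sort(rng.uniform(0.0, morgans_per_chr, size=k))
                strand = (first + np.searchsorted(xpos, chr_gpos)) % 2
                seg = parent_haps[:, start:stop]
                out[start:stop] = seg[strand, np.arange(stop - start)]
        return out

    for i, row in enumerate(table.itertuples(index=False)):
        if row.sire_id == UNKNOWN_PARENT and row.dam_id == UNKNOWN_PARENT:
            if not row.founder_breed:
                raise ValueError(f"founder {row.animal_id!r} lacks a breed label")
            p = breed_model.freqs_for(row.founder_breed)
            haps[i] = (rng.random((2, n_snp)) < p).astype(np.int8)
        elif row.sire_id == UNKNOWN_PARENT or row.dam_id == UNKNOWN_PARENT:
            raise ValueError(
                f"non-founder {row.animal_id!r} is missing a parent")
        else:
            haps[i, 0] = gamete(haps[index[row.sire_id]])
            haps[i, 1] = gamete(haps[index[row.dam_id]])

    snp_ids = [f"SNP{c}_{j + 1}" for c, j in zip(chrom, np.tile(np.arange(per_chr),
                                                                n_chromosomes))]
    genotypes = GenotypeMatrix(
        animal_ids=table["animal_id"].tolist(), snp_ids=snp_ids,
        chrom=chrom, pos=pos, dosages=haps.sum(axis=1).astype(float))
    return GeneDropResult(genotypes=genotypes, haplotypes=haps,
                          chrom_bounds=bounds)


def draw_marker_effects(n_snp: int, prop_classes, sigma_g2: float,
                        seed: int) -> TrueValues:
    """Assign each SNP to one of four effect classes and draw its effect.

    Class variances are (0, 1e-4, 1e-3, 1e-2) x ``sigma_g2``; class-1
    effects are exactly zero.
    """
    prop_classes = np.asarray(prop_classes, dtype=float)
    if prop_classes.shape != (4,):
        raise ValueError("prop_classes must have length 4")
    if (prop_classes < 0).any():
        raise ValueError("prop_classes must be non-negative")
    if not math.isclose(prop_classes.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("prop_classes must sum to 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(4, size=n_snp, p=prop_classes) + 1
    variances = np.array(CLASS_VARIANCE_MULTIPLIERS) * sigma_g2
    effects = np.zeros(n_snp)
    for c in (2, 3, 4):
        mask = classes == c
        effects[mask] = rng.normal(0.0, math.sqrt(variances[c - 1]),
                                   size=mask.sum())
    return TrueValues(snp_ids=[f"snp{j}" for j in range(n_snp)],
                      marker_effects=effects, marker_class=classes)


def simulate_phenotypes(pedigree: Pedigree, genotypes: GenotypeMatrix,
                        true_values: TrueValues, config: SimConfig,
                        include_fixed_effects: bool = True) -> pd.DataFrame:
    """Build the phenotype table for generation >= 1 animals.

    y = mu + fixed effects + breed effects + TBV + residual, where
    TBV = centred dosages x marker effects plus an iid polygenic
    remainder, and the residual variance is set so the realised
    narrow-sense heritability var(TBV)/(var(TBV)+sigma_e2) equals
    ``config.h2``. Also emits a genetically correlated carcass-weight
    style covariate (``hcwt``) with heritability ``h2_covariate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    table = pedigree.table
    dos = genotypes.dosages
    if np.isnan(dos).any():
        raise ValueError("genotypes must be complete for phenotype simulation")

    centred = dos - dos.mean(axis=0)
    g_marker = centred @ true_values.marker_effects
    var_marker = g_marker.var()
    if var_marker > 0 and config.polygenic_frac > 0:
        poly_var = var_marker * config.polygenic_frac / (1 - config.polygenic_frac)
        poly = rng.normal(0.0, math.sqrt(poly_var), size=len(table))
    else:
        poly = np.zeros(len(table))
    tbv = g_marker + poly
    true_values.breeding_values = pd.Series(tbv, index=table["animal_id"].values)

    var_g = tbv.var()
    sigma_e2 = var_g * (1 - config.h2) / config.h2  # 0 when no genetic signal

    # breed effects via pedigree-derived breed fractions
    from mbgp.relationships import breed_composition_from_pedigree
    comp = breed_composition_from_pedigree(pedigree)
    breed_effects = rng.normal(0.0, config.breed_effect_sd,
                               size=len(comp.breed_names))
    true_values.breed_effects = dict(zip(comp.breed_names, breed_effects))
    breed_part = comp.breed_fractions @ breed_effects

    mask = (table["role"] == "progeny").values
    sub = table[mask].reset_index(drop=True)
    n = len(sub)
    age = rng.normal(300.0, 20.0, size=n)

    fixed_part = np.zeros(n)
    true_fixed: dict[str, dict] = {}
    if include_fixed_effects:
        cg = (sub["birth_year"].astype(str) + "x" + sub["site"].astype(str)
              + "x" + sub["slaughter_group"].astype(str))
        factor_values = {
            "sex": sub["sex"], "birth_type": sub["birth_type"],
            "rearing_type": sub["rearing_type"], "contemporary_group": cg,
        }
        for name, values in factor_values.items():
            sd = config.fixed_effect_sds.get(name, 0.0)
            levels = sorted(values.unique())
            eff = dict(zip(levels, rng.normal(0.0, sd, size=len(levels))))
            true_fixed[name] = eff
            fixed_part += values.map(eff).values
        # age-of-dam effect: cohort-A records only
        aod = rng.choice([2, 3, 4, 5], size=n)
        aod_sd = config.fixed_effect_sds.get("age_of_dam", 0.0)
        aod_eff = dict(zip([2, 3, 4, 5], rng.normal(0.0, aod_sd, size=4)))
        true_fixed["age_of_dam"] = aod_eff
        is_a = (sub["cohort"] == "A").values
        fixed_part += np.where(is_a, pd.Series(aod).map(aod_eff).values, 0.0)
        fixed_part += config.age_effect * (age - age.mean())
    else:
        aod = np.zeros(n, dtype=int)
    true_values.fixed_effects = true_fixed

    e = rng.normal(0.0, math.sqrt(sigma_e2), size=n)
    y = (config.mu + fixed_part + breed_part[mask] + tbv[mask] + e)

    # correlated covariate trait (carcass-weight stand-in), own heritability
    h2c = config.h2_covariate
    sd_tbv = tbv[mask].std() if tbv[mask].std() > 0 else 1.0
    g_cov = tbv[mask] / sd_tbv * math.sqrt(h2c)
    hcwt = 22.0 + 3.6 * (g_cov + rng.normal(0.0, math.sqrt(1 - h2c), size=n))

    out = sub[["animal_id", "sex", "birth_type", "rearing_type", "site",
               "birth_year", "slaughter_group", "cohort", "sire_family"]].copy()
    out["contemporary_group"] = (out["birth_year"].astype(str) + "x"
                                 + out["site"].astype(str) + "x"
                                 + out["slaughter_group"].astype(str))
    out["age"] = age
    out["age_of_dam"] = aod
    out["trait"] = y
    out["hcwt"] = hcwt
    out["dataset"] = out["cohort"]
    return out


def standardise_within_dataset(phenotypes: pd.DataFrame, trait: str,
                               group_field: str) -> pd.DataFrame:
    """Centre and scale ``trait`` to mean 0, sample SD 1 within each group.

    Uses the n-1 (sample) standard deviation. Other columns are left
    untouched. Groups with zero variance or fewer than two non-missing
    records raise a ``ValueError`` naming the group.
    """
    out = phenotypes.copy()
    for group, idx in out.groupby(group_field).groups.items():
        vals = out.loc[idx, trait]
        ok = vals.notna()
        if ok.sum() < 2:
            raise ValueError(
                f"group {group!r} has fewer than 2 non-missing records")
        sd = vals[ok].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"group {group!r} has zero variance in {trait!r}")
        out.loc[idx, trait] = (vals - vals[ok].mean()) / sd
    return out


def inject_missingness_and_contamination(
        genotypes: GenotypeMatrix, missing_rate: float,
        bad_snp_ids=(), bad_animal_ids=(), seed: int = 0,
        contaminated_animal_id: str | None = None,
        planted_call_rate: float = 0.05,
        contaminated_het: float = 0.7) -> GenotypeMatrix:
    """Plant QC failures: background missingness, low-call-rate SNPs and
    animals, and one high-heterozygosity (contaminated) animal."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if not 0.0 <= planted_call_rate <= 1.0:
        raise ValueError("planted_call_rate must be in [0, 1]")
    out = genotypes.copy()
    sidx = {s: j for j, s in enumerate(out.snp_ids)}
    aidx = out.animal_index()
    for s in bad_snp_ids:
        if s not in sidx:
            raise KeyError(f"unknown SNP id {s!r}")
    for a in bad_animal_ids:
        if a not in aidx:
            raise KeyError(f"unknown animal id {a!r}")
    if contaminated_animal_id is not None and contaminated_animal_id not in aidx:
        raise KeyError(f"unknown animal id {contaminated_animal_id!r}")

    rng = np.random.default_rng(seed)
    if missing_rate > 0:
        drop = rng.random(out.dosages.shape) < missing_rate
        out.dosages[drop] = np.nan
    for s in bad_snp_ids:
        j = sidx[s]
        drop = rng.random(out.n_animals) >= planted_call_rate
        out.dosages[drop, j] = np.nan
    for a in bad_animal_ids:
        i = aidx[a]
        drop = rng.random(out.n_snps) >= planted_call_rate
        out.dosages[i, drop] = np.nan
    if contaminated_animal_id is not None:
        i = aidx[contaminated_animal_id]
        het = rng.random(out.n_snps) < contaminated_het
        row = out.dosages[i]
        row[het] = 1.0
        homo = ~het & ~np.isnan(row)
        row[homo] = np.where(rng.random(homo.sum()) < 0.5, 0.0, 2.0)
    return out


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    breed_model: BreedModel
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    haplotypes: np.ndarray
    true_values: TrueValues
    phenotypes: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: breeds -> pedigree -> genotypes -> phenotypes."""
    config.validate()
    breed_model = simulate_breed_frequencies(
        config.n_snp, len(config.breed_names), config.fst, config.seed,
        breed_names=config.breed_names)
    pedigree = simulate_pedigree(config, breed_model)
    drop = gene_drop(pedigree, breed_model, config.n_chromosomes,
                     config.morgans_per_chr, config.seed + 3)
    true_values = draw_marker_effects(config.n_snp, config.prop_classes,
                                      config.sigma_g2, config.seed + 4)
    true_values.snp_ids = list(drop.genotypes.snp_ids)
    phenotypes = simulate_phenotypes(
        pedigree, drop.genotypes, true_values, config,
        include_fixed_effects=config.include_fixed_effects)
    genotypes = drop.genotypes
    if config.missing_rate > 0:
        genotypes = inject_missingness_and_contamination(
            genotypes, config.missing_rate, seed=config.seed + 5)
    return SimulatedDataset(config=config, breed_model=breed_model,
                            pedigree=pedigree, genotypes=genotypes,
                            haplotypes=drop.haplotypes,
                            true_values=true_values, phenotypes=phenotypes)
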