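import numpy as np
import pandas as pd
import pytest

from mbgp.data import Pedigree
from mbgp.simulate import SimConfig, simulate_dataset


def ped_row(animal_id, sire_id="0", dam_id="0", generation=0,
            founder_breed="", sex="M", cohort="A", sire_family="",
            birth_type=1, rearing_type=1, site="A1", birth_year=2007,
            slaughter_group=1):
    return dict(animal_id=animal_id, sire_id=sire_id, dam_id=dam_id,
                generation=generation, founder_breed=founder_breed, sex=sex,
                cohort=cohort, sire_family=sire_family, birth_type=birth_type,
                rearing_type=rearing_type, site=site, birth_year=birth_year,
                slaughter_group=slaughter_group)


def make_pedigree(rows):
    return Pedigree(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_snp=500, n_chromosomes=5, n_sires_A=12,
                     family_size_A=15, n_sires_B=4, family_size_B=25, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def cv_dataset():
    """Stronger-signal dataset for cross-validation behaviour tests:
    no fixed/breed effects, h2 = 0.5, many causal SNPs."""
    cfg = SimConfig(n_snp=500, n_chromosomes=5, n_sires_A=20,
                    family_size_A=20, n_sires_B=4, family_size_B=25,
                    h2=0.5, seed=19, include_fixed_effects=False,
                    breed_effect_sd=0.0,
                    prop_classes=(0.5, 0.3, 0.15, 0.05))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def founder_genotypes():
    """Unstructured founder-population genotypes (no families)."""
    rng = np.random.default_rng(42)
    n, m = 300, 400
    p = rng.uniform(0.1, 0.9, m)
    from mbgp.data import GenotypeMatrix
    return GenotypeMatrix(
        animal_ids=[f"f{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        chrom=np.repeat(np.arange(1, 5), m // 4),
        pos=np.tile(np.arange(1, m // 4 + 1) * 1000, 4),
        dosages=rng.binomial(2, p, size=(n, m)).astype(float))
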