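import dataclasses

import pytest

from hircus.pedigree import Pedigree, PedigreeRecord, relationship_matrix
from hircus.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale synthetic cohort (1538 kids) shared across tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A small cohort for quick model fits: 250 kids, 25 sires, 120 dams."""
    cfg = SimulationConfig(n_kids=250, n_dams=120, n_sires=25, n_herds=6, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_growth_chain(small_dataset):
    """A short fitted growth chain reused by summary/invariant tests."""
    from hircus.growth_model import ModelSpec, build_design, gibbs_chain

    ped, rec = small_dataset
    design = build_design(rec, ped, ModelSpec(trait_pair=("bw", "cg")))
    A = relationship_matrix(ped)
    return gibbs_chain(design, A, n_iter=3000, burn_in=500, thin=5, seed=21)


@pytest.fixture(scope="session")
def small_survival_chain(small_dataset):
    from hircus.pedigree import relationship_matrix
    from hircus.survival_model import aft_gibbs_chain, censor_records

    ped, rec = small_dataset
    design = censor_records(rec, ped)
    A = relationship_matrix(ped)
    return aft_gibbs_chain(design, A, n_iter=3000, burn_in=500, thin=5, seed=22)


@pytest.fixture(scope="session")
def calibration_cohorts():
    """Twenty default-settings cohorts (seeds 0..19) for calibration checks."""
    return [simulate_dataset(SimulationConfig(seed=s)) for s in range(20)]


def trio_pedigree():
    return Pedigree(
        [
            PedigreeRecord("sire"),
            PedigreeRecord("dam"),
            PedigreeRecord("kid", "sire", "dam"),
        ]
    )


def no_contrast_config(**overrides) -> SimulationConfig:
    """Generator settings with zero fixed contrasts and full retention."""
    base = dict(
        sex_contrast=0.0,
        birth_type_contrast=0.0,
        attrition={a: 1.0 for a in ("birth", "3mo", "6mo", "9mo", "12mo")},
    )
    base.update(overrides)
    cfg = SimulationConfig(**base)
    # push the survival scale up so nobody dies (pure growth experiments)
    sp = dataclasses.replace(cfg.survival, intercept=20.0)
    return dataclasses.replace(cfg, survival=sp)
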