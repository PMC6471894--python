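import numpy as np
import pandas as pd
import pytest

from pedimpute.core import GenotypeMatrix, Pedigree, PedigreeRecord
from pedimpute.simulate import (
    Cross,
    SimConfig,
    StudyDesign,
    simulate_study,
)


def make_gm(dosage, chrom=None, pos=None, samples=None, **kwargs) -> GenotypeMatrix:
    from pedimpute.core import genotype_matrix_from_arrays

    dosage = np.asarray(dosage, dtype=np.int8)
    m = dosage.shape[1]
    if chrom is None:
        chrom = ["chr1"] * m
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    return genotype_matrix_from_arrays(chrom, pos, dosage, samples=samples, **kwargs)


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree(
        records=[
            PedigreeRecord("sire1", None, None, "Factorial_parents"),
            PedigreeRecord("dam1", None, None, "Factorial_parents"),
            PedigreeRecord("kid1", "sire1", "dam1", "Factorial_progenies"),
        ]
    )


@pytest.fixture
def tiny_design() -> StudyDesign:
    return StudyDesign(
        factorial_females=["F1"],
        factorial_males=["M1"],
        factorial_crosses=[Cross("F1", "M1", 4)],
        multipair_females=[],
        multipair_males=[],
        multipair_crosses=[],
        dual_role_females={},
        n_unrelated=2,
        grandparent_of=None,
        n_sequenced_progenies=2,
    )


@pytest.fixture
def small_config(tiny_design) -> SimConfig:
    return SimConfig(
        n_chrom=1,
        chrom_length_bp=2_000_000,
        n_seq_sites=400,
        chip_fraction=0.05,
        design=tiny_design,
        seed=7,
    )


@pytest.fixture
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def study_scale_run():
    """One study-shaped simulation + evaluation shared by slower tests."""
    from pedimpute.evaluate import evaluate_imputation
    from pedimpute.imputers import fill_chip_missing

    cfg = SimConfig(n_seq_sites=4000, chip_fraction=0.02, seed=11)
    study = simulate_study(cfg)
    chip = study.chip_all.take_samples(study.reference_ids)
    chip, _ = fill_chip_missing(chip, study.pedigree, seed=11)
    ev = evaluate_imputation(study.haps_ref, chip, study.pedigree, seed=11)
    return {"study": study, "chip": chip, "ev": ev}
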