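"""Shared fixtures: small simulated populations and design helpers."""

import warnings

import numpy as np
import pandas as pd
import pytest

import ovinepred as op

# the MME ridge warning on singular marker G is expected throughout
warnings.filterwarnings("ignore", message=".*relationship matrix not positive definite.*")


@pytest.fixture(scope="session")
def small_multibreed():
    """Four-breed crossbred population, small but structurally complete."""
    cfg = op.PopulationConfig(
        n_snps_dense=1500,
        n_reference=400,
        n_founders_per_breed=60,
        divergence_generations=20,
        effective_size=60,
        n_qtl=150,
        n_validation_sires_per_breed=8,
        seed=42,
    )
    geno, ped, truth = op.simulate_population(cfg)
    design = op.simulate_phenotypes(geno, ped, truth, cfg, seed=43)
    return cfg, geno, ped, truth, design


@pytest.fixture(scope="session")
def small_singlebreed():
    """Single-breed population with family structure (half-sib groups)."""
    cfg = op.PopulationConfig(
        n_breeds=1,
        breed_labels=("Merino",),
        n_snps_dense=1500,
        n_reference=500,
        n_founders_per_breed=120,
        divergence_generations=20,
        effective_size=80,
        n_qtl=150,
        var_breed=0.0,
        n_validation_sires_per_breed=20,
        distant_generations=4,
        seed=7,
    )
    geno, ped, truth = op.simulate_population(cfg)
    design = op.simulate_phenotypes(geno, ped, truth, cfg, seed=8)
    return cfg, geno, ped, truth, design


def unstructured_design(y, ids, breed="M"):
    """Minimal design (intercept only) over unrelated individuals."""
    ids = np.asarray(ids, dtype=object)
    ped = op.Pedigree(
        table=pd.DataFrame(
            {
                "id": ids,
                "sire": "",
                "dam": "",
                f"breed_{breed}": 1.0,
                "flock": "FL1",
                "birth_year": 1,
                "role": "reference",
            }
        ),
        breeds=[breed],
    )
    tab = pd.DataFrame(
        {"id": ids, "trait": y, "flock": "FL1", "birth_year": 1, "mgmt_group": "G1"}
    )
    return op.build_design(tab, ped, trait="trait"), ped


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
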