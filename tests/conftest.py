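import numpy as np
import pandas as pd
import pytest

import sizespectra as sz


@pytest.fixture
def toy_table():
    """Two localities on one continent, two species with known masses."""
    table = pd.DataFrame({
        "locality_id": ["L1", "L1", "L2"],
        "continent": ["X", "X", "X"],
        "species_id": ["sp_a", "sp_b", "sp_a"],
    })
    masses = pd.Series([10.0, 250.0], index=["sp_a", "sp_b"], name="mass_g")
    masses.index.name = "species_id"
    return sz.AssemblageTable(table, masses)


def tiny_study_config(out_dir: str, seed: int = 5) -> sz.StudyConfig:
    """A two-continent study small enough for fast end-to-end runs."""
    pools = [
        sz.PoolConfig("X", n_species=80, log2_mass_location=5.0,
                      log2_mass_scale=3.0, log2_mass_skew=2.0,
                      mass_floor_g=1.0, mass_ceiling_g=1.0e6,
                      occupancy_intercept=-1.0, occupancy_mass_coef=0.2,
                      n_localities=4),
        sz.PoolConfig("Y", n_species=80, log2_mass_location=6.0,
                      log2_mass_scale=3.0, log2_mass_skew=2.0,
                      mass_floor_g=1.0, mass_ceiling_g=1.0e6,
                      occupancy_intercept=-1.0, occupancy_mass_coef=0.2,
                      n_localities=4),
    ]
    return sz.StudyConfig(pools=pools, seed=seed, out_dir=out_dir)


@pytest.fixture
def turnover_pool():
    """One seeded pool under the size-dependent-occupancy protocol."""
    return sz.generate_continent_pool(sz.turnover_protocol_config(), 3)
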