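"""Shared fixtures: small marker maps, genotype matrices, and one
session-scoped simulated population reused by the slower tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from selectwatch.io import GenotypeMatrix, MarkerMap
from selectwatch.simulate import SimConfig, breed_forward, simulate_founders, study_scenario


def make_markers(n_snps: int, chrom: str = "1", pos=None, spacing: int = 1000) -> MarkerMap:
    if pos is None:
        pos = np.arange(1, n_snps + 1) * spacing
    df = pd.DataFrame({
        "id": [f"s{i}" for i in range(n_snps)],
        "chrom": chrom,
        "pos_bp": np.asarray(pos, dtype=int),
        "a1": "A",
        "a2": "G",
    })
    return MarkerMap(df)


def make_gm(calls, chrom: str = "1", pos=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    markers = make_markers(calls.shape[1], chrom=chrom, pos=pos)
    return GenotypeMatrix(markers, [f"x{i}" for i in range(calls.shape[0])], calls)


@pytest.fixture(scope="session")
def small_sim_cfg() -> SimConfig:
    # trimmed scenario: ~4 kb marker spacing keeps ROH detectable while
    # staying fast enough for CI
    return study_scenario(seed=11, n_snps=2000, n_dams_per_year=16,
                          chrom_len_bp=4_000_000, focal_pos_bp=2_000_000,
                          years=(2015, 2021), selection_start_year=2018)


@pytest.fixture(scope="session")
def small_sim(small_sim_cfg):
    return breed_forward(simulate_founders(small_sim_cfg), small_sim_cfg)


@pytest.fixture(scope="session")
def neutral_sim():
    # balanced sexes and mid focal frequency keep every genotype-by-year
    # cell well populated for the export tests
    cfg = SimConfig(seed=5, n_snps=1500, n_dams_per_year=24, years=(2016, 2021),
                    focal_q0=0.45, male_fraction_breeding=0.5)
    return cfg, breed_forward(simulate_founders(cfg), cfg)
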