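"""Shared fixtures: small simulated panels and the full study conditions."""

import numpy as np
import pandas as pd
import pytest

from fstscan.simulate import (
    PlantedRegion,
    SimulationConfig,
    simulate_genotypes,
    simulate_study,
)


def study_conditions(seed: int) -> SimulationConfig:
    """The benchmark simulation: 2x400 samples, 27 chromosomes x 200 SNPs,
    background F_ST 0.01, three ~30-SNP planted regions at F_ST 0.15."""
    regions = tuple(
        PlantedRegion(chromosome=c, start=40_000_000, end=55_000_000, fst=0.15)
        for c in (1, 2, 3)
    )
    return SimulationConfig(
        n_samples_per_group=(400, 400),
        n_chromosomes=27,
        snps_per_chromosome=200,
        chromosome_length=100_000_000,
        fst_background=0.01,
        planted_regions=regions,
        missing_rate=0.01,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples_per_group=(40, 40),
        n_chromosomes=3,
        snps_per_chromosome=120,
        chromosome_length=50_000_000,
        fst_background=0.02,
        planted_regions=(PlantedRegion(1, 10_000_000, 20_000_000, 0.25),),
        missing_rate=0.02,
        flocks_per_group=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, genes_per_chromosome=6)


@pytest.fixture
def toy_ped_map(tmp_path):
    """Hand-written 2-sample, 3-marker PED/MAP pair with known call matrix."""
    map_text = "1 snp1 0 100\n1 snp2 0 200\n2 snp3 0 150\n"
    ped_text = (
        "FAM1 S1 0 0 2 -9 A A A G 0 0\n"
        "FAM1 S2 0 0 2 -9 A G G G C C\n"
    )
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp
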