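import numpy as np
import pytest

from haplodrop import (
    GeneDropConfig,
    HaplotypeSet,
    Individual,
    Pedigree,
    SynthConfig,
    simulate_population,
)


@pytest.fixture(scope="session")
def toy_hs() -> HaplotypeSet:
    return HaplotypeSet(
        names=("A", "B", "C", "D"),
        sequences={
            "A": "AAAAAAAAAA",
            "B": "AAAAAAAAAT",
            "C": "TTTTTAAAAA",
            "D": "AAAATTAAAA",
        },
    )


@pytest.fixture(scope="session")
def eight_hap_hs() -> HaplotypeSet:
    return HaplotypeSet(names=tuple("ABCDEFGH"))


def make_pedigree(rows):
    """rows: (id, sire, dam, sex, birth, death) tuples; None = unknown."""
    return Pedigree(
        Individual(
            id=r[0], sire_id=r[1], dam_id=r[2], sex=r[3],
            birth_year=r[4], death_year=r[5],
        )
        for r in rows
    )


@pytest.fixture(scope="session")
def three_generation():
    """Founders (1989) -> child (1993) -> grandchild (1994); all alive to 1995."""
    pedigree = make_pedigree(
        [
            ("F1", None, None, "M", 1989, 1995),
            ("F2", None, None, "F", 1989, 1995),
            ("F3", None, None, "F", 1989, 1995),
            ("C1", "F1", "F2", "M", 1993, 1995),
            ("G1", "C1", "F3", "F", 1994, 1995),
        ]
    )
    observed = {"F1": ("A", "A"), "F2": ("B", "B"), "F3": ("B", "B")}
    return pedigree, observed


@pytest.fixture(scope="session")
def neutral_population():
    """A medium neutral synthetic population, fully genotyped (shared, read-only)."""
    cfg = SynthConfig(seed=11, genotyping_missingness=0.0)
    return cfg, simulate_population(cfg)


@pytest.fixture(scope="session")
def small_genedrop_config():
    return GeneDropConfig(n_sim=200, seed=7)
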