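"""Synthetic pedigreed populations with MHC haplotypes and fitness records.

The generator emulates the design of a multi-decade individual-based study
of a closed, polygynous ungulate population with overlapping generations:

* founders enter with Hardy-Weinberg diplotypes drawn from configurable
  haplotype frequencies (eight haplotypes by default, one rare at ~3%);
* each study year, adult females (age >= 1) produce small litters (0-3
  lambs), each lamb's sire drawn from adult males with a gamma-distributed
  polygyny skew so that male annual breeding success can range from 0 to
  the mid-twenties while females are capped at 3;
* lambs inherit one haplotype from each parent (Mendelian, intact
  haplotype blocks — no recombination or mutation) and survive their first
  year with a baseline probability, optionally multiplied per carried copy
  of a selected haplotype (viability selection); fertility selection
  multiplies male siring weight analogously;
* adults survive year to year with age-specific probabilities; birth and
  death years are recorded so the pedigree supports standing-population
  reconstruction;
* six fitness measures are derived from realised life histories: total
  fitness (lifetime offspring of all individuals born), juvenile survival,
  adult annual survival, adult lifespan, adult annual breeding success and
  adult lifetime breeding success.

Individuals alive at the end of the study window have their observation
censored there (death year set to the final year); lifespan and lifetime
measures for such individuals are right-truncated, as in any ongoing field
study.  A genotyping-missingness step hides a configurable fraction of
diplotypes to emulate incomplete assay coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .haplotypes import HaplotypeSet, write_diplotypes, write_haplotype_fasta
from .pedigree import Individual, Pedigree, write_pedigree

__all__ = [
    "SynthConfig",
    "SimulatedPopulation",
    "ExtinctionError",
    "simulate_population",
    "apply_missingness",
    "generate_haplotype_sequences",
    "simulate_glm_response",
    "write_fixture_set",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_HAP_FREQS = {
    "A": 0.25,
    "B": 0.18,
    "C": 0.15,
    "D": 0.03,  # the rare haplotype
    "E": 0.13,
    "F": 0.12,
    "G": 0.08,
    "H": 0.06,
}


class ExtinctionError(RuntimeError):
    """The simulated population died out; relax survival/breeding parameters."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study population.

    ``selection`` maps haplotype label -> (juvenile viability effect,
    male fertility effect); a viability effect ``s`` multiplies juvenile
    survival probability by ``(1 + s)`` per carried copy (clamped to
    [0, 1]) and a fertility effect multiplies a male's siring weight by
    ``(1 + s)`` per copy.  ``male_skew`` is the gamma shape of per-male
    annual siring weights: smaller values give stronger polygyny.
    ``fitness_effect_sizes`` holds per-haplotype effects for GLM-recovery
    experiments via :func:`simulate_glm_response`.
    """

    n_founders: int = 100
    founder_hap_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAP_FREQS)
    )
    founder_birth_years: tuple[int, int] = (1985, 1988)
    cohort_years: tuple[int, int] = (1989, 2012)
    juvenile_survival: float = 0.45
    adult_survival_young: float = 0.75
    adult_survival_old: float = 0.60
    old_age: int = 7
    litter_probs: tuple[float, ...] = (0.15, 0.55, 0.28, 0.02)
    male_skew: float = 0.7
    selection: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    genotyping_missingness: float = 0.15
    fitness_effect_sizes: Mapping[str, float] = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self) -> None:
        total = sum(self.founder_hap_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"founder haplotype frequencies sum to {total}, not 1")
        if any(not (0 <= p <= 1) for p in self.founder_hap_freqs.values()):
            raise ValueError("founder haplotype frequencies must lie in [0, 1]")
        if abs(sum(self.litter_probs) - 1.0) > 1e-9:
            raise ValueError("litter size probabilities must sum to 1")
        if not (0 <= self.genotyping_missingness <= 1):
            raise ValueError("genotyping_missingness must lie in [0, 1]")
        unknown = set(self.selection) - set(self.founder_hap_freqs)
        if unknown:
            raise ValueError(f"selection on unknown haplotypes: {sorted(unknown)}")

    @property
    def hap_names(self) -> tuple[str, ...]:
        return tuple(self.founder_hap_freqs)


@dataclass
class SimulatedPopulation:
    """Everything one run of the generator produced."""

    pedigree: Pedigree
    diplotypes: dict[str, tuple[str, str]]  # post-missingness (observed)
    true_diplotypes: dict[str, tuple[str, str]]
    fitness: pd.DataFrame  # one row per individual, lifetime measures
    annual: pd.DataFrame  # one row per adult-year
    manifest: dict


class _Animal:
    __slots__ = (
        "idx", "id", "sex", "birth", "death", "sire", "dam",
        "haps", "alive", "juvenile_survivor", "annual_breeding",
    )

    def __init__(self, idx, sex, birth, sire, dam, haps):
        self.idx = idx
        self.id = f"I{idx:05d}"
        self.sex = sex
        self.birth = birth
        self.death = None
        self.sire = sire
        self.dam = dam
        self.haps = haps  # pair of int codes
        self.alive = True
        self.juvenile_survivor = False
        self.annual_breeding: dict[int, int] = {}


def _survival_multiplier(haps, sel_juv):
    m = 1.0
    for h in haps:
        m *= 1.0 + sel_juv[h]
    return m


def simulate_population(cfg: SynthConfig) -> SimulatedPopulation:
    """Run the individual-based simulation; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    names = cfg.hap_names
    k = len(names)
    freqs = np.array([cfg.founder_hap_freqs[h] for h in names])
    sel_juv = np.array([cfg.selection.get(h, (0.0, 0.0))[0] for h in names])
    sel_fert = np.array([cfg.selection.get(h, (0.0, 0.0))[1] for h in names])

    animals: list[_Animal] = []

    def new_animal(sex, birth, sire, dam, haps):
        a = _Animal(len(animals) + 1, sex, birth, sire, dam, haps)
        animals.append(a)
        return a

    # Founders: Hardy-Weinberg diplotypes, birth years spread over the
    # pre-study window so they are adults when the study cohorts begin.
    fy0, fy1 = cfg.founder_birth_years
    for _ in range(cfg.n_founders):
        sex = "M" if rng.random() < 0.5 else "F"
        birth = int(rng.integers(fy0, fy1 + 1))
        haps = tuple(rng.choice(k, size=2, p=freqs))
        a = new_animal(sex, birth, None, None, haps)
        a.juvenile_survivor = True  # founders enter as established animals

    y0, y1 = cfg.cohort_years
    for year in range(y0, y1 + 1):
        adults = [a for a in animals if a.alive and a.birth < year]
        females = [a for a in adults if a.sex == "F"]
        males = [a for a in adults if a.sex == "M"]
        if not females or not males:
            raise ExtinctionError(
                f"population lost all adult {'females' if not females else 'males'} "
                f"by {year}; increase survival or founder count"
            )
        # Polygyny: per-male annual siring weight, gamma-skewed and scaled
        # by any fertility selection on carried haplotypes.
        weights = rng.gamma(cfg.male_skew, 1.0, size=len(males))
        for i, m in enumerate(males):
            for h in m.haps:
                weights[i] *= 1.0 + sel_fert[h]
        weights = weights / weights.sum()

        lambs: list[_Animal] = []
        for mother in females:
            litter = int(rng.choice(len(cfg.litter_probs), p=cfg.litter_probs))
            for _ in range(litter):
                father = males[int(rng.choice(len(males), p=weights))]
                haps = (
                    father.haps[int(rng.random() >= 0.5)],
                    mother.haps[int(rng.random() >= 0.5)],
                )
                sex = "M" if rng.random() < 0.5 else "F"
                lamb = new_animal(sex, year, father.id, mother.id, haps)
                mother.annual_breeding[year] = mother.annual_breeding.get(year, 0) + 1
                father.annual_breeding[year] = father.annual_breeding.get(year, 0) + 1
                lambs.append(lamb)

        # Juvenile viability, with optional haplotype selection.
        for lamb in lambs:
            p = cfg.juvenile_survival * _survival_multiplier(lamb.haps, sel_juv)
            p = min(max(p, 0.0), 1.0)
            if rng.random() < p:
                lamb.juvenile_survivor = True
            else:
                lamb.alive = False
                lamb.death = year

        # Adult overwinter survival, age-specific.
        for a in adults:
            age = year - a.birth
            p = cfg.adult_survival_young if age < cfg.old_age else cfg.adult_survival_old
            if rng.random() >= p:
                a.alive = False
                a.death = year

    for a in animals:
        if a.alive:
            a.death = y1  # censoring at the end of the study window

    pedigree = Pedigree(
        Individual(
            id=a.id, sire_id=a.sire, dam_id=a.dam, sex=a.sex,
            birth_year=a.birth, death_year=a.death,
        )
        for a in animals
    )
    true_diplotypes = {a.id: (names[a.haps[0]], names[a.haps[1]]) for a in animals}
    observed = apply_missingness(
        true_diplotypes, cfg.genotyping_missingness, rng
    )

    fitness_rows = []
    annual_rows = []
    for a in animals:
        total_fitness = sum(a.annual_breeding.values())
        adult = a.juvenile_survivor
        lifespan = (a.death - a.birth) if adult else None
        fitness_rows.append(
            {
                "ID": a.id,
                "sex": a.sex,
                "birth_year": a.birth,
                "death_year": a.death,
                "total_fitness": total_fitness,
                "juvenile_survival": int(a.juvenile_survivor),
                "adult_lifespan": lifespan,
                "adult_lifetime_breeding": total_fitness if adult else None,
            }
        )
        if adult:
            first_adult_year = max(a.birth + 1, y0)
            for year in range(first_adult_year, min(a.death, y1) + 1):
                survived = int(year < a.death or (year == a.death and a.alive))
                annual_rows.append(
                    {
                        "ID": a.id,
                        "year": year,
                        "age": year - a.birth,
                        "adult_annual_survival": survived,
                        "adult_annual_breeding": a.annual_breeding.get(year, 0),
                    }
                )

    fitness = pd.DataFrame(fitness_rows)
    annual = pd.DataFrame(annual_rows)
    final_year_ids = pedigree.alive_in_year(y1)
    manifest = {
        "config": _config_dict(cfg),
        "n_individuals": len(animals),
        "n_genotyped": len(observed),
        "n_cohorts": y1 - y0 + 1,
        "final_year_population": len(final_year_ids),
        "seed": cfg.seed,
    }
    return SimulatedPopulation(
        pedigree=pedigree,
        diplotypes=observed,
        true_diplotypes=true_diplotypes,
        fitness=fitness,
        annual=annual,
        manifest=manifest,
    )


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["founder_hap_freqs"] = dict(cfg.founder_hap_freqs)
    d["selection"] = {h: list(v) for h, v in cfg.selection.items()}
    d["fitness_effect_sizes"] = dict(cfg.fitness_effect_sizes)
    d["litter_probs"] = list(cfg.litter_probs)
    d["founder_birth_years"] = list(cfg.founder_birth_years)
    d["cohort_years"] = list(cfg.cohort_years)
    return d


def apply_missingness(
    diplotypes: Mapping[str, tuple[str, str]],
    rate: float,
    rng: np.random.Generator,
) -> dict[str, tuple[str, str]]:
    """Independently drop each individual's diplotype with probability ``rate``."""
    if not (0 <= rate <= 1):
        raise ValueError("missingness rate must lie in [0, 1]")
    if rate == 0:
        return dict(diplotypes)
    keep = rng.random(len(diplotypes)) >= rate
    return {iid: pair for (iid, pair), k in zip(diplotypes.items(), keep) if k}


def generate_haplotype_sequences(
    hap_names: tuple[str, ...] | list[str],
    length: int = 120,
    seed: int = 7,
    divergent: str | None = "D",
) -> HaplotypeSet:
    """Random but fixed divergent amino-acid sequences, one per haplotype.

    Sequences are mutations of a common random backbone; the ``divergent``
    haplotype (if named) receives roughly twice as many substitutions,
    mirroring a set in which the rarest haplotype is also the most
    diverged.  Synthetic sequences: they carry no biological information.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    base = rng.choice(aa, size=length)
    sequences = {}
    for name in hap_names:
        n_mut = 24 if name == divergent else 12
        seq = base.copy()
        positions = rng.choice(length, size=n_mut, replace=False)
        for pos in positions:
            choices = [r for r in AMINO_ACIDS if r != seq[pos]]
            seq[pos] = choices[int(rng.integers(len(choices)))]
        sequences[name] = "".join(seq)
    if len(set(sequences.values())) != len(sequences):
        raise RuntimeError("generated sequences collided; change the seed")
    return HaplotypeSet(names=tuple(hap_names), sequences=sequences)


def simulate_glm_response(
    design: pd.DataFrame,
    coef: Mapping[str, float],
    family: str,
    rng: np.random.Generator,
    zero_inflation: float = 0.0,
    thresholds: tuple[float, ...] = (),
) -> np.ndarray:
    """Draw a response vector from a GLM with known coefficients.

    Used for parameter-recovery experiments: the linear predictor is
    ``design @ coef`` (labels matched by column name), pushed through the
    family's link.  ``zero_inflation`` is the structural-zero probability
    for the zero-inflated Poisson family; ``thresholds`` are the ordinal
    cut points on the latent probit scale.
    """
    from scipy import stats as sps

    beta = np.array([coef.get(c, 0.0) for c in design.columns])
    eta = np.asarray(design, dtype=float) @ beta
    n = len(eta)
    if family == "binomial_probit":
        return (rng.random(n) < sps.norm.cdf(eta)).astype(float)
    if family == "poisson_log":
        return rng.poisson(np.exp(eta)).astype(float)
    if family == "zero_inflated_poisson":
        y = rng.poisson(np.exp(eta)).astype(float)
        y[rng.random(n) < zero_inflation] = 0.0
        return y
    if family == "ordinal_probit":
        latent = eta + rng.standard_normal(n)
        return np.searchsorted(np.asarray(thresholds), latent).astype(float)
    raise ValueError(f"unknown family {family!r}")


def write_fixture_set(
    sim: SimulatedPopulation,
    directory: str | Path,
    hs: HaplotypeSet | None = None,
) -> dict[str, Path]:
    """Write a self-contained demo dataset: pedigree, diplotypes, FASTA, fitness, manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if hs is None:
        names = tuple(sim.manifest["config"]["founder_hap_freqs"])
        hs = generate_haplotype_sequences(names, seed=sim.manifest["seed"] % (2**31))
    paths = {
        "pedigree": directory / "pedigree.tsv",
        "diplotypes": directory / "diplotypes.tsv",
        "fasta": directory / "haplotypes.fasta",
        "fitness": directory / "fitness.tsv",
        "manifest": directory / "manifest.yaml",
    }
    write_pedigree(sim.pedigree, paths["pedigree"])
    write_diplotypes(sim.diplotypes, paths["diplotypes"])
    write_haplotype_fasta(hs, paths["fasta"])
    sim.fitness.to_csv(paths["fitness"], sep="\t", index=False, na_rep="NA")
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(sim.manifest, fh, sort_keys=False)
    return paths
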