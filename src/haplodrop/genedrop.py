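"""Gene-drop simulation of haplotype trajectories under neutrality.

The gene-drop asks: given the *observed* pedigree and the genotypes of the
earliest ("founder") birth cohorts, how much would haplotype frequencies in
the standing population change through time by Mendelian segregation and
demography alone?  Each replicate re-transmits haplotypes down the fixed
pedigree:

* founder-cohort individuals keep their observed diplotypes verbatim;
* any individual without an observed diplotype in or before the founder
  window, and *every* individual born in the simulated window (whether
  genotyped or not), receives one simulated haplotype per parental slot —
  a Mendelian draw (each of the parent's two haplotypes with probability
  1/2) when that parent is in the pedigree, otherwise a draw from the
  observed haplotype frequencies of the individual's own birth cohort;
* individuals born before the founder window keep observed diplotypes when
  available and are otherwise frequency-sampled, since they can be parents
  of founder-cohort animals.

Standing-population frequencies are then tabulated per calendar year over
either the genotyped individuals only (default; the same set the observed
trajectory uses, so observed and simulated series are compositionally
identical) or over every individual alive.

Cohort frequencies are computed once from the observed data and held fixed
across replicates.  A cohort with no genotyped member falls back to the
nearest cohort that has data (earlier preferred on ties); the fallback is
logged.

Reproducibility: one root seed; replicate ``r`` consumes an independent
child stream spawned from it, so results are invariant to how replicates
are batched or parallelised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeSet
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneDropConfig",
    "HaplotypeAssignment",
    "FrequencyTable",
    "GeneDropResult",
    "DropEngine",
    "observed_standing_frequencies",
    "cohort_frequencies",
    "sample_offspring_haplotype",
    "drop_once",
    "run_genedrop",
    "expected_frequency_trajectory",
]


@dataclass(frozen=True)
class GeneDropConfig:
    """Study-window and replication settings for a gene-drop run.

    ``founder_years`` and ``simulated_years`` are inclusive (first, last)
    calendar-year pairs; the founder window must precede the simulated
    window.  ``frequency_individuals`` selects the standing-population set
    used for frequency tabulation: ``"genotyped_only"`` restricts both the
    observed and simulated series to individuals with observed diplotypes,
    ``"all"`` uses every individual alive (all are assigned in simulation).
    """

    founder_years: tuple[int, int] = (1989, 1992)
    simulated_years: tuple[int, int] = (1993, 2012)
    n_sim: int = 5000
    seed: int = 0
    frequency_individuals: str = "genotyped_only"

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be a positive integer")
        if self.founder_years[0] > self.founder_years[1]:
            raise ValueError("founder_years must be an increasing pair")
        if self.simulated_years[0] > self.simulated_years[1]:
            raise ValueError("simulated_years must be an increasing pair")
        if self.founder_years[1] >= self.simulated_years[0]:
            raise ValueError("founder window must precede the simulated window")
        if self.frequency_individuals not in ("genotyped_only", "all"):
            raise ValueError(
                "frequency_individuals must be 'genotyped_only' or 'all'"
            )


@dataclass
class HaplotypeAssignment:
    """One replicate's diplotype assignment with provenance flags.

    ``flags[id]`` is ``"observed"`` (kept verbatim), ``"mendelian"`` (both
    alleles drawn from assigned parents) or ``"frequency_sampled"`` (at
    least one allele drawn from cohort frequencies).  ``allele_sources``
    retains the per-slot detail.
    """

    pairs: dict[str, tuple[str, str]]
    flags: dict[str, str]
    allele_sources: dict[str, tuple[str, str]]


@dataclass
class FrequencyTable:
    """Year x haplotype standing-population frequencies.

    Years with no eligible individuals are *undefined*: their frequency row
    is NaN and ``n_individuals`` is 0.  Defined rows sum to 1 exactly
    (counts over 2N).
    """

    years: np.ndarray
    haplotypes: tuple[str, ...]
    freq: np.ndarray
    n_individuals: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_individuals = np.asarray(self.n_individuals, dtype=int)
        defined = self.n_individuals > 0
        sums = self.freq[defined].sum(axis=1)
        if defined.any() and not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise ValueError("defined frequency rows must sum to 1")

    @property
    def defined(self) -> np.ndarray:
        return self.n_individuals > 0

    def to_frame(self, long: bool = False) -> pd.DataFrame:
        wide = pd.DataFrame(self.freq, index=self.years, columns=list(self.haplotypes))
        wide.index.name = "year"
        if not long:
            out = wide.copy()
            out["n"] = self.n_individuals
            return out
        melted = wide.reset_index().melt(
            id_vars="year", var_name="haplotype", value_name="frequency"
        )
        n_map = dict(zip(self.years, self.n_individuals))
        melted["n"] = melted["year"].map(n_map)
        return melted


def cohort_frequencies(
    pedigree: Pedigree,
    diplotypes: Mapping[str, tuple[str, str]],
    hs: HaplotypeSet,
) -> dict[int, np.ndarray]:
    """Observed haplotype frequencies per birth cohort, with nearest-cohort fallback.

    Returns a frequency vector for *every* birth year present in the
    pedigree.  Cohorts without any genotyped member inherit the nearest
    genotyped cohort's frequencies (earlier year preferred on ties).
    """
    index = hs.index()
    counts: dict[int, np.ndarray] = {}
    for ind in pedigree:
        pair = diplotypes.get(ind.id)
        if pair is None:
            continue
        vec = counts.setdefault(ind.birth_year, np.zeros(len(hs)))
        for hap in pair:
            vec[index[hap]] += 1
    if not counts:
        raise ValueError("no genotyped individuals: cannot form cohort frequencies")
    freq = {year: vec / vec.sum() for year, vec in counts.items()}
    data_years = sorted(freq)
    out: dict[int, np.ndarray] = {}
    for ind in pedigree:
        year = ind.birth_year
        if year in out:
            continue
        if year in freq:
            out[year] = freq[year]
        else:
            nearest = min(data_years, key=lambda y: (abs(y - year), y))
            logger.info(
                "birth cohort %d has no genotyped members; using cohort %d frequencies",
                year,
                nearest,
            )
            out[year] = freq[nearest]
    return out


def observed_standing_frequencies(
    pedigree: Pedigree,
    diplotypes: Mapping[str, tuple[str, str]],
    years: Iterator[int] | np.ndarray | list[int],
    hs: HaplotypeSet,
) -> FrequencyTable:
    """Per-year haplotype frequencies over alive, genotyped individuals."""
    years = np.asarray(list(years), dtype=int)
    index = hs.index()
    freq = np.full((len(years), len(hs)), np.nan)
    n = np.zeros(len(years), dtype=int)
    for j, year in enumerate(years):
        alive = pedigree.alive_in_year(int(year))
        counts = np.zeros(len(hs))
        m = 0
        for iid in alive:
            pair = diplotypes.get(iid)
            if pair is None:
                continue
            m += 1
            for hap in pair:
                counts[index[hap]] += 1
        n[j] = m
        if m > 0:
            freq[j] = counts / (2 * m)
        else:
            logger.warning("year %d has no alive genotyped individuals", year)
    return FrequencyTable(years=years, haplotypes=tuple(hs.names), freq=freq, n_individuals=n)


def sample_offspring_haplotype(
    parent_pair: tuple[str, str], rng: np.random.Generator
) -> str:
    """Mendelian draw: each of the parent's two haplotypes with probability 1/2."""
    return parent_pair[int(rng.random() >= 0.5)]


class DropEngine:
    """Precomputed arrays for fast, replicate-vectorised gene-drops.

    Individuals are laid out in topological (parents-first) order.  Per
    replicate the engine consumes exactly two uniforms per individual (one
    per parental slot), whether or not they end up used, which makes the
    scalar reference path (:meth:`drop_once`) and the vectorised path
    (:meth:`run`) bit-identical given the same stream.
    """

    OBS, MEND, FREQ = 0, 1, 2  # allele-source codes

    def __init__(
        self,
        pedigree: Pedigree,
        diplotypes: Mapping[str, tuple[str, str]],
        hs: HaplotypeSet,
        config: GeneDropConfig,
    ):
        self.pedigree = pedigree
        self.hs = hs
        self.config = config
        self.ids = pedigree.topological_order()
        self._pos = {iid: k for k, iid in enumerate(self.ids)}
        n = len(self.ids)
        hap_index = hs.index()
        self.n_hap = len(hs)

        self.birth = np.array([pedigree[i].birth_year for i in self.ids])
        self.sire = np.array(
            [self._pos.get(pedigree[i].sire_id, -1) if pedigree[i].sire_id else -1 for i in self.ids]
        )
        self.dam = np.array(
            [self._pos.get(pedigree[i].dam_id, -1) if pedigree[i].dam_id else -1 for i in self.ids]
        )
        self.obs = np.full((n, 2), -1, dtype=np.int64)
        for iid, pair in diplotypes.items():
            if iid in self._pos:
                self.obs[self._pos[iid]] = [hap_index[pair[0]], hap_index[pair[1]]]
        self.genotyped = self.obs[:, 0] >= 0

        founder_hi = config.founder_years[1]
        # Observed diplotypes are kept verbatim only in / before the founder
        # window; simulated-cohort genotypes are never copied.
        self.fixed = (self.birth <= founder_hi) & self.genotyped

        cf = cohort_frequencies(pedigree, diplotypes, hs)
        self.cum_by_year = {year: np.cumsum(vec) for year, vec in cf.items()}
        self.cohort_freq = cf

        self._year_groups = [
            (year, np.flatnonzero(self.birth == year))
            for year in np.unique(self.birth)
        ]
        self._alive_cache: dict[tuple[str, int], np.ndarray] = {}

    # -- core transmission ---------------------------------------------
    def _alive_indices(self, year: int, which: str) -> np.ndarray:
        key = (which, year)
        if key not in self._alive_cache:
            alive = self.pedigree.alive_in_year(year)
            idx = np.array(sorted(self._pos[i] for i in alive), dtype=int)
            if which == "genotyped_only":
                idx = idx[self.genotyped[idx]]
            self._alive_cache[key] = idx
        return self._alive_cache[key]

    def run(self, n_sim: int, seed: int) -> np.ndarray:
        """Simulate ``n_sim`` replicates; returns (n_sim, n_individuals, 2) codes."""
        n = len(self.ids)
        children = np.random.SeedSequence(seed).spawn(n_sim)
        u = np.empty((n_sim, n, 2))
        for r, child in enumerate(children):
            u[r] = np.random.default_rng(child).random((n, 2))
        assigned = np.empty((n_sim, n, 2), dtype=np.int64)
        for year, group in self._year_groups:
            fixed = group[self.fixed[group]]
            if fixed.size:
                assigned[:, fixed, :] = self.obs[fixed]
            sim = group[~self.fixed[group]]
            if not sim.size:
                continue
            cum = self.cum_by_year[year]
            for slot, parents in ((0, self.sire), (1, self.dam)):
                pidx = parents[sim]
                known = pidx >= 0
                out = np.empty((n_sim, sim.size), dtype=np.int64)
                if known.any():
                    ks = sim[known]
                    choose = (u[:, ks, slot] >= 0.5).astype(np.int64)
                    parental = assigned[:, pidx[known], :]
                    out[:, known] = np.take_along_axis(
                        parental, choose[..., None], axis=2
                    )[..., 0]
                if (~known).any():
                    us = sim[~known]
                    out[:, ~known] = np.searchsorted(
                        cum, u[:, us, slot], side="right"
                    )
                assigned[:, sim, slot] = out
        return assigned

    def drop_once(self, rng: np.random.Generator) -> HaplotypeAssignment:
        """Scalar reference drop; consumes the same uniforms as :meth:`run`."""
        n = len(self.ids)
        u = rng.random((n, 2))
        codes = np.empty((n, 2), dtype=np.int64)
        sources = np.empty((n, 2), dtype=np.int64)
        for year, group in self._year_groups:
            for k in group:
                if self.fixed[k]:
                    codes[k] = self.obs[k]
                    sources[k] = self.OBS
                    continue
                cum = self.cum_by_year[year]
                for slot, parent in ((0, self.sire[k]), (1, self.dam[k])):
                    if parent >= 0:
                        codes[k, slot] = codes[parent, int(u[k, slot] >= 0.5)]
                        sources[k, slot] = self.MEND
                    else:
                        codes[k, slot] = np.searchsorted(cum, u[k, slot], side="right")
                        sources[k, slot] = self.FREQ
        names = self.hs.names
        source_name = {self.OBS: "observed", self.MEND: "mendelian", self.FREQ: "frequency_sampled"}
        pairs, flags, per_allele = {}, {}, {}
        for k, iid in enumerate(self.ids):
            pairs[iid] = (names[codes[k, 0]], names[codes[k, 1]])
            srcs = (source_name[sources[k, 0]], source_name[sources[k, 1]])
            per_allele[iid] = srcs
            if srcs == ("observed", "observed"):
                flags[iid] = "observed"
            elif "frequency_sampled" in srcs:
                flags[iid] = "frequency_sampled"
            else:
                flags[iid] = "mendelian"
        return HaplotypeAssignment(pairs=pairs, flags=flags, allele_sources=per_allele)

    # -- frequency tabulation --------------------------------------------
    def standing_frequencies(
        self, assigned: np.ndarray, years: np.ndarray, which: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-replicate standing frequencies: (n_sim, n_years, n_hap) and year Ns."""
        which = which or self.config.frequency_individuals
        n_sim = assigned.shape[0]
        k = self.n_hap
        freq = np.full((n_sim, len(years), k), np.nan)
        n_per_year = np.zeros(len(years), dtype=int)
        offsets = np.arange(n_sim)[:, None, None] * k
        for j, year in enumerate(years):
            idx = self._alive_indices(int(year), which)
            n_per_year[j] = idx.size
            if idx.size == 0:
                continue
            flat = (assigned[:, idx, :] + offsets).ravel()
            counts = np.bincount(flat, minlength=n_sim * k).reshape(n_sim, k)
            freq[:, j, :] = counts / (2 * idx.size)
        return freq, n_per_year

    def expected_allele_frequencies(self) -> np.ndarray:
        """Exact per-individual expected haplotype frequencies (n x n_hap).

        Mendelian transmission preserves expectations: a child's expected
        frequency vector is the mean of its two allele-source vectors
        (parent's vector if the parent is known, else the cohort frequency
        vector).  Fixed individuals contribute their observed dosage / 2.
        """
        n = len(self.ids)
        e = np.empty((n, self.n_hap))
        for year, group in self._year_groups:
            for k in group:
                if self.fixed[k]:
                    vec = np.zeros(self.n_hap)
                    vec[self.obs[k, 0]] += 0.5
                    vec[self.obs[k, 1]] += 0.5
                    e[k] = vec
                else:
                    halves = []
                    for parent in (self.sire[k], self.dam[k]):
                        halves.append(
                            e[parent] if parent >= 0 else self.cohort_freq[year]
                        )
                    e[k] = 0.5 * (halves[0] + halves[1])
        return e


@dataclass
class GeneDropResult:
    """Observed trajectory plus the full stack of simulated replicates.

    ``sim_freq`` has shape (n_sim, n_years, n_haplotypes); years with no
    eligible individuals are NaN in both observed and simulated series.
    """

    haplotypes: tuple[str, ...]
    years: np.ndarray
    observed: FrequencyTable
    sim_freq: np.ndarray
    sim_n: np.ndarray
    config: GeneDropConfig

    @property
    def n_sim(self) -> int:
        return self.sim_freq.shape[0]

    def replicate_table(self, r: int) -> FrequencyTable:
        return FrequencyTable(
            years=self.years,
            haplotypes=self.haplotypes,
            freq=self.sim_freq[r],
            n_individuals=self.sim_n,
        )

    def replicates(self) -> Iterator[FrequencyTable]:
        for r in range(self.n_sim):
            yield self.replicate_table(r)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: replicate ('observed' or index), year, haplotype, frequency, n."""
        frames = [self.observed.to_frame(long=True).assign(replicate="observed")]
        for r in range(self.n_sim):
            frames.append(self.replicate_table(r).to_frame(long=True).assign(replicate=str(r)))
        out = pd.concat(frames, ignore_index=True)
        return out[["replicate", "year", "haplotype", "frequency", "n"]]


def drop_once(
    pedigree: Pedigree,
    diplotypes: Mapping[str, tuple[str, str]],
    hs: HaplotypeSet,
    config: GeneDropConfig,
    rng: np.random.Generator,
) -> HaplotypeAssignment:
    """One replicate of the gene-drop, with per-individual provenance flags."""
    return DropEngine(pedigree, diplotypes, hs, config).drop_once(rng)


def run_genedrop(
    pedigree: Pedigree,
    diplotypes: Mapping[str, tuple[str, str]],
    hs: HaplotypeSet,
    config: GeneDropConfig,
) -> GeneDropResult:
    """Full gene-drop: ``config.n_sim`` replicates plus the observed trajectory.

    Identical ``config.seed`` gives bit-identical output.
    """
    engine = DropEngine(pedigree, diplotypes, hs, config)
    years = np.arange(config.simulated_years[0], config.simulated_years[1] + 1)
    assigned = engine.run(config.n_sim, config.seed)
    sim_freq, sim_n = engine.standing_frequencies(assigned, years)
    observed = observed_standing_frequencies(pedigree, diplotypes, years, hs)
    return GeneDropResult(
        haplotypes=tuple(hs.names),
        years=years,
        observed=observed,
        sim_freq=sim_freq,
        sim_n=sim_n,
        config=config,
    )


def expected_frequency_trajectory(
    pedigree: Pedigree,
    diplotypes: Mapping[str, tuple[str, str]],
    hs: HaplotypeSet,
    config: GeneDropConfig,
    which: str | None = None,
) -> FrequencyTable:
    """Exact expectation of the simulated standing-frequency trajectory.

    Propagates per-individual expected frequencies through the pedigree
    (closed form, no Monte Carlo) and averages over each year's standing
    set.  Useful as an oracle: replicate means from :func:`run_genedrop`
    converge to this table.
    """
    engine = DropEngine(pedigree, diplotypes, hs, config)
    which = which or config.frequency_individuals
    e = engine.expected_allele_frequencies()
    years = np.arange(config.simulated_years[0], config.simulated_years[1] + 1)
    freq = np.full((len(years), len(hs)), np.nan)
    n = np.zeros(len(years), dtype=int)
    for j, year in enumerate(years):
        idx = engine._alive_indices(int(year), which)
        n[j] = idx.size
        if idx.size:
            freq[j] = e[idx].mean(axis=0)
    return FrequencyTable(years=years, haplotypes=tuple(hs.names), freq=freq, n_individuals=n)
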