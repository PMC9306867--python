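"""Pedigree data model, TSV I/O, validation and traversal order.

A pedigree is a directed acyclic graph of parent-offspring links with
life-year annotations (birth year, death year).  Two derived views drive
everything downstream:

* the *birth cohort* of a year — all individuals born in that year;
* the *standing population* of a year — all individuals alive in that
  year, with the life interval treated as inclusive on both ends (an
  animal that dies in year ``y`` is counted as present in ``y``).

Individuals whose death year is unknown contribute to the standing
population only in their birth year, unless an optional ``FINAL_YEAR``
column supplies a last-seen year.  This avoids fabricating presence for
animals that disappeared from observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "validate_pedigree",
    "topological_order",
    "birth_cohort",
    "alive_in_year",
]

_MALE_CODES = {"m", "male", "1"}
_FEMALE_CODES = {"f", "female", "2"}


class PedigreeError(ValueError):
    """Raised for structural problems: duplicate ids, dangling parents, cycles."""


@dataclass(frozen=True)
class Individual:
    """One pedigree record.

    ``sire_id``/``dam_id`` are ``None`` when the parent is unknown; ``sex``
    is ``'M'``, ``'F'`` or ``None``; ``death_year`` is ``None`` when the
    individual's death was not recorded.  ``final_year`` optionally records
    the last year an individual of unknown fate was seen alive.
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str | None = None
    birth_year: int = 0
    death_year: int | None = None
    final_year: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be a non-empty string")
        if self.sire_id == self.id or self.dam_id == self.id:
            raise PedigreeError(f"individual {self.id!r} is its own parent")

    @property
    def last_year_alive(self) -> int:
        """Final year this individual counts as present in the standing population."""
        if self.death_year is not None:
            return self.death_year
        if self.final_year is not None:
            return self.final_year
        return self.birth_year


class Pedigree:
    """Collection of :class:`Individual` keyed by id.

    Construction checks structural integrity (unique ids, resolvable parent
    links, acyclicity); softer consistency rules are reported by
    :func:`validate_pedigree`.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._individuals[ind.id] = ind
        for ind in self._individuals.values():
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None and pid not in self._individuals:
                    raise PedigreeError(
                        f"parent {pid!r} of {ind.id!r} is not in the pedigree"
                    )
        cycle = self._find_cycle()
        if cycle is not None:
            raise PedigreeError(
                "pedigree contains an ancestral cycle: " + " -> ".join(cycle)
            )
        self._topo_cache: list[str] | None = None

    # -- basic container behaviour -------------------------------------
    def __len__(self) -> int:
        return len(self._individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._individuals

    def __getitem__(self, individual_id: str) -> Individual:
        return self._individuals[individual_id]

    def __iter__(self):
        return iter(self._individuals.values())

    @property
    def ids(self) -> list[str]:
        return list(self._individuals)

    @property
    def year_range(self) -> tuple[int, int]:
        years = [ind.birth_year for ind in self]
        return (min(years), max(years))

    # -- graph helpers --------------------------------------------------
    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._individuals)
        for ind in self:
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None:
                    g.add_edge(pid, ind.id)
        return g

    def _find_cycle(self) -> list[str] | None:
        try:
            cycle = nx.find_cycle(self._graph())
        except nx.NetworkXNoCycle:
            return None
        return [edge[0] for edge in cycle] + [cycle[-1][1]]

    def topological_order(self) -> list[str]:
        """Parents-first ordering, deterministic via (birth_year, id) tie-break."""
        if self._topo_cache is None:
            key = lambda nid: (self._individuals[nid].birth_year, nid)
            self._topo_cache = list(
                nx.lexicographical_topological_sort(self._graph(), key=key)
            )
        return list(self._topo_cache)

    def birth_cohort(self, year: int) -> set[str]:
        return {ind.id for ind in self if ind.birth_year == year}

    def alive_in_year(self, year: int) -> set[str]:
        return {
            ind.id
            for ind in self
            if ind.birth_year <= year <= ind.last_year_alive
        }

    def validate(self) -> list[str]:
        """Return human-readable descriptions of every invariant violation."""
        violations: list[str] = []
        for ind in self:
            if ind.death_year is not None and ind.death_year < ind.birth_year:
                violations.append(
                    f"{ind.id}: death year {ind.death_year} precedes "
                    f"birth year {ind.birth_year}"
                )
            for role, pid, expected_sex in (
                ("sire", ind.sire_id, "M"),
                ("dam", ind.dam_id, "F"),
            ):
                if pid is None:
                    continue
                parent = self._individuals[pid]
                if parent.birth_year >= ind.birth_year:
                    violations.append(
                        f"{ind.id} (born {ind.birth_year}): {role} {pid} born "
                        f"{parent.birth_year}, not before offspring"
                    )
                if parent.sex is not None and parent.sex != expected_sex:
                    violations.append(
                        f"{ind.id}: {role} {pid} has recorded sex {parent.sex}"
                    )
        return violations


def _parse_sex(raw: str | None) -> str | None:
    if raw is None:
        return None
    token = str(raw).strip().lower()
    if token in _MALE_CODES:
        return "M"
    if token in _FEMALE_CODES:
        return "F"
    return None


def read_pedigree(
    path: str | Path, missing_code: str = "NA", strict: bool = False
) -> Pedigree:
    """Read a tab-separated pedigree file.

    Required columns: ``ID``, ``SIRE``, ``DAM``, ``BIRTH_YEAR``; optional:
    ``SEX``, ``DEATH_YEAR``, ``FINAL_YEAR``.  Cells equal to ``missing_code``
    (or empty) are treated as unknown.  Structural defects raise
    :class:`PedigreeError`; soft inconsistencies (parent born after
    offspring, sex mismatches) are logged as warnings unless ``strict``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"ID", "SIRE", "DAM", "BIRTH_YEAR"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise PedigreeError(f"pedigree file lacks columns: {sorted(missing_cols)}")

    def cell(value: str) -> str | None:
        value = value.strip()
        return None if value == "" or value == missing_code else value

    individuals = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        birth = cell(rec["BIRTH_YEAR"])
        if birth is None:
            raise PedigreeError(f"individual {rec['ID']!r} has no birth year")
        death = cell(rec.get("DEATH_YEAR", ""))
        final = cell(rec.get("FINAL_YEAR", ""))
        individuals.append(
            Individual(
                id=rec["ID"].strip(),
                sire_id=cell(rec["SIRE"]),
                dam_id=cell(rec["DAM"]),
                sex=_parse_sex(cell(rec.get("SEX", ""))),
                birth_year=int(birth),
                death_year=int(death) if death is not None else None,
                final_year=int(final) if final is not None else None,
            )
        )
    pedigree = Pedigree(individuals)
    violations = pedigree.validate()
    if violations:
        if strict:
            raise PedigreeError("; ".join(violations))
        for v in violations:
            logger.warning("pedigree inconsistency: %s", v)
    return pedigree


def write_pedigree(
    pedigree: Pedigree, path: str | Path, missing_code: str = "NA"
) -> None:
    """Write the same TSV dialect :func:`read_pedigree` accepts."""
    sex_out = {"M": "M", "F": "F", None: missing_code}
    rows = []
    for ind in pedigree:
        rows.append(
            {
                "ID": ind.id,
                "SIRE": ind.sire_id if ind.sire_id is not None else missing_code,
                "DAM": ind.dam_id if ind.dam_id is not None else missing_code,
                "SEX": sex_out[ind.sex],
                "BIRTH_YEAR": ind.birth_year,
                "DEATH_YEAR": ind.death_year
                if ind.death_year is not None
                else missing_code,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# Functional wrappers mirroring the method API -------------------------------

def validate_pedigree(pedigree: Pedigree) -> list[str]:
    return pedigree.validate()


def topological_order(pedigree: Pedigree) -> list[str]:
    return pedigree.topological_order()


def birth_cohort(pedigree: Pedigree, year: int) -> set[str]:
    return pedigree.birth_cohort(year)


def alive_in_year(pedigree: Pedigree, year: int) -> set[str]:
    return pedigree.alive_in_year(year)
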