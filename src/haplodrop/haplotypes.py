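"""MHC haplotype and diplotype model: dosage, heterozygosity, p-distance.

Haplotypes here are intact multi-locus units (e.g. eight class IIa
haplotypes A-H segregating in a closed sheep population), each backed by a
concatenated amino-acid sequence across its linked loci.  A diplotype is
the unordered pair of haplotypes an individual carries.

Divergence between the two haplotypes of a diplotype is the amino-acid
p-distance: the proportion of aligned positions at which the residues
differ.  Columns where either sequence has a gap ('-') are excluded
(pairwise deletion); comparison is case-insensitive and 'X' counts as an
ordinary, mismatching residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "HaplotypeSet",
    "Diplotype",
    "read_haplotype_fasta",
    "write_haplotype_fasta",
    "read_diplotypes",
    "write_diplotypes",
    "p_distance",
    "diplotype_divergence",
    "heterozygosity",
    "dosage_matrix",
]

GAP = "-"


@dataclass(frozen=True)
class HaplotypeSet:
    """Ordered haplotype labels with optional aligned amino-acid sequences."""

    names: tuple[str, ...]
    sequences: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("haplotype names must be unique")
        if any(not n for n in self.names):
            raise ValueError("haplotype names must be non-empty")
        if self.sequences is not None:
            lengths = {len(s) for s in self.sequences.values()}
            if len(lengths) > 1:
                raise ValueError(
                    f"aligned sequences must have equal length, got {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.names)

    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    def sequence(self, name: str) -> str:
        if self.sequences is None or name not in self.sequences:
            raise KeyError(f"no sequence available for haplotype {name!r}")
        return self.sequences[name]


@dataclass(frozen=True)
class Diplotype:
    """Unordered haplotype pair carried by one individual."""

    individual_id: str
    hap1: str
    hap2: str

    @property
    def pair(self) -> tuple[str, str]:
        """Canonically (lexicographically) ordered pair."""
        return tuple(sorted((self.hap1, self.hap2)))  # type: ignore[return-value]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diplotype):
            return NotImplemented
        return self.individual_id == other.individual_id and self.pair == other.pair

    def __hash__(self) -> int:
        return hash((self.individual_id, self.pair))


def read_haplotype_fasta(path: str | Path) -> HaplotypeSet:
    """Load aligned amino-acid haplotype sequences (record id = haplotype label)."""
    names: list[str] = []
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate haplotype label {record.id!r} in FASTA")
        names.append(record.id)
        sequences[record.id] = str(record.seq).upper()
    if not names:
        raise ValueError(f"no FASTA records found in {path}")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError(
            f"haplotype sequences are not aligned (lengths {sorted(lengths)})"
        )
    return HaplotypeSet(names=tuple(names), sequences=sequences)


def write_haplotype_fasta(hs: HaplotypeSet, path: str | Path) -> None:
    if hs.sequences is None:
        raise ValueError("haplotype set carries no sequences")
    with open(path, "w") as fh:
        for name in hs.names:
            fh.write(f">{name}\n{hs.sequences[name]}\n")


def read_diplotypes(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a diplotype TSV with columns ID, HAP1, HAP2 into an id -> pair mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ID", "HAP1", "HAP2"}
    if not required <= set(df.columns):
        raise ValueError(f"diplotype file lacks columns: {sorted(required - set(df.columns))}")
    out: dict[str, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        if row.ID in out:
            raise ValueError(f"duplicate individual {row.ID!r} in diplotype file")
        out[row.ID] = (row.HAP1, row.HAP2)
    return out


def write_diplotypes(
    diplotypes: Mapping[str, tuple[str, str]], path: str | Path
) -> None:
    pd.DataFrame(
        [(i, h1, h2) for i, (h1, h2) in diplotypes.items()],
        columns=["ID", "HAP1", "HAP2"],
    ).to_csv(path, sep="\t", index=False)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of compared (pairwise-deletion) positions that differ.

    Positions where either sequence carries a gap are dropped before
    comparison.  Raises on length mismatch or when no comparable positions
    remain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    gap = GAP.encode()
    comparable = (a != gap) & (b != gap)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable (gap-free) positions between sequences")
    return float((a[comparable] != b[comparable]).sum() / n)


def diplotype_divergence(d: Diplotype, hs: HaplotypeSet) -> float:
    """Amino-acid p-distance between the two haplotypes of a diplotype."""
    if d.hap1 == d.hap2:
        return 0.0
    return p_distance(hs.sequence(d.hap1), hs.sequence(d.hap2))


def heterozygosity(d: Diplotype) -> int:
    """1 if the two haplotypes differ, else 0."""
    return int(d.hap1 != d.hap2)


def dosage_matrix(
    diplotypes: Iterable[Diplotype] | Mapping[str, tuple[str, str]],
    hs: HaplotypeSet,
) -> pd.DataFrame:
    """Individuals x haplotypes matrix of copy counts (0/1/2); rows sum to 2.

    Column sums divided by twice the number of rows give sample haplotype
    frequencies, which is what makes dosage the natural additive predictor.
    """
    if isinstance(diplotypes, Mapping):
        items = [Diplotype(i, h1, h2) for i, (h1, h2) in diplotypes.items()]
    else:
        items = list(diplotypes)
    index = hs.index()
    mat = np.zeros((len(items), len(hs)), dtype=np.int64)
    ids = []
    for row, d in enumerate(items):
        for hap in (d.hap1, d.hap2):
            if hap not in index:
                raise ValueError(
                    f"unknown haplotype label {hap!r} for individual {d.individual_id!r}"
                )
            mat[row, index[hap]] += 1
        ids.append(d.individual_id)
    return pd.DataFrame(mat, index=ids, columns=list(hs.names))
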