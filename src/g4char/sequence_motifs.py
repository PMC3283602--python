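"""DNA oligonucleotides, G-quadruplex motif scanning, and oligonucleotide masses.

A putative intramolecular G-quadruplex (G4) motif is four or more runs of
consecutive guanines ("G-tracts") on one strand, separated by short loops.
Four tracts of length >= 3 can fold into a three-layer G4, which is the
structural hypothesis the rest of this package characterizes by mass
spectrometry, circular dichroism, and thermal melting.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "Oligonucleotide",
    "G4Motif",
    "scan_g4_motifs",
    "predicted_tetrad_layers",
    "oligo_mass",
    "read_fasta",
    "ATOMIC_MASS",
    "RESIDUE_FORMULA",
    "WATER_FORMULA",
    "formula_mass",
]

MassMode = Literal["average", "monoisotopic"]

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Standard atomic masses (Da). Average values follow the IUPAC 2021
#: abridged table; monoisotopic values are the lightest-isotope masses.
ATOMIC_MASS: dict[str, dict[str, float]] = {
    "average": {
        "C": 12.011,
        "H": 1.008,
        "N": 14.007,
        "O": 15.999,
        "P": 30.973761998,
    },
    "monoisotopic": {
        "C": 12.0,
        "H": 1.00782503207,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "P": 30.97376163,
    },
}

#: Elemental composition of one internal deoxynucleotide residue
#: (nucleoside monophosphate minus water).
RESIDUE_FORMULA: dict[str, Counter] = {
    "A": Counter({"C": 10, "H": 12, "N": 5, "O": 5, "P": 1}),
    "C": Counter({"C": 9, "H": 12, "N": 3, "O": 6, "P": 1}),
    "G": Counter({"C": 10, "H": 12, "N": 5, "O": 6, "P": 1}),
    "T": Counter({"C": 10, "H": 13, "N": 2, "O": 7, "P": 1}),
}

WATER_FORMULA = Counter({"H": 2, "O": 1})


def formula_mass(formula: Counter, mode: MassMode = "average") -> float:
    """Mass in Da of an elemental formula given as an element->count mapping."""
    try:
        masses = ATOMIC_MASS[mode]
    except KeyError:
        raise ValueError(f"unknown mass mode {mode!r}") from None
    return sum(masses[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class Oligonucleotide:
    """A named single-stranded DNA sequence, read 5'->3'.

    The sequence is stored uppercase and must be non-empty over {A, C, G, T}.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("empty oligonucleotide sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"invalid DNA characters {sorted(bad)} in sequence {self.name!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "Oligonucleotide":
        rc = self.sequence.translate(_COMPLEMENT)[::-1]
        return Oligonucleotide(name=f"{self.name}_revcomp", sequence=rc)

    def composition(self) -> Counter:
        """Base counts of the sequence."""
        return Counter(self.sequence)

    def formula(self) -> Counter:
        """Elemental formula of the neutral oligonucleotide."""
        f = Counter()
        for base in self.sequence:
            f += RESIDUE_FORMULA[base]
        f += WATER_FORMULA
        return f

    def mass(self, mode: MassMode = "average") -> float:
        return oligo_mass(self, mode)


@dataclass(frozen=True)
class G4Motif:
    """A located putative G-quadruplex motif inside a parent sequence.

    ``tracts`` are half-open 0-based intervals of maximal G-runs (each of
    length >= the configured minimum), in 5'->3' order, and ``loops`` are
    the intervening subsequences between consecutive tracts.
    """

    parent: Oligonucleotide
    tracts: tuple[tuple[int, int], ...]
    min_tract: int = 3
    loop_bounds: tuple[int, int] = (1, 7)

    def __post_init__(self) -> None:
        if len(self.tracts) < 4:
            raise ValueError("a G4 motif needs at least 4 G-tracts")
        prev_end = -1
        for start, end in self.tracts:
            if not (0 <= start < end <= len(self.parent)):
                raise ValueError(f"tract ({start}, {end}) outside parent sequence")
            if start <= prev_end:
                raise ValueError("tracts must be ordered and non-overlapping")
            if end - start < self.min_tract:
                raise ValueError(
                    f"tract ({start}, {end}) shorter than minimum {self.min_tract}"
                )
            if set(self.parent.sequence[start:end]) != {"G"}:
                raise ValueError(f"tract ({start}, {end}) is not a G-run")
            prev_end = end
        lo, hi = self.loop_bounds
        for loop in self.loops:
            if not lo <= len(loop) <= hi:
                raise ValueError(f"loop {loop!r} outside bounds {self.loop_bounds}")

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    @property
    def min_tract_len(self) -> int:
        return min(end - start for start, end in self.tracts)

    @property
    def loops(self) -> tuple[str, ...]:
        seq = self.parent.sequence
        return tuple(
            seq[self.tracts[i][1] : self.tracts[i + 1][0]]
            for i in range(len(self.tracts) - 1)
        )

    @property
    def start(self) -> int:
        return self.tracts[0][0]

    @property
    def end(self) -> int:
        return self.tracts[-1][1]

    @property
    def sequence(self) -> str:
        return self.parent.sequence[self.start : self.end]


def scan_g4_motifs(
    seq: Oligonucleotide | str,
    min_tract: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
) -> list[G4Motif]:
    """Find putative G-quadruplex motifs on the given strand.

    Tracts are greedy maximal runs of >= ``min_tract`` guanines; consecutive
    tracts whose separation lies within ``[loop_min, loop_max]`` nucleotides
    are chained, and every maximal chain of at least four tracts is reported
    as one motif (alternative overlapping decompositions are not enumerated).
    Motifs are returned 5'->3' by start position.
    """
    if isinstance(seq, str):
        seq = Oligonucleotide(name="query", sequence=seq)
    if min_tract < 2:
        raise ValueError("min_tract must be >= 2")
    if not 1 <= loop_min <= loop_max:
        raise ValueError("need 1 <= loop_min <= loop_max")

    runs = [
        (m.start(), m.end())
        for m in re.finditer("G+", seq.sequence)
        if m.end() - m.start() >= min_tract
    ]

    motifs: list[G4Motif] = []
    chain: list[tuple[int, int]] = []

    def flush() -> None:
        if len(chain) >= 4:
            motifs.append(
                G4Motif(
                    parent=seq,
                    tracts=tuple(chain),
                    min_tract=min_tract,
                    loop_bounds=(loop_min, loop_max),
                )
            )

    for run in runs:
        if chain and loop_min <= run[0] - chain[-1][1] <= loop_max:
            chain.append(run)
        else:
            flush()
            chain = [run]
    flush()
    return motifs


def predicted_tetrad_layers(motif: G4Motif) -> tuple[int, int]:
    """Predicted number of stacked G-tetrad layers and interlayer cation sites.

    The shortest tract limits the stack height: a motif whose shortest tract
    has k guanines can stack k tetrads, with k - 1 monovalent cations (K+ or
    NH4+) sandwiched between adjacent layers.
    """
    layers = motif.min_tract_len
    return layers, layers - 1


def oligo_mass(seq: Oligonucleotide | str, mode: MassMode = "average") -> float:
    """Neutral mass (Da) of a linear, unmodified DNA oligonucleotide.

    Computed as the sum of per-residue masses (nucleoside monophosphate
    minus water, from the built-in elemental-composition table) plus one
    water, so mass is additive over concatenation up to one water:
    mass(s1 + s2) = mass(s1) + mass(s2) - m(H2O).
    """
    if isinstance(seq, str):
        seq = Oligonucleotide(name="query", sequence=seq)
    return formula_mass(seq.formula(), mode)


def read_fasta(path: str | Path) -> list[Oligonucleotide]:
    """Read a (multi-record) FASTA file into Oligonucleotide objects."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [Oligonucleotide(name=r.id, sequence=str(r.seq)) for r in records]
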