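"""Native electrospray mass spectrometry of DNA-ligand complexes.

Negative-mode ESI of a folded G-quadruplex produces multiply deprotonated
ions that can retain interlayer ammonium cations and non-covalently bound
ligand cations.  The ion-formula convention used throughout is that each
retained cation (NH4+ or a ligand cation) displaces one additional proton,
so an ion written [M + a*NH4 + b*L - (z+a+b)*H]^z- carries net charge -z.

From an assigned spectrum the relative-binding-affinity statistic IR_a is
computed: the summed relative intensity of all DNA-ligand complex ions
divided by the summed intensity of free plus complex ions, a dimensionless
ratio in [0, 1] that increases with ligand binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_motifs import ATOMIC_MASS, MassMode, Oligonucleotide, oligo_mass

__all__ = [
    "MassSpectrum",
    "IonSpecies",
    "PeakAssignment",
    "BindingTable",
    "theoretical_mz",
    "assign_peaks",
    "unassigned_peaks",
    "binding_table_from_assignments",
    "ira",
    "LIGAND_MASSES",
    "NH4_MASS",
    "PROTON_MASS",
]

#: Mass of the ammonium cation NH4 (Da); electron mass neglected at
#: ion-trap resolution.
NH4_MASS: dict[str, float] = {"average": 18.0385, "monoisotopic": 18.0343741}

#: Mass of a hydrogen atom (Da), used for deprotonation bookkeeping.
PROTON_MASS: dict[str, float] = {
    "average": ATOMIC_MASS["average"]["H"],
    "monoisotopic": ATOMIC_MASS["monoisotopic"]["H"],
}

#: Built-in ligand cation masses (Da).  Berberine is a planar isoquinoline
#: alkaloid cation (C20H18NO4+) that binds and stabilizes G-quadruplexes.
LIGAND_MASSES: dict[str, dict[str, float]] = {
    "berberine": {"average": 336.4, "monoisotopic": 336.1230},
}


@dataclass(frozen=True)
class IonSpecies:
    """A candidate ion: one oligonucleotide with a ammoniums, b ligands, charge z.

    ``charge`` is the magnitude of the negative charge; ``ligand_cation_mass``
    is the mass of the retained ligand cation in Da.
    """

    charge: int
    n_ammonium: int = 0
    n_ligand: int = 0
    ligand_cation_mass: float = LIGAND_MASSES["berberine"]["average"]

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge magnitude must be >= 1")
        if self.n_ammonium < 0 or self.n_ligand < 0:
            raise ValueError("cation counts must be non-negative")

    @property
    def label(self) -> str:
        parts = ["M"]
        if self.n_ammonium:
            parts.append(f"+{self.n_ammonium}NH4")
        if self.n_ligand:
            parts.append(f"+{self.n_ligand}L")
        n_h = self.charge + self.n_ammonium + self.n_ligand
        parts.append(f"-{n_h}H")
        return f"[{''.join(parts)}]{self.charge}-"


@dataclass
class MassSpectrum:
    """A centroided peak list: (m/z, relative intensity in % of base peak).

    Peaks are strictly increasing in m/z; intensities lie in (0, 100] with
    exactly one base peak at 100% when the spectrum is non-empty.
    """

    peaks: list[tuple[float, float]]
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = self.mz
        if len(mz) and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        ri = self.rel_intensity
        if len(ri):
            if np.any(ri <= 0) or np.any(ri > 100 + 1e-9):
                raise ValueError("relative intensities must lie in (0, 100]")
            n_base = int(np.sum(np.isclose(ri, 100.0, atol=1e-9)))
            if n_base != 1:
                raise ValueError(f"expected exactly one base peak, found {n_base}")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)

    @property
    def rel_intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)

    @classmethod
    def from_arrays(
        cls, mz: Sequence[float], intensity: Sequence[float], label: str = ""
    ) -> "MassSpectrum":
        """Build from raw arrays, sorting by m/z and normalizing to % of base peak."""
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.size == 0:
            return cls(peaks=[], label=label)
        order = np.argsort(mz)
        mz, intensity = mz[order], intensity[order]
        top = intensity.max()
        if top <= 0:
            raise ValueError("spectrum has no positive intensity")
        rel = 100.0 * intensity / top
        keep = rel > 0
        return cls(peaks=list(zip(mz[keep], rel[keep])), label=label)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "MassSpectrum":
        """Read a two-column (mz, intensity) CSV; intensities are re-normalized."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("spectrum CSV needs two columns: mz, intensity")
        return cls.from_arrays(
            df.iloc[:, 0].to_numpy(),
            df.iloc[:, 1].to_numpy(),
            label=label if label is not None else str(path),
        )


@dataclass(frozen=True)
class PeakAssignment:
    """A spectrum peak matched to an ion-species hypothesis."""

    peak_index: int
    species: IonSpecies
    mz_error: float  # observed - theoretical, Th


def theoretical_mz(
    M_oligo: float, species: IonSpecies, mode: MassMode = "average"
) -> float:
    """Theoretical m/z (Th) of a negative-mode DNA +/- ammonium +/- ligand ion.

    m/z = (M + a*m(NH4) + b*M_L - (z + a + b)*m(H)) / z : each retained
    cation displaces one extra proton so the net charge is -z.
    """
    if M_oligo <= 0:
        raise ValueError("oligonucleotide mass must be positive")
    a, b, z = species.n_ammonium, species.n_ligand, species.charge
    m_h = PROTON_MASS[mode]
    m = (
        M_oligo
        + a * NH4_MASS[mode]
        + b * species.ligand_cation_mass
        - (z + a + b) * m_h
    )
    return m / z


def assign_peaks(
    spectrum: MassSpectrum,
    oligo: Oligonucleotide,
    candidates: Sequence[IonSpecies],
    tol: float = 1.0,
    mode: MassMode = "average",
) -> list[PeakAssignment]:
    """Match spectrum peaks to candidate ion species within an m/z tolerance.

    Each peak gets at most one species and each species at most one peak;
    candidate-peak pairs are taken in order of increasing |m/z error|, ties
    broken toward smaller ligand count, then fewer ammoniums, then lower
    charge.  Peaks with no candidate within ``tol`` stay unassigned.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    M = oligo_mass(oligo, mode)
    mz_obs = spectrum.mz

    pairs = []
    for ci, sp in enumerate(candidates):
        mz_th = theoretical_mz(M, sp, mode)
        for pi in range(len(mz_obs)):
            err = mz_obs[pi] - mz_th
            if abs(err) <= tol:
                # quantize |error| so numerically exact ties break on species
                pairs.append(
                    (round(abs(err), 9), sp.n_ligand, sp.n_ammonium, sp.charge, ci, pi, err)
                )
    pairs.sort()

    assignments: list[PeakAssignment] = []
    used_peaks: set[int] = set()
    used_species: set[int] = set()
    for _, _, _, _, ci, pi, err in pairs:
        if pi in used_peaks or ci in used_species:
            continue
        used_peaks.add(pi)
        used_species.add(ci)
        assignments.append(
            PeakAssignment(peak_index=pi, species=candidates[ci], mz_error=err)
        )
    assignments.sort(key=lambda a: a.peak_index)
    return assignments


def unassigned_peaks(
    spectrum: MassSpectrum, assignments: Sequence[PeakAssignment]
) -> list[int]:
    """Indices of spectrum peaks not claimed by any assignment."""
    used = {a.peak_index for a in assignments}
    return [i for i in range(len(spectrum)) if i not in used]


@dataclass(frozen=True)
class BindingTable:
    """Summed relative intensities keyed by ligand stoichiometry b in {0,1,2,3}.

    Entry b pools every assigned peak with b bound ligands across all charge
    states and ammonium counts.  An all-zero table is flagged ``empty`` and
    cannot yield an IR_a value.
    """

    intensities: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.intensities) != 4:
            raise ValueError("binding table has stoichiometries 0..3")
        if any(v < 0 for v in self.intensities):
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_dict(cls, d: Mapping[int, float]) -> "BindingTable":
        extra = set(d) - {0, 1, 2, 3}
        if extra:
            raise ValueError(f"unsupported stoichiometries {sorted(extra)}")
        return cls(tuple(float(d.get(b, 0.0)) for b in range(4)))

    @property
    def empty(self) -> bool:
        return sum(self.intensities) == 0

    @property
    def free(self) -> float:
        return self.intensities[0]

    @property
    def complexed(self) -> float:
        return sum(self.intensities[1:])


def binding_table_from_assignments(
    assignments: Sequence[PeakAssignment], spectrum: MassSpectrum
) -> BindingTable:
    """Pool assigned-peak intensities by ligand stoichiometry.

    Missing stoichiometries contribute zero; an assignment-free spectrum
    yields the (flagged) all-zero table.
    """
    ri = spectrum.rel_intensity
    sums = [0.0, 0.0, 0.0, 0.0]
    for a in assignments:
        if not 0 <= a.peak_index < len(spectrum):
            raise ValueError(f"assignment refers to missing peak {a.peak_index}")
        b = min(a.species.n_ligand, 3)
        sums[b] += float(ri[a.peak_index])
    return BindingTable(tuple(sums))


def ira(table: BindingTable, round_to: int | None = 2) -> float:
    """Relative-binding-affinity statistic IR_a in [0, 1].

    IR_a = (sum of 1:1, 1:2 and 1:3 complex-ion intensities) / (that sum
    plus the free G-quadruplex intensity).  Undefined for an all-zero table.
    """
    total = sum(table.intensities)
    if total == 0:
        raise ValueError("IR_a undefined: all-zero binding table")
    value = table.complexed / total
    return round(value, round_to) if round_to is not None else value
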