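"""End-to-end characterization runs: scan -> MS assignment/IR_a -> CD call ->
melting fits and ligand-stabilization report, collected in one JSON-ready
report with per-stage error isolation."""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .cd_spectra import CDSpectrum, classify_topology
from .melting import (
    MeltingCurve,
    celsius_to_kelvin,
    normalize_curve,
    stabilization,
    vant_hoff_fit,
)
from .native_ms import (
    LIGAND_MASSES,
    BindingTable,
    IonSpecies,
    MassSpectrum,
    assign_peaks,
    binding_table_from_assignments,
    ira,
    unassigned_peaks,
)
from .sequence_motifs import Oligonucleotide, read_fasta, scan_g4_motifs, predicted_tetrad_layers
from .synthetic_data import (
    MUTANT_SEQUENCE,
    S1_SEQUENCE,
    GeneratorConfig,
    gen_cd_spectrum,
    gen_melting_curve,
    gen_ms_spectrum,
)

__all__ = ["RunReport", "run_characterization", "demo_config", "candidate_species"]


@dataclass
class RunReport:
    """Machine-readable record of one characterization run.

    Numeric fields are reproducible bit-for-bit under identical inputs and
    seeds; ``created`` is wall-clock metadata only.
    """

    config: dict
    stages: dict[str, Any] = field(default_factory=dict)
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds")
    )

    def to_dict(self) -> dict:
        return _jsonable(asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def candidate_species(
    ligand_mass: float,
    charges: Sequence[int] = (3, 4, 5),
    max_nh4: int = 3,
    max_ligand: int = 3,
) -> list[IonSpecies]:
    """Enumerate the ion-species hypotheses for peak assignment."""
    return [
        IonSpecies(charge=z, n_ammonium=a, n_ligand=b, ligand_cation_mass=ligand_mass)
        for z in charges
        for a in range(max_nh4 + 1)
        for b in range(max_ligand + 1)
    ]


def _resolve_ligand_mass(cfg: Mapping) -> float:
    if "ligand_mass" in cfg:
        return float(cfg["ligand_mass"])
    name = cfg.get("ligand", "berberine")
    try:
        return LIGAND_MASSES[name]["average"]
    except KeyError:
        raise ValueError(f"unknown ligand {name!r}; supply ligand_mass") from None


def _fit_to_dict(fit, t_ref_k: float | None) -> dict:
    d = {
        "tm_c": fit.tm_c,
        "dh_j_mol": fit.dh,
        "ds_j_mol_k": fit.ds,
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
        "tm_raw_c": fit.tm_raw_c,
        "label": fit.label,
    }
    if t_ref_k is not None:
        d["dg_kj_mol_at_tref"] = fit.gibbs(t_ref_k)
        d["t_ref_k"] = t_ref_k
    if "warning" in fit.diagnostics:
        d["warning"] = fit.diagnostics["warning"]
    return d


def _stage_scan(cfg: Mapping, seed: int) -> dict:
    if "fasta" in cfg:
        oligos = read_fasta(cfg["fasta"])
    else:
        oligos = [Oligonucleotide(cfg.get("name", "query"), cfg["sequence"])]
    kwargs = {
        k: cfg[k] for k in ("min_tract", "loop_min", "loop_max") if k in cfg
    }
    results = []
    for oligo in oligos:
        targets = [(oligo, "+")]
        if cfg.get("both_strands"):
            targets.append((oligo.reverse_complement(), "-"))
        for target, strand in targets:
            for m in scan_g4_motifs(target, **kwargs):
                layers, sites = predicted_tetrad_layers(m)
                results.append(
                    {
                        "name": oligo.name,
                        "strand": strand,
                        "start": m.start,
                        "end": m.end,
                        "n_tracts": m.n_tracts,
                        "tracts": list(m.tracts),
                        "loops": list(m.loops),
                        "min_tract_len": m.min_tract_len,
                        "predicted_layers": layers,
                        "interlayer_cation_sites": sites,
                        "sequence": m.sequence,
                    }
                )
    return {"n_sequences": len(oligos), "n_motifs": len(results), "motifs": results}


def _load_or_simulate_ms(cfg: Mapping, oligo: Oligonucleotide, seed: int) -> MassSpectrum:
    if "path" in cfg:
        return MassSpectrum.from_csv(cfg["path"])
    sim = cfg["simulate"]
    ligand_mass = _resolve_ligand_mass(cfg)
    z = int(sim.get("charge", 4))
    a = int(sim.get("n_ammonium", 2))
    species = [
        (
            IonSpecies(charge=z, n_ammonium=a, n_ligand=int(b), ligand_cation_mass=ligand_mass),
            float(pct),
        )
        for b, pct in sim["intensities"].items()
    ]
    gen_cfg = GeneratorConfig(seed=seed, noise_sd=float(sim.get("noise_sd", 0.0)))
    spectrum, _ = gen_ms_spectrum(
        species, oligo, peak_fwhm=float(sim.get("fwhm", 0.6)), cfg=gen_cfg
    )
    return spectrum


def _stage_ms(cfg: Mapping, seed: int) -> dict:
    oligo = Oligonucleotide(cfg.get("name", "query"), cfg["sequence"])
    spectrum = _load_or_simulate_ms(cfg, oligo, seed)
    ligand_mass = _resolve_ligand_mass(cfg)
    candidates = candidate_species(
        ligand_mass,
        charges=tuple(cfg.get("charges", (3, 4, 5))),
        max_nh4=int(cfg.get("max_nh4", 3)),
        max_ligand=int(cfg.get("max_ligand", 3)),
    )
    tol = float(cfg.get("tol", 1.0))
    assignments = assign_peaks(spectrum, oligo, candidates, tol=tol)
    table = binding_table_from_assignments(assignments, spectrum)

    base_idx = int(np.argmax(spectrum.rel_intensity))
    base_assignment = next(
        (a for a in assignments if a.peak_index == base_idx), None
    )
    dominant_complex = (
        base_assignment is not None and base_assignment.species.n_ligand >= 1
    )
    result = {
        "n_peaks": len(spectrum),
        "tol": tol,
        "assignments": [
            {
                "peak_index": a.peak_index,
                "mz": float(spectrum.mz[a.peak_index]),
                "rel_intensity": float(spectrum.rel_intensity[a.peak_index]),
                "species": a.species.label,
                "charge": a.species.charge,
                "n_ammonium": a.species.n_ammonium,
                "n_ligand": a.species.n_ligand,
                "mz_error": a.mz_error,
            }
            for a in assignments
        ],
        "unassigned_peaks": unassigned_peaks(spectrum, assignments),
        "binding_table": list(table.intensities),
        "binding_table_empty": table.empty,
        "dominant_complex_ion": dominant_complex,
    }
    result["ira"] = None if table.empty else ira(table)
    return result


def _stage_cd(cfg: Mapping, seed: int) -> dict:
    if "path" in cfg:
        spec = CDSpectrum.from_csv(cfg["path"])
    else:
        gen_cfg = GeneratorConfig(seed=seed, noise_sd=float(cfg.get("noise_sd", 0.0)))
        spec, _ = gen_cd_spectrum(cfg["simulate"], cfg=gen_cfg)
    call = classify_topology(spec, window=float(cfg.get("window", 6.0)))
    return {
        "label": spec.label,
        "call": call.call,
        "positive_max_nm": call.positive_max_nm,
        "negative_min_nm": call.negative_min_nm,
        "secondary_positive_nm": call.secondary_positive_nm,
    }


def _load_or_simulate_melt(entry: Mapping, seed: int) -> MeltingCurve:
    if "path" in entry:
        return MeltingCurve.from_csv(
            entry["path"], strand_concentration=entry.get("strand_concentration")
        )
    gen_cfg = GeneratorConfig(
        seed=seed,
        noise_sd=float(entry.get("noise_sd", 0.0)),
    )
    curve, _ = gen_melting_curve(entry["preset"], cfg=gen_cfg)
    return curve


def _fit_entry(entry: Mapping, seed: int, t_ref_k: float):
    curve = _load_or_simulate_melt(entry, seed)
    norm = normalize_curve(
        curve,
        lower_window=tuple(entry["lower_window"]) if "lower_window" in entry else None,
        upper_window=tuple(entry["upper_window"]) if "upper_window" in entry else None,
    )
    return vant_hoff_fit(norm)


def _stage_melting(cfg: Mapping, seed: int) -> dict:
    t_ref_k = float(celsius_to_kelvin(float(cfg.get("t_ref_c", 67.0))))
    result: dict[str, Any] = {"t_ref_c": float(cfg.get("t_ref_c", 67.0))}
    free_fit = _fit_entry(cfg["free"], seed, t_ref_k)
    result["free"] = _fit_to_dict(free_fit, t_ref_k)
    if "bound" in cfg:
        bound_fit = _fit_entry(cfg["bound"], seed, t_ref_k)
        result["bound"] = _fit_to_dict(bound_fit, t_ref_k)
        rep = stabilization(free_fit, bound_fit, t_ref_k)
        result["stabilization"] = {
            "ddh_j_mol": rep.ddh,
            "dds_j_mol_k": rep.dds,
            "ddg_kj_mol": rep.ddg,
            "dtm_c": rep.dtm,
            "t_ref_k": rep.t_ref_k,
        }
    return result


_STAGE_RUNNERS = {
    "scan": _stage_scan,
    "ms": _stage_ms,
    "cd": _stage_cd,
    "melting": _stage_melting,
}


def run_characterization(config: Mapping) -> RunReport:
    """Run the configured stages and collect a RunReport.

    ``config`` holds a ``seed``, an optional ``stages`` list, and one section
    per stage (``scan``, ``ms``, ``cd``, ``melting``).  A failing stage is
    recorded as an error entry without aborting the others; an unknown stage
    name or unreadable config raises immediately.
    """
    if not isinstance(config, Mapping):
        raise ValueError("config must be a mapping")
    seed = int(config.get("seed", 0))
    stages = config.get("stages")
    if stages is None:
        stages = [s for s in _STAGE_RUNNERS if s in config]
    unknown = set(stages) - set(_STAGE_RUNNERS)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")

    report = RunReport(config=_jsonable(dict(config)))
    for name in stages:
        if name not in config:
            report.stages[name] = {"error": f"missing config section {name!r}"}
            continue
        try:
            report.stages[name] = _STAGE_RUNNERS[name](config[name], seed)
        except Exception as exc:  # stage isolation
            report.stages[name] = {"error": f"{type(exc).__name__}: {exc}"}
    return report


def demo_config(seed: int = 0, mutant: bool = False) -> dict:
    """A self-contained demo run mirroring the characterization narrative.

    The wild-type configuration scans the relaxin G-rich strand, simulates
    the berberine-binding MS spectrum (free 30%, 1:1 100%, 1:2 75% at the
    4- charge state with two ammoniums), a parallel CD spectrum, and the
    KCl-free vs KCl-berberine melting pair.  With ``mutant=True`` the G->T
    mutant control is scanned and its MS spectrum has only the free DNA ion.
    """
    sequence = MUTANT_SEQUENCE if mutant else S1_SEQUENCE
    name = "S1-mutant" if mutant else "S1"
    ms_intensities = {0: 100} if mutant else {0: 30, 1: 100, 2: 75}
    cfg = {
        "seed": seed,
        "scan": {"sequence": sequence, "name": name},
        "ms": {
            "sequence": sequence,
            "name": name,
            "ligand": "berberine",
            "simulate": {"intensities": ms_intensities, "charge": 4, "n_ammonium": 2},
        },
        "cd": {"simulate": "mutant272" if mutant else "parallel"},
        "melting": {
            "free": {"preset": "KCl-free"},
            "bound": {"preset": "KCl-berberine"},
            "t_ref_c": 67.0,
        },
    }
    return cfg
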