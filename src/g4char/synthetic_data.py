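"""Seeded generators for instrument-like inputs: melting curves, native MS
spectra, and CD spectra.

Every generator is a pure function of its parameters and the config seed,
and returns the simulated data together with a "truth" record holding the
generating parameters, so every downstream fit doubles as a
parameter-recovery test.

Melting presets mirror three measured conditions for the relaxin-promoter
G-quadruplex: Tm = 67 degC in 100 mM KCl, 77 degC after adding berberine at
1:4, and 37 degC in 100 mM LiCl.  The generator enthalpy is fixed at
-200 kJ/mol (folding direction), a typical van't Hoff enthalpy for a sharp
three-tetrad intramolecular transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .cd_spectra import CDSpectrum
from .melting import GAS_CONSTANT, MeltingCurve, celsius_to_kelvin
from .native_ms import IonSpecies, MassSpectrum, theoretical_mz
from .sequence_motifs import Oligonucleotide, oligo_mass

__all__ = [
    "GeneratorConfig",
    "MeltPreset",
    "MELT_PRESETS",
    "S1_SEQUENCE",
    "MUTANT_SEQUENCE",
    "gen_melting_curve",
    "gen_ms_spectrum",
    "gen_cd_spectrum",
]

#: The relaxin-promoter G-rich strand and its G->T mutant control.
S1_SEQUENCE = "GGGAGGGAAGGGAAGGG"
MUTANT_SEQUENCE = "GTGAGTGAAGTGAAGTG"


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded generator settings; identical config + seed => identical output.

    ``noise_sd`` is a fraction of the signal amplitude (0 disables noise).
    Grid parameters override the per-generator defaults when set.
    """

    seed: int = 0
    noise_sd: float = 0.0
    mz_step: float = 0.05
    wavelength_range: tuple[float, float] = (220.0, 320.0)
    wavelength_step: float = 0.5
    temperature_range: tuple[float, float] | None = None
    temperature_step: float = 0.5

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class MeltPreset:
    """Generating parameters for a two-state melting curve.

    Baselines are (intercept, slope) lines in the temperature (degC) domain;
    ``folded_baseline`` is the low-temperature signal level and
    ``unfolded_baseline`` the high-temperature one, in mdeg-like units.
    """

    name: str
    tm_c: float
    dh: float = -200e3  # J/mol, folding direction
    folded_baseline: tuple[float, float] = (14.0, -0.02)
    unfolded_baseline: tuple[float, float] = (2.5, -0.008)
    temperature_range: tuple[float, float] = (20.0, 95.0)


MELT_PRESETS: dict[str, MeltPreset] = {
    # 10 uM strand in 100 mM KCl, 30 mM Tris-HCl pH 7.4
    "KCl-free": MeltPreset(name="KCl-free", tm_c=67.0),
    # same buffer after adding berberine at a 1:4 strand:ligand ratio
    "KCl-berberine": MeltPreset(name="KCl-berberine", tm_c=77.0),
    # 100 mM LiCl destabilizes the fold; window shifted to bracket Tm
    "LiCl-free": MeltPreset(
        name="LiCl-free", tm_c=37.0, temperature_range=(10.0, 75.0)
    ),
}


def _two_state_theta(t_k: np.ndarray, tm_k: float, dh: float) -> np.ndarray:
    ln_k = -(dh / GAS_CONSTANT) * (1.0 / t_k - 1.0 / tm_k)
    return 1.0 / (1.0 + np.exp(-np.clip(ln_k, -500, 500)))


def gen_melting_curve(
    preset: MeltPreset | str,
    cfg: GeneratorConfig = GeneratorConfig(),
    strand_concentration: float | None = 10e-6,
) -> tuple[MeltingCurve, dict]:
    """Simulate a two-state melting curve with sloping linear baselines.

    theta(T) = K/(1+K) with ln K = -(dH/R)(1/T - 1/Tm); the signal is
    unfolded(T) + [folded(T) - unfolded(T)] * theta(T), plus Gaussian noise
    of sd = noise_sd * amplitude when noise_sd > 0.  Returns the curve and a
    truth record with every generating parameter.
    """
    if isinstance(preset, str):
        preset = MELT_PRESETS[preset]
    t0, t1 = cfg.temperature_range or preset.temperature_range
    t_c = np.arange(t0, t1 + cfg.temperature_step / 2, cfg.temperature_step)
    t_k = celsius_to_kelvin(t_c)
    tm_k = float(celsius_to_kelvin(preset.tm_c))
    theta = _two_state_theta(t_k, tm_k, preset.dh)

    fb = preset.folded_baseline[0] + preset.folded_baseline[1] * t_c
    ub = preset.unfolded_baseline[0] + preset.unfolded_baseline[1] * t_c
    signal = ub + (fb - ub) * theta

    amplitude = float(np.median(np.abs(fb - ub)))
    truth: dict = {
        "preset": preset.name,
        "tm_c": preset.tm_c,
        "dh": preset.dh,
        "ds": preset.dh / tm_k,
        "folded_baseline": preset.folded_baseline,
        "unfolded_baseline": preset.unfolded_baseline,
        "temperature_range": (float(t0), float(t1)),
        "temperature_step": cfg.temperature_step,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "theta": theta,
    }
    if not t0 <= preset.tm_c <= t1:
        truth["warning"] = "temperature grid does not bracket the preset Tm"
    if cfg.noise_sd > 0:
        signal = signal + cfg.rng().normal(0.0, cfg.noise_sd * amplitude, t_c.shape)
    curve = MeltingCurve(
        temperature=t_c,
        signal=signal,
        label=preset.name,
        strand_concentration=strand_concentration,
    )
    return curve, truth


def gen_ms_spectrum(
    species_intensities: Sequence[tuple[IonSpecies, float]],
    oligo: Oligonucleotide | str,
    peak_fwhm: float = 0.6,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[MassSpectrum, dict]:
    """Simulate a centroided negative-mode ESI spectrum of DNA complexes.

    Gaussian profiles of width ``peak_fwhm`` are placed at the theoretical
    m/z of each species (scaled to the given relative intensities, exactly
    one of which must be 100), summed on an m/z grid with optional Gaussian
    baseline noise, then centroided back to a peak list normalized to % of
    base peak.  Species closer than one FWHM merge and are flagged in the
    truth record.
    """
    if isinstance(oligo, str):
        oligo = Oligonucleotide(name="query", sequence=oligo)
    if not species_intensities:
        raise ValueError("need at least one species")
    heights = [h for _, h in species_intensities]
    if any(h <= 0 or h > 100 for h in heights):
        raise ValueError("intensities must lie in (0, 100]")
    if sum(1 for h in heights if h == 100) != 1:
        raise ValueError("exactly one species must be at 100%")

    M = oligo_mass(oligo)
    centers = [theoretical_mz(M, sp) for sp, _ in species_intensities]
    sigma = peak_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    truth: dict = {
        "oligo": oligo.sequence,
        "oligo_mass": M,
        "peak_fwhm": peak_fwhm,
        "species": [
            {
                "charge": sp.charge,
                "n_ammonium": sp.n_ammonium,
                "n_ligand": sp.n_ligand,
                "mz": mz,
                "intensity": h,
            }
            for (sp, h), mz in zip(species_intensities, centers)
        ],
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
    }
    order = np.argsort(centers)
    sorted_centers = np.asarray(centers)[order]
    if np.any(np.diff(sorted_centers) < peak_fwhm):
        truth["warning"] = "species closer than one FWHM: merged peaks likely"

    grid = np.arange(
        min(centers) - 10 * peak_fwhm,
        max(centers) + 10 * peak_fwhm,
        cfg.mz_step,
    )
    profile = np.zeros_like(grid)
    for c, (_, h) in zip(centers, species_intensities):
        profile += h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    if cfg.noise_sd > 0:
        profile = profile + cfg.rng().normal(
            0.0, cfg.noise_sd * profile.max(), grid.shape
        )

    # centroid: local maxima above a 1% floor, intensity-weighted centers
    idx, _ = find_peaks(profile, height=0.01 * profile.max())
    half = max(1, int(round(3 * sigma / cfg.mz_step)))
    mzs, hts = [], []
    for i in idx:
        sl = slice(max(0, i - half), min(grid.size, i + half + 1))
        w = np.clip(profile[sl], 0, None)
        if w.sum() <= 0:
            continue
        mzs.append(float(np.sum(grid[sl] * w) / w.sum()))
        hts.append(float(profile[i]))
    spectrum = MassSpectrum.from_arrays(mzs, hts, label=f"sim:{oligo.name}")
    return spectrum, truth


#: CD band models (center nm, amplitude mdeg, sigma nm) per topology tag.
_CD_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "parallel": ((264.0, 10.0, 8.0), (242.0, -6.0, 7.0)),
    "antiparallel": ((295.0, 8.0, 9.0), (265.0, -5.0, 9.0)),
    "mutant272": ((272.0, 6.0, 10.0),),
}


def gen_cd_spectrum(
    topology: str,
    cfg: GeneratorConfig = GeneratorConfig(),
    amplitude_scale: float = 1.0,
) -> tuple[CDSpectrum, dict]:
    """Simulate a CD spectrum as a sum of Gaussian bands.

    ``topology`` is one of 'parallel' (+264/-242 nm), 'antiparallel'
    (+295/-265 nm) or 'mutant272' (+272 nm only, the non-G4 control
    signature).  Gaussian noise of sd = noise_sd * max band amplitude is
    added when noise_sd > 0.
    """
    try:
        bands = _CD_BANDS[topology]
    except KeyError:
        raise ValueError(
            f"unknown topology {topology!r}; expected one of {sorted(_CD_BANDS)}"
        ) from None
    lo, hi = cfg.wavelength_range
    wl = np.arange(lo, hi + cfg.wavelength_step / 2, cfg.wavelength_step)
    y = np.zeros_like(wl)
    for center, amp, sig in bands:
        y += amplitude_scale * amp * np.exp(-0.5 * ((wl - center) / sig) ** 2)
    if cfg.noise_sd > 0:
        scale = amplitude_scale * max(abs(b[1]) for b in bands)
        y = y + cfg.rng().normal(0.0, cfg.noise_sd * scale, wl.shape)
    truth = {
        "topology": topology,
        "bands": [
            {"center": c, "amplitude": amplitude_scale * a, "sigma": s}
            for c, a, s in bands
        ],
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
    }
    return CDSpectrum(wavelengths=wl, ellipticity=y, label=f"sim:{topology}"), truth
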