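"""Circular dichroism spectra: extremum detection and G4 topology calls.

Parallel-stranded G-quadruplexes show a positive CD band near 264 nm with a
negative band near 242 nm; antiparallel topologies show the positive band
near 295 nm.  Classification here is a band-position rule on the smoothed
spectrum's global positive maximum, with a configurable wavelength window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import argrelextrema

__all__ = ["CDSpectrum", "TopologyCall", "find_extrema", "classify_topology"]


@dataclass
class CDSpectrum:
    """Ellipticity (mdeg) on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    ellipticity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise ValueError("wavelength and ellipticity arrays differ in length")
        if self.wavelengths.size < 10:
            raise ValueError("CD spectrum needs at least 10 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "CDSpectrum":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("CD CSV needs two columns: wavelength, ellipticity")
        wl = df.iloc[:, 0].to_numpy(dtype=float)
        el = df.iloc[:, 1].to_numpy(dtype=float)
        order = np.argsort(wl)
        return cls(wl[order], el[order], label=label if label is not None else str(path))


@dataclass(frozen=True)
class TopologyCall:
    """A topology classification with its band-position evidence.

    ``positive_max_nm`` / ``negative_min_nm`` are the grid wavelengths of the
    global positive maximum and global negative minimum of the smoothed
    spectrum (None where the spectrum has no signal of that sign).
    """

    call: str  # parallel | antiparallel | other
    positive_max_nm: float | None
    negative_min_nm: float | None
    secondary_positive_nm: float | None = None


def _smooth(spec: CDSpectrum, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window >= spec.wavelengths.size:
        raise ValueError("smoothing window exceeds spectrum length")
    if window == 1:
        return spec.ellipticity.copy()
    return uniform_filter1d(spec.ellipticity, size=window, mode="nearest")


def find_extrema(
    spec: CDSpectrum, smooth_window: int = 5
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Positive maxima and negative minima of the moving-average-smoothed signal.

    Returns two lists of (wavelength nm, smoothed ellipticity): local maxima
    with positive signal and local minima with negative signal, at grid
    wavelengths.  Deterministic; a flat spectrum has no extrema.
    """
    y = _smooth(spec, smooth_window)
    wl = spec.wavelengths
    imax = argrelextrema(y, np.greater)[0]
    imin = argrelextrema(y, np.less)[0]
    maxima = [(float(wl[i]), float(y[i])) for i in imax if y[i] > 0]
    minima = [(float(wl[i]), float(y[i])) for i in imin if y[i] < 0]
    return maxima, minima


def classify_topology(
    spec: CDSpectrum,
    parallel_max: float = 264.0,
    antiparallel_max: float = 295.0,
    window: float = 6.0,
    smooth_window: int = 5,
) -> TopologyCall:
    """Classify G4 topology from CD band positions.

    The call is ``parallel`` if the global positive maximum lies within
    +/- ``window`` nm of ``parallel_max``, ``antiparallel`` if within the
    antiparallel window, ``other`` otherwise.  Spectra showing comparable
    positive local maxima in both windows (hybrid-like) are reported as
    ``other`` with both wavelengths as evidence; spectra with no positive
    signal are ``other`` with empty evidence.
    """
    y = _smooth(spec, smooth_window)
    wl = spec.wavelengths

    i_top = int(np.argmax(y))
    if y[i_top] <= 0:
        return TopologyCall(call="other", positive_max_nm=None, negative_min_nm=None)
    pos_nm = float(wl[i_top])

    i_bot = int(np.argmin(y))
    neg_nm = float(wl[i_bot]) if y[i_bot] < 0 else None

    # hybrid guard: a secondary positive local maximum in the other band
    # window with at least half the primary amplitude
    maxima, _ = find_extrema(spec, smooth_window)
    in_par = [m for m in maxima if abs(m[0] - parallel_max) <= window]
    in_anti = [m for m in maxima if abs(m[0] - antiparallel_max) <= window]
    if in_par and in_anti:
        a_par = max(v for _, v in in_par)
        a_anti = max(v for _, v in in_anti)
        if min(a_par, a_anti) >= 0.5 * max(a_par, a_anti):
            secondary = (
                max(in_anti, key=lambda m: m[1])[0]
                if abs(pos_nm - parallel_max) <= window
                else max(in_par, key=lambda m: m[1])[0]
            )
            return TopologyCall(
                call="other",
                positive_max_nm=pos_nm,
                negative_min_nm=neg_nm,
                secondary_positive_nm=float(secondary),
            )

    if abs(pos_nm - parallel_max) <= window:
        call = "parallel"
    elif abs(pos_nm - antiparallel_max) <= window:
        call = "antiparallel"
    else:
        call = "other"
    return TopologyCall(call=call, positive_max_nm=pos_nm, negative_min_nm=neg_nm)
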