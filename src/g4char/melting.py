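"""Thermal melting analysis: baseline normalization, van't Hoff fits, and
ligand-stabilization deltas.

The model is an intramolecular two-state equilibrium between folded and
unfolded DNA.  With theta the folded fraction, K(T) = theta / (1 - theta)
is concentration-independent, and ln K is linear in 1/T:

    ln K = -dH/(R T) + dS/R

so a linear regression of ln K on 1/T yields the van't Hoff enthalpy
(slope = -dH/R) and entropy (intercept = dS/R); the melting temperature Tm
is the ln K = 0 crossing, i.e. Tm = dH/dS in kelvin.  Signs follow the
folding direction (dH < 0 for a fold stable at low temperature); the
unfolding-direction values are the negatives and are kept in diagnostics.

Raw melting curves carry sloping linear baselines for the folded and
unfolded states.  ``normalize_curve`` fits those baselines in user-chosen
low- and high-temperature windows and converts signal to theta.  Because a
broad transition leaks into any finite baseline window, the baseline fit is
refined iteratively against the current two-state model estimate; on
noiseless two-state input this converges to the exact theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GAS_CONSTANT",
    "MeltingCurve",
    "NormalizedCurve",
    "ThermoFit",
    "StabilizationReport",
    "NoTransitionError",
    "InsufficientTransitionError",
    "normalize_curve",
    "vant_hoff_fit",
    "gibbs",
    "stabilization",
    "intramolecularity_check",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

GAS_CONSTANT = 8.314  # J/(mol K)
_ZERO_C = 273.15


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + _ZERO_C


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - _ZERO_C


class NoTransitionError(ValueError):
    """The curve shows no resolvable folded-to-unfolded transition."""


class InsufficientTransitionError(ValueError):
    """Too few points inside the transition band for a van't Hoff fit."""


@dataclass
class MeltingCurve:
    """Signal (CD ellipticity at a fixed wavelength) vs temperature in Celsius."""

    temperature: np.ndarray  # degC, strictly increasing
    signal: np.ndarray
    label: str = ""
    strand_concentration: float | None = None  # molar, optional

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal arrays differ in length")
        if self.temperature.size < 15:
            raise ValueError("melting curve needs at least 15 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temperature[-1] - self.temperature[0] < 30:
            raise ValueError("melting curve must span at least 30 degC")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.temperature[0]), float(self.temperature[-1])

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        label: str | None = None,
        strand_concentration: float | None = None,
    ) -> "MeltingCurve":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("melting CSV needs two columns: temperature, signal")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        s = df.iloc[:, 1].to_numpy(dtype=float)
        order = np.argsort(t)
        return cls(
            t[order],
            s[order],
            label=label if label is not None else str(path),
            strand_concentration=strand_concentration,
        )


@dataclass
class NormalizedCurve:
    """Folded fraction theta vs absolute temperature (kelvin)."""

    temperature_k: np.ndarray
    theta: np.ndarray
    label: str = ""
    strand_concentration: float | None = None
    folded_baseline: tuple[float, float] = (np.nan, np.nan)  # intercept, slope
    unfolded_baseline: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        self.temperature_k = np.asarray(self.temperature_k, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.temperature_k.shape != self.theta.shape:
            raise ValueError("temperature and theta arrays differ in length")


@dataclass
class ThermoFit:
    """Two-state van't Hoff parameters for one melting curve.

    dH and dS are in the folding direction (J/mol and J/(mol K)); the
    unfolding-direction values are their negatives, kept in ``diagnostics``.
    ``tm_c`` is the ln K = 0 crossing of the regression; ``tm_raw_c`` is the
    raw theta = 0.5 interpolation of the normalized data.
    """

    tm_c: float
    dh: float
    ds: float
    r_squared: float = float("nan")
    n_points: int = 0
    tm_raw_c: float | None = None
    label: str = ""
    strand_concentration: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def gibbs(self, t_ref_k: float, round_to: int | None = 1) -> float:
        """dG (kJ/mol) at a reference temperature via dG = dH - T dS."""
        return gibbs(self.dh, self.ds, t_ref_k, round_to=round_to)


@dataclass(frozen=True)
class StabilizationReport:
    """Ligand-induced thermodynamic differences, bound minus free."""

    ddh: float  # J/mol
    dds: float  # J/(mol K)
    ddg: float  # kJ/mol at t_ref_k
    dtm: float  # degC
    t_ref_k: float


def _linear_fit(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, s, 1)
    return float(intercept), float(slope)


def _eval_line(line: tuple[float, float], t: np.ndarray) -> np.ndarray:
    intercept, slope = line
    return intercept + slope * t


def normalize_curve(
    raw: MeltingCurve,
    lower_window: tuple[float, float] | None = None,
    upper_window: tuple[float, float] | None = None,
    max_refine: int = 100,
    theta_band: tuple[float, float] = (0.15, 0.85),
) -> NormalizedCurve:
    """Convert a raw melting curve to folded fraction theta.

    Linear baselines are fit in the ``lower_window`` (low temperature, folded
    state) and ``upper_window`` (high temperature, unfolded state); theta is
    (signal - unfolded)/(folded - unfolded), which is 1 at low temperature by
    construction regardless of signal polarity.  Window defaults are the
    first 15% and last 10% of the temperature span.

    With ``max_refine`` > 0 the baselines are re-estimated iteratively: the
    current theta is van't Hoff-fitted, the implied two-state theta is used
    to deconvolve residual transition signal from the window points, and the
    baselines are re-solved by least squares.  On noiseless two-state data
    this converges to the generator's exact theta; it is a no-op when the
    windows are free of transition signal.
    """
    t_c, s = raw.temperature, raw.signal
    t0, t1 = raw.span
    span = t1 - t0
    if lower_window is None:
        lower_window = (t0, t0 + 0.15 * span)
    if upper_window is None:
        upper_window = (t1 - 0.10 * span, t1)
    lo_a, lo_b = lower_window
    up_a, up_b = upper_window
    if lo_a < t0 - 1e-9 or up_b > t1 + 1e-9:
        raise ValueError("baseline windows must lie inside the temperature span")
    if lo_b >= up_a:
        raise ValueError("baseline windows must not overlap")
    m_lo = (t_c >= lo_a - 1e-9) & (t_c <= lo_b + 1e-9)
    m_up = (t_c >= up_a - 1e-9) & (t_c <= up_b + 1e-9)
    if m_lo.sum() < 3 or m_up.sum() < 3:
        raise ValueError("each baseline window needs at least 3 points")

    folded = _linear_fit(t_c[m_lo], s[m_lo])
    unfolded = _linear_fit(t_c[m_up], s[m_up])

    amp = _eval_line(folded, t_c) - _eval_line(unfolded, t_c)
    signal_range = float(s.max() - s.min())
    if np.median(np.abs(amp)) < max(1e-12, 0.05 * signal_range):
        raise NoTransitionError(
            "folded and unfolded baselines coincide: no transition to normalize"
        )

    theta = (s - _eval_line(unfolded, t_c)) / amp
    t_k = celsius_to_kelvin(t_c)
    m_win = m_lo | m_up

    def _model_rss(state: tuple) -> float:
        """Full-curve residual of the two-state reconstruction of the signal."""
        fold, unfold, th = state
        params = _vant_hoff_regression(t_k, th, theta_band)
        if params is None:
            return np.inf
        slope, intercept = params
        ln_k = slope / t_k + intercept
        th_model = 1.0 / (1.0 + np.exp(-np.clip(ln_k, -500, 500)))
        fb, ub = _eval_line(fold, t_c), _eval_line(unfold, t_c)
        return float(np.sum((s - (ub + (fb - ub) * th_model)) ** 2))

    # Iteratively deconvolve residual transition signal from the baseline
    # windows; with noise the iteration can wander, so the iterate whose
    # implied two-state model best reconstructs the whole curve wins.
    best_state = (folded, unfolded, theta)
    best_rss = _model_rss(best_state)
    for _ in range(max_refine):
        params = _vant_hoff_regression(t_k, theta, theta_band)
        if params is None:
            break
        slope, intercept = params
        ln_k = slope / t_k + intercept
        theta_model = 1.0 / (1.0 + np.exp(-np.clip(ln_k, -500, 500)))
        # window points: signal = folded*theta + unfolded*(1-theta), linear
        # in the four baseline coefficients
        th_w = theta_model[m_win]
        t_w = t_c[m_win]
        design = np.column_stack(
            [th_w, th_w * t_w, 1.0 - th_w, (1.0 - th_w) * t_w]
        )
        coef, *_ = np.linalg.lstsq(design, s[m_win], rcond=None)
        new_folded = (float(coef[0]), float(coef[1]))
        new_unfolded = (float(coef[2]), float(coef[3]))
        new_amp = _eval_line(new_folded, t_c) - _eval_line(new_unfolded, t_c)
        if np.median(np.abs(new_amp)) < max(1e-12, 0.05 * signal_range):
            break  # refinement degenerated; keep previous baselines
        new_theta = (s - _eval_line(new_unfolded, t_c)) / new_amp
        converged = np.max(np.abs(new_theta - theta)) < 1e-12
        folded, unfolded, theta = new_folded, new_unfolded, new_theta
        rss = _model_rss((folded, unfolded, theta))
        if rss < best_rss:
            best_rss, best_state = rss, (folded, unfolded, theta)
        if converged:
            break
    folded, unfolded, theta = best_state

    return NormalizedCurve(
        temperature_k=t_k,
        theta=theta,
        label=raw.label,
        strand_concentration=raw.strand_concentration,
        folded_baseline=folded,
        unfolded_baseline=unfolded,
    )


def _vant_hoff_regression(
    t_k: np.ndarray, theta: np.ndarray, theta_band: tuple[float, float]
) -> tuple[float, float] | None:
    """Regress ln K on 1/T over the in-band points; None if under-determined."""
    lo, hi = theta_band
    th = np.clip(theta, 1e-9, 1 - 1e-9)
    band = (th >= lo) & (th <= hi)
    if band.sum() < 5:
        return None
    ln_k = np.log(th[band] / (1 - th[band]))
    res = stats.linregress(1.0 / t_k[band], ln_k)
    if not np.isfinite(res.slope) or res.slope == 0:
        return None
    return float(res.slope), float(res.intercept)


def _raw_tm(t_k: np.ndarray, theta: np.ndarray) -> float | None:
    """Linear interpolation of the first theta = 0.5 crossing, in Celsius."""
    d = theta - 0.5
    sign_change = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if d[0] == 0:
        return float(kelvin_to_celsius(t_k[0]))
    if sign_change.size == 0:
        return None
    i = int(sign_change[0])
    if d[i + 1] == d[i]:
        return float(kelvin_to_celsius(t_k[i]))
    frac = -d[i] / (d[i + 1] - d[i])
    return float(kelvin_to_celsius(t_k[i] + frac * (t_k[i + 1] - t_k[i])))


def vant_hoff_fit(
    curve: NormalizedCurve, theta_band: tuple[float, float] = (0.15, 0.85)
) -> ThermoFit:
    """Fit the intramolecular two-state van't Hoff model to a normalized curve.

    Only points with theta inside ``theta_band`` enter the ln K vs 1/T
    regression (the default [0.15, 0.85] band avoids baseline-dominated
    divergence of ln K).  Requires at least 5 in-band points.
    """
    t_k, theta = curve.temperature_k, np.clip(curve.theta, 1e-9, 1 - 1e-9)
    lo, hi = theta_band
    band = (theta >= lo) & (theta <= hi)
    n = int(band.sum())
    if n < 5:
        raise InsufficientTransitionError(
            f"only {n} points with theta in [{lo}, {hi}]; need >= 5"
        )
    ln_k = np.log(theta[band] / (1 - theta[band]))
    inv_t = 1.0 / t_k[band]
    res = stats.linregress(inv_t, ln_k)
    dh = -GAS_CONSTANT * res.slope  # folding direction
    ds = GAS_CONSTANT * res.intercept
    if ds == 0:
        raise InsufficientTransitionError("zero fitted dS; Tm undefined")
    tm_k = dh / ds  # ln K = 0 crossing
    diag: dict = {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "unfolding_dh": -dh,
        "unfolding_ds": -ds,
        "theta_band": theta_band,
    }
    in_band_theta = theta[band]
    if np.any(np.diff(in_band_theta) > 0):
        diag["warning"] = "non-monotone theta inside the fitting band"
    return ThermoFit(
        tm_c=float(kelvin_to_celsius(tm_k)),
        dh=float(dh),
        ds=float(ds),
        r_squared=float(res.rvalue**2),
        n_points=n,
        tm_raw_c=_raw_tm(t_k, curve.theta),
        label=curve.label,
        strand_concentration=curve.strand_concentration,
        diagnostics=diag,
    )


def gibbs(
    dh: float, ds: float, t_ref_k: float, round_to: int | None = 1
) -> float:
    """Gibbs free energy dG = dH - T dS, reported in kJ/mol.

    ``dh`` in J/mol, ``ds`` in J/(mol K); rounded to ``round_to`` decimals
    for reporting (None for the raw value).
    """
    if t_ref_k < 0:
        raise ValueError("reference temperature must be non-negative (kelvin)")
    value = (dh - t_ref_k * ds) / 1000.0
    return round(value, round_to) if round_to is not None else value


def stabilization(
    free: ThermoFit, bound: ThermoFit, t_ref_k: float
) -> StabilizationReport:
    """Ligand-induced stabilization: component-wise bound minus free.

    dG values are evaluated at the same ``t_ref_k`` before differencing;
    ddG is reported to 1 decimal (kJ/mol) to match the precision the other
    reported energies carry.
    """
    dg_free = gibbs(free.dh, free.ds, t_ref_k, round_to=None)
    dg_bound = gibbs(bound.dh, bound.ds, t_ref_k, round_to=None)
    return StabilizationReport(
        ddh=bound.dh - free.dh,
        dds=bound.ds - free.ds,
        ddg=round(dg_bound - dg_free, 1),
        dtm=bound.tm_c - free.tm_c,
        t_ref_k=t_ref_k,
    )


def intramolecularity_check(
    fits: Sequence[ThermoFit], tol: float = 1.0
) -> tuple[bool, dict]:
    """Test for concentration-independent Tm across strand concentrations.

    An intramolecular fold melts at the same Tm regardless of strand
    concentration; returns True iff the maximum pairwise |Tm difference|
    is within ``tol`` degC, with a per-concentration Tm report.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits at distinct concentrations")
    tms = [f.tm_c for f in fits]
    max_diff = max(tms) - min(tms)
    report = {
        "tm_by_concentration": [
            {"strand_concentration": f.strand_concentration, "tm_c": f.tm_c, "label": f.label}
            for f in fits
        ],
        "max_tm_difference_c": max_diff,
        "tolerance_c": tol,
    }
    return bool(max_diff <= tol), report
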