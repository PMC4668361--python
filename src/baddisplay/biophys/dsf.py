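"""Differential scanning fluorimetry (thermal shift) curves and Tm extraction.

A melt curve is modeled as a linear baseline plus a sum of logistic
(two-state) unfolding transitions,

    F(T) = b0 + b1*T + sum_j A_j / (1 + exp((Tm_j - T) / w_j)),

acquired on a 20-100 degC grid at 0.2 degC steps.  Transitions are located
as peaks of the smoothed first derivative dF/dT and each is refined by a
local logistic fit.  A multi-domain construct (Fab + CH2 + CH3) shows
several transitions; the Fab melt is assigned to the largest-amplitude one,
the CH2/CH3 transitions being reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from ..errors import ConfigError, NoTransitionError

DEFAULT_T_MIN = 20.0
DEFAULT_T_MAX = 100.0
DEFAULT_T_STEP = 0.2


def default_temperature_grid(
    t_min: float = DEFAULT_T_MIN,
    t_max: float = DEFAULT_T_MAX,
    step: float = DEFAULT_T_STEP,
) -> np.ndarray:
    n = int(round((t_max - t_min) / step)) + 1
    return t_min + step * np.arange(n)


@dataclass(frozen=True)
class Transition:
    """A two-state unfolding transition: midpoint, signal amplitude, width."""

    tm: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence vs temperature trace."""

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("temperatures and fluorescence must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"temperature_C": self.temperatures, "fluorescence": self.fluorescence}
        ).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeltCurve":
        df = pd.read_csv(path)
        return cls(df["temperature_C"].to_numpy(), df["fluorescence"].to_numpy())


@dataclass(frozen=True)
class MeltFitResult:
    """Detected transitions plus the Fab-melt assignment."""

    transitions: tuple[Transition, ...]
    assigned_fab_tm: float


def simulate_melt_curve(
    transitions: Sequence[Transition],
    baseline_slope: float = 0.0,
    baseline_intercept: float = 0.0,
    noise_sd: float = 0.0,
    grid: Optional[np.ndarray] = None,
    seed: int = 0,
) -> MeltCurve:
    """Generate a melt curve from logistic transitions plus Gaussian noise."""
    if not transitions:
        raise ConfigError("at least one transition required")
    t = default_temperature_grid() if grid is None else np.asarray(grid, dtype=float)
    for tr in transitions:
        if not t[0] <= tr.tm <= t[-1]:
            raise ConfigError(f"transition Tm {tr.tm} outside the temperature grid")
    f = baseline_intercept + baseline_slope * t
    for tr in transitions:
        f = f + tr.amplitude / (1.0 + np.exp((tr.tm - t) / tr.width))
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return MeltCurve(temperatures=t, fluorescence=f)


def _logistic_with_baseline(t, b0, b1, amplitude, tm, width):
    return b0 + b1 * t + amplitude / (1.0 + np.exp((tm - t) / width))


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + y.size]
    return out


def _global_refine(
    t: np.ndarray, f: np.ndarray, transitions: list[Transition]
) -> list[Transition]:
    """Joint fit of baseline plus all logistic transitions over the full grid."""
    k = len(transitions)

    def model(tt, *theta):
        b0, b1 = theta[0], theta[1]
        out = b0 + b1 * tt
        for j in range(k):
            a, tm, w = theta[2 + 3 * j : 5 + 3 * j]
            out = out + a / (1.0 + np.exp((tm - tt) / w))
        return out

    p0 = [float(f[0]), 0.0]
    lo = [-np.inf, -np.inf]
    hi = [np.inf, np.inf]
    for tr in transitions:
        p0 += [tr.amplitude, tr.tm, tr.width]
        lo += [0.0, float(t[0]), float(np.median(np.diff(t)) / 2)]
        hi += [np.inf, float(t[-1]), 8.0]
    try:
        popt, _ = curve_fit(model, t, f, p0=p0, bounds=(lo, hi), maxfev=10000)
    except RuntimeError:
        return transitions
    return [
        Transition(
            tm=float(popt[3 + 3 * j]),
            amplitude=float(popt[2 + 3 * j]),
            width=float(popt[4 + 3 * j]),
        )
        for j in range(k)
    ]


def extract_transitions(
    curve: MeltCurve,
    smoothing_window: int = 5,
    min_prominence: float = 0.05,
    fit_halfwidth: float = 8.0,
) -> MeltFitResult:
    """Locate melt transitions and assign the Fab melt.

    Parameters
    ----------
    curve
        The melt trace (>= 50 grid points).
    smoothing_window
        Points in the centered moving average applied to dF/dT (default 5,
        i.e. 1 degC on the standard 0.2 degC grid).
    min_prominence
        Minimum fitted transition amplitude, as a fraction of the total
        signal range; smaller candidate peaks are discarded as noise.
    fit_halfwidth
        Half-width (degC) of the local window used for the refining
        logistic fit around each derivative peak.

    The Fab melt is assigned to the largest-amplitude transition.
    """
    t, f = curve.temperatures, curve.fluorescence
    if t.size < 50:
        raise ValueError("need at least 50 grid points")
    step = float(np.median(np.diff(t)))
    # Savitzky-Golay first derivative for peak finding (window ~5 degC),
    # followed by the configured moving average; raw data are used for the
    # refining local fits, so the heavier smoothing only steers detection.
    sg_window = min(max(int(round(5.0 / step)) | 1, 7), t.size - (1 - t.size % 2))
    deriv = savgol_filter(f, sg_window, polyorder=3, deriv=1, delta=step)
    smoothed = _smooth(deriv, smoothing_window)
    signal_range = float(f.max() - f.min())
    if signal_range <= 0:
        raise NoTransitionError("flat curve: no transition found")
    # Candidate peaks are gated permissively on the derivative (a quarter of
    # its own maximum); each candidate is then refined by a local logistic
    # fit and kept only if its fitted amplitude exceeds min_prominence of
    # the total signal range.
    candidate_threshold = 0.25 * float(smoothed.max())
    if candidate_threshold <= 0:
        raise NoTransitionError("no rising transition in curve")
    peaks, _ = find_peaks(smoothed, prominence=candidate_threshold)
    if peaks.size == 0:
        raise NoTransitionError("no derivative peak found")

    transitions: list[Transition] = []
    for peak in peaks:
        lo = np.searchsorted(t, t[peak] - fit_halfwidth)
        hi = np.searchsorted(t, t[peak] + fit_halfwidth, side="right")
        tw, fw = t[lo:hi], f[lo:hi]
        amp0 = max(float(fw[-1] - fw[0]), 1e-6)
        p0 = [float(fw[0]), 0.0, amp0, float(t[peak]), 1.5]
        try:
            popt, _ = curve_fit(
                _logistic_with_baseline,
                tw,
                fw,
                p0=p0,
                bounds=(
                    [-np.inf, -np.inf, 0.0, tw[0], step / 2],
                    [np.inf, np.inf, np.inf, tw[-1], 8.0],
                ),
                maxfev=5000,
            )
            _, _, amplitude, tm, width = popt
        except RuntimeError:
            # fall back to the derivative peak itself
            amplitude, tm, width = (
                float(smoothed[peak] * 4.0),
                float(t[peak]),
                1.0,
            )
        if amplitude >= min_prominence * signal_range:
            transitions.append(
                Transition(tm=float(tm), amplitude=float(amplitude), width=float(width))
            )

    if not transitions:
        raise NoTransitionError(
            f"no transition amplitude above {min_prominence:.0%} of the signal range"
        )
    transitions.sort(key=lambda tr: tr.tm)
    if len(transitions) > 1:
        # overlapping tails bias the local fits; refine all transitions
        # jointly with a shared baseline over the full curve
        transitions = _global_refine(t, f, transitions)
    fab = max(transitions, key=lambda tr: tr.amplitude)
    return MeltFitResult(transitions=tuple(transitions), assigned_fab_tm=fab.tm)
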