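"""1:1 Langmuir SPR kinetics: sensorgram simulation and global fitting.

The 1:1 (Langmuir) interaction model with association rate constant ka
(1/(M s)), dissociation rate constant kd (1/s) and saturating response Rmax
(RU) gives piecewise-exponential sensorgrams.  During an injection at
analyte concentration C, starting from bound level R0,

    R(t) = Req + (R0 - Req) * exp(-(ka*C + kd) * t),   Req = Rmax*C/(C + KD)

and during dissociation R(t) = R0 * exp(-kd * t), with KD = kd/ka.

Two injection designs are supported: multi-cycle (surface regenerated
between concentrations, each cycle starting at R0 = 0) and single-cycle
kinetics (an ascending concentration series injected without regeneration,
carrying R0 across segments).  Fitting is global nonlinear least squares
over all segments sharing (ka, kd, Rmax), multistarted over log-spaced
rate-constant initializations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ..errors import ConfigError, FitFailureError


@dataclass(frozen=True)
class LangmuirParams:
    """1:1 binding parameters; KD is derived as kd/ka exactly."""

    ka: float  # 1/(M s)
    kd: float  # 1/s
    rmax: float  # RU

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ConfigError("ka, kd and rmax must all be > 0")

    @property
    def kD_molar(self) -> float:
        return self.kd / self.ka

    @property
    def kD_nM(self) -> float:
        return self.kD_molar * 1e9


def kd_equilibrium(params: LangmuirParams) -> float:
    """Equilibrium dissociation constant in nM: (kd/ka) * 1e9."""
    return params.kD_nM


@dataclass(frozen=True)
class InjectionSeries:
    """Concentration series and timing of one kinetics experiment."""

    mode: Literal["multi_cycle", "single_cycle"]
    concentrations: tuple[float, ...]  # molar
    t_assoc: float = 120.0
    t_dissoc: float = 1000.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations)
        if c.size == 0 or np.any(c <= 0):
            raise ConfigError("concentrations must be positive")
        d = np.diff(c)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigError("concentrations must be strictly monotone")
        if self.mode == "single_cycle" and np.any(np.diff(c) < 0):
            raise ConfigError("single-cycle series must ascend")
        if self.t_assoc <= 0 or self.t_dissoc <= 0:
            raise ConfigError("injection times must be > 0")


def il13_injection_series() -> InjectionSeries:
    """Multi-cycle two-fold series 1.56-50 nM, 120 s association, 1000 s dissociation."""
    return InjectionSeries(
        mode="multi_cycle",
        concentrations=tuple(50e-9 / 2**k for k in range(5, -1, -1)),
        t_assoc=120.0,
        t_dissoc=1000.0,
    )


def vegf_injection_series() -> InjectionSeries:
    """Single-cycle three-fold series 6.17-500 nM, 120 s association, 300 s dissociation."""
    return InjectionSeries(
        mode="single_cycle",
        concentrations=tuple(500e-9 / 3**k for k in range(4, -1, -1)),
        t_assoc=120.0,
        t_dissoc=300.0,
    )


@dataclass(frozen=True)
class Sensorgram:
    """Time-indexed response trace with per-point phase and concentration labels."""

    time: np.ndarray  # global seconds
    response: np.ndarray  # RU
    phase: np.ndarray  # 'assoc' | 'dissoc'
    concentration: np.ndarray  # molar; concentration of the current/most recent injection
    series: InjectionSeries
    noise_sd: float = 0.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "response_RU": self.response,
                "phase": self.phase,
                "concentration_M": self.concentration,
            }
        ).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path, series: InjectionSeries) -> "Sensorgram":
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(float),
            response=df["response_RU"].to_numpy(float),
            phase=df["phase"].to_numpy(str),
            concentration=df["concentration_M"].to_numpy(float),
            series=series,
        )


def _segments(series: InjectionSeries, dt: float) -> list[tuple[str, float, int]]:
    """(phase, concentration, n_points) per segment, in acquisition order."""
    n_assoc = int(round(series.t_assoc / dt))
    n_dissoc = int(round(series.t_dissoc / dt))
    segs: list[tuple[str, float, int]] = []
    for conc in series.concentrations:
        segs.append(("assoc", conc, n_assoc))
        segs.append(("dissoc", conc, n_dissoc))
    return segs


def _model_response(
    params: LangmuirParams, series: InjectionSeries, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free piecewise-exponential trace; returns time, response, phase, conc."""
    times: list[np.ndarray] = []
    responses: list[np.ndarray] = []
    phases: list[np.ndarray] = []
    concs: list[np.ndarray] = []
    t0 = 0.0
    r0 = 0.0
    kD = params.kD_molar
    for phase, conc, n in _segments(series, dt):
        t_local = dt * np.arange(n)
        if phase == "assoc":
            if series.mode == "multi_cycle":
                r0 = 0.0  # regeneration between cycles
            req = params.rmax * conc / (conc + kD)
            r = req + (r0 - req) * np.exp(-(params.ka * conc + params.kd) * t_local)
            r0 = req + (r0 - req) * math.exp(-(params.ka * conc + params.kd) * n * dt)
        else:
            r = r0 * np.exp(-params.kd * t_local)
            r0 = r0 * math.exp(-params.kd * n * dt)
        times.append(t0 + t_local)
        responses.append(r)
        phases.append(np.full(n, phase, dtype=object))
        concs.append(np.full(n, conc))
        t0 += n * dt
    time = np.concatenate(times)
    response = np.concatenate(responses)
    phase_arr = np.concatenate(phases)
    conc_arr = np.concatenate(concs)
    return time, response, phase_arr, conc_arr


def simulate_sensorgram(
    params: LangmuirParams,
    series: InjectionSeries,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
) -> Sensorgram:
    """Simulate a 1:1 Langmuir sensorgram under the given injection design."""
    time, response, phase, conc = _model_response(params, series, dt)
    if noise_sd > 0:
        response = response + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=response.size
        )
    return Sensorgram(
        time=time,
        response=response,
        phase=phase,
        concentration=conc,
        series=series,
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class LangmuirFit:
    """Best-fit parameters plus residual diagnostics."""

    params: LangmuirParams
    rmse: float
    residuals: np.ndarray
    n_starts: int
    cost: float

    @property
    def kD_nM(self) -> float:
        return self.params.kD_nM


def fit_langmuir(
    sensorgram: Sensorgram,
    ka_range: tuple[float, float] = (1e3, 1e7),
    kd_range: tuple[float, float] = (1e-5, 1e-1),
    n_grid: int = 3,
) -> LangmuirFit:
    """Global 1:1 Langmuir fit over all segments sharing (ka, kd, Rmax).

    Unweighted least squares in log-parameter space, multistarted from an
    ``n_grid x n_grid`` log-spaced grid over the ka and kd ranges.  Rmax is
    initialized from the observed response maximum.  The best-objective
    solution is returned; failure from every start raises FitFailureError.
    """
    series = sensorgram.series
    n_conc = len(series.concentrations)
    if series.mode == "multi_cycle" and n_conc < 2:
        raise ConfigError("multi-cycle fits need >= 2 concentrations")
    if series.mode == "single_cycle" and n_conc < 3:
        raise ConfigError("single-cycle fits need >= 3 injections")
    dt = float(np.median(np.diff(sensorgram.time)))
    observed = sensorgram.response
    rmax0 = max(float(observed.max()) * 1.2, 1e-6)

    def residual(log_params: np.ndarray) -> np.ndarray:
        params = LangmuirParams(*np.exp(np.clip(log_params, -46.0, 46.0)))
        _, model, _, _ = _model_response(params, series, dt)
        return model[: observed.size] - observed

    best: Optional[tuple[float, np.ndarray]] = None
    n_starts = 0
    for ka0 in np.geomspace(*ka_range, n_grid):
        for kd0 in np.geomspace(*kd_range, n_grid):
            n_starts += 1
            x0 = np.log([ka0, kd0, rmax0])
            try:
                sol = least_squares(residual, x0, method="lm", max_nfev=4000)
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            if best is None or sol.cost < best[0]:
                best = (float(sol.cost), sol.x)
    if best is None:
        raise FitFailureError(
            f"1:1 Langmuir fit failed from all {n_starts} starting points"
        )
    cost, x = best
    params = LangmuirParams(*np.exp(x))
    res = residual(x)
    return LangmuirFit(
        params=params,
        rmse=float(np.sqrt(np.mean(res**2))),
        residuals=res,
        n_starts=n_starts,
        cost=cost,
    )


def fit_to_json(fit: LangmuirFit, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "ka_per_M_s": fit.params.ka,
                "kd_per_s": fit.params.kd,
                "rmax_RU": fit.params.rmax,
                "KD_nM": fit.params.kD_nM,
                "rmse_RU": fit.rmse,
                "n_starts": fit.n_starts,
            },
            indent=1,
        )
    )


# Table-style scale factors: rate constants are conventionally printed as
# ka x 1e5 (1/(M s)) and kd x 1e-5 (1/s).
KA_TABLE_SCALE = 1e5
KD_TABLE_SCALE = 1e-5


def params_from_table(
    ka_e5: float, kd_em5: float, rmax: float = 100.0
) -> LangmuirParams:
    """Build params from table-scaled rate constants (ka x 1e5, kd x 1e-5)."""
    return LangmuirParams(ka=ka_e5 * KA_TABLE_SCALE, kd=kd_em5 * KD_TABLE_SCALE, rmax=rmax)


def params_to_table(params: LangmuirParams) -> tuple[float, float]:
    """Inverse of :func:`params_from_table` for the rate constants."""
    return params.ka / KA_TABLE_SCALE, params.kd / KD_TABLE_SCALE
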