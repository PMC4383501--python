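"""1:1 Langmuir kinetics for SPR sensorgrams.

An SPR sensorgram records the biosensor response R(t) while analyte at
concentration C flows over the immobilized partner (association) and is then
rinsed away (dissociation). Under first-order 1:1 Langmuir kinetics:

    association:   R(t) = (1 - exp(-(k_a C + k_d) t)) * k_a C R_max / (k_a C + k_d)
    dissociation:  R(t) = R_0 * exp(-k_d (t - t_0))

with association rate constant k_a (M^-1 s^-1), dissociation rate constant
k_d (s^-1), saturation response R_max, and R_0 the response when the rinse
starts at t_0. The equilibrium binding affinity is K_A = k_a / k_d (M^-1).

Fitting is two-stage by default: k_d comes from a nonlinear least-squares fit
of the dissociation phase (initialized log-linearly), and k_a is then fitted
on the association phase with k_d held fixed. A joint three-parameter
association fit is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

PHASE_ASSOCIATION = "association"
PHASE_DISSOCIATION = "dissociation"

_KD_LOWER_BOUND = 1e-12
_KA_LOWER_BOUND = 1e-12


@dataclass(frozen=True, eq=False)
class Sensorgram:
    """A phase-labelled SPR time series for one analyte concentration.

    ``time`` is in seconds and strictly increasing; every association sample
    precedes every dissociation sample; ``conc`` is the analyte concentration
    in mol/L and ``t0`` the dissociation start time in seconds.
    """

    time: np.ndarray
    response: np.ndarray
    phase: np.ndarray
    conc: float
    t0: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        p = np.asarray(self.phase)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        object.__setattr__(self, "phase", p)
        if not (len(t) == len(r) == len(p)):
            raise ValueError("time, response and phase must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        bad = set(np.unique(p)) - {PHASE_ASSOCIATION, PHASE_DISSOCIATION}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        if self.conc <= 0:
            raise ValueError("analyte concentration must be positive")
        diss = p == PHASE_DISSOCIATION
        if diss.any():
            first_diss = t[diss][0]
            if (t[p == PHASE_ASSOCIATION] >= first_diss).any():
                raise ValueError("association must precede dissociation")

    @property
    def association(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.phase == PHASE_ASSOCIATION
        return self.time[m], self.response[m]

    @property
    def dissociation(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.phase == PHASE_DISSOCIATION
        return self.time[m], self.response[m]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "response": self.response, "phase": self.phase}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, conc: float, t0: float | None = None) -> "Sensorgram":
        df = pd.read_csv(path)
        phase = df["phase"].to_numpy()
        if t0 is None:
            diss = df["time_s"].to_numpy()[phase == PHASE_DISSOCIATION]
            t0 = float(diss[0]) if diss.size else float(df["time_s"].iloc[-1])
        return cls(
            time=df["time_s"].to_numpy(dtype=float),
            response=df["response"].to_numpy(dtype=float),
            phase=phase,
            conc=conc,
            t0=t0,
        )


def model_dissociation(R0: float, kd: float, t, t0: float = 0.0):
    """Exponential rinse-phase decay R0 * exp(-kd (t - t0))."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < t0):
        raise ValueError("dissociation model requires t >= t0")
    out = R0 * np.exp(-kd * (t - t0))
    return float(out) if out.ndim == 0 else out


def model_association(ka: float, kd: float, C: float, Rmax: float, t):
    """Langmuir 1:1 association response at analyte concentration C."""
    if ka <= 0 or kd <= 0:
        raise ValueError("ka and kd must be positive")
    if C <= 0:
        raise ValueError("C must be positive")
    t = np.asarray(t, dtype=float)
    kobs = ka * C + kd
    out = (1.0 - np.exp(-kobs * t)) * ka * C * Rmax / kobs
    return float(out) if out.ndim == 0 else out


def association_plateau(ka: float, kd: float, C: float, Rmax: float) -> float:
    """Equilibrium response: Rmax * K_A C / (1 + K_A C)."""
    return ka * C * Rmax / (ka * C + kd)


def binding_affinity(ka: float, kd: float) -> float:
    """Equilibrium binding affinity K_A = k_a / k_d (M^-1)."""
    if kd == 0:
        raise ValueError("kd must be non-zero")
    return ka / kd


@dataclass(frozen=True)
class DissociationFit:
    kd: float
    R0: float
    residual_norm: float
    converged: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class AssociationFit:
    ka: float
    Rmax: float
    kd: float           # the value used (fixed or jointly fitted)
    kd_was_fixed: bool
    residual_norm: float
    converged: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class KineticFit:
    """Combined two-stage fit result; K_A is always exactly ka / kd."""

    ka: float
    kd: float
    R_max: float
    R_0: float
    residual_norm: float
    converged: bool
    flags: tuple[str, ...] = ()

    @property
    def K_A(self) -> float:
        return binding_affinity(self.ka, self.kd)


def fit_dissociation(sensorgram: Sensorgram) -> DissociationFit:
    """Fit R0 and kd on the dissociation phase.

    Initialized by log-linear regression when all responses are positive,
    falling back to direct nonlinear least squares otherwise. A kd driven to
    the lower bound (e.g. by a constant trace) is flagged.
    """
    t, r = sensorgram.dissociation
    if len(t) < 5:
        raise ValueError("need at least 5 dissociation samples")
    t0 = sensorgram.t0
    flags: list[str] = []

    if np.all(r > 0):
        slope, intercept = np.polyfit(t - t0, np.log(r), 1)
        kd0 = max(-slope, _KD_LOWER_BOUND)
        r00 = math.exp(intercept)
    else:
        flags.append("nonpositive_responses_direct_nls")
        kd0 = 1e-3
        r00 = max(float(r[0]), 1e-6)

    def f(tt, R0, kd):
        return R0 * np.exp(-kd * (tt - t0))

    converged = True
    try:
        popt, _ = curve_fit(
            f,
            t,
            r,
            p0=[r00, kd0],
            bounds=([0.0, _KD_LOWER_BOUND], [np.inf, np.inf]),
            maxfev=20000,
        )
        R0_fit, kd_fit = float(popt[0]), float(popt[1])
    except RuntimeError:
        converged = False
        flags.append("no_convergence")
        R0_fit, kd_fit = r00, kd0
    # A kd whose total decay over the observed window is negligible is
    # indistinguishable from the kd -> 0 boundary: flag it.
    if kd_fit * (t[-1] - t[0]) < 1e-6:
        flags.append("kd_at_lower_bound")
        converged = False
    resid = float(np.linalg.norm(f(t, R0_fit, kd_fit) - r))
    return DissociationFit(
        kd=kd_fit, R0=R0_fit, residual_norm=resid,
        converged=converged, flags=tuple(flags),
    )


def fit_association(
    sensorgram: Sensorgram,
    C: float | None = None,
    kd_fixed: float | None = None,
) -> AssociationFit:
    """Fit ka (and Rmax) on the association phase.

    With ``kd_fixed`` (the default workflow passes the dissociation-phase
    estimate) only ka and Rmax are free; without it, kd is fitted jointly.
    """
    C = sensorgram.conc if C is None else C
    if C <= 0:
        raise ValueError("C must be positive")
    t, r = sensorgram.association
    if len(t) < 5:
        raise ValueError("need at least 5 association samples")
    flags: list[str] = []

    plateau = float(np.max(np.abs(r))) if len(r) else 0.0
    if plateau == 0.0:
        # No signal at all: the model is unidentifiable; report the boundary.
        kd = kd_fixed if kd_fixed is not None else _KD_LOWER_BOUND
        return AssociationFit(
            ka=_KA_LOWER_BOUND, Rmax=0.0, kd=kd,
            kd_was_fixed=kd_fixed is not None,
            residual_norm=float(np.linalg.norm(r)),
            converged=False,
            flags=("zero_signal", "ka_at_lower_bound"),
        )

    ka0 = 1e4
    rmax0 = max(plateau, 1e-9) * 1.2
    converged = True
    if kd_fixed is not None:
        def f(tt, ka, Rmax):
            return model_association(ka, kd_fixed, C, Rmax, tt)

        p0 = [ka0, rmax0]
        bounds = ([_KA_LOWER_BOUND, 0.0], [np.inf, np.inf])
    else:
        def f(tt, ka, Rmax, kd):
            return model_association(ka, kd, C, Rmax, tt)

        p0 = [ka0, rmax0, 1e-3]
        bounds = (
            [_KA_LOWER_BOUND, 0.0, _KD_LOWER_BOUND],
            [np.inf, np.inf, np.inf],
        )
    try:
        popt, _ = curve_fit(f, t, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        converged = False
        flags.append("no_convergence")
        popt = p0
    ka_fit = float(popt[0])
    rmax_fit = float(popt[1])
    kd_used = kd_fixed if kd_fixed is not None else float(popt[2])
    if ka_fit <= 10 * _KA_LOWER_BOUND:
        flags.append("ka_at_lower_bound")
        converged = False
    resid = float(np.linalg.norm(f(t, *popt) - r))
    return AssociationFit(
        ka=ka_fit, Rmax=rmax_fit, kd=kd_used,
        kd_was_fixed=kd_fixed is not None,
        residual_norm=resid, converged=converged, flags=tuple(flags),
    )


def fit_kinetics(sensorgram: Sensorgram, joint: bool = False) -> KineticFit:
    """Two-stage (default) or joint kinetic fit of a full sensorgram."""
    diss = fit_dissociation(sensorgram)
    assoc = fit_association(
        sensorgram, kd_fixed=None if joint else diss.kd
    )
    kd = assoc.kd if joint else diss.kd
    return KineticFit(
        ka=assoc.ka,
        kd=kd,
        R_max=assoc.Rmax,
        R_0=diss.R0,
        residual_norm=float(np.hypot(diss.residual_norm, assoc.residual_norm)),
        converged=diss.converged and assoc.converged,
        flags=diss.flags + assoc.flags,
    )


@dataclass(frozen=True)
class CoverageSummary:
    """Replicate summary of per-sensing-area surface coverages (ng/cm^2)."""

    values: tuple[float, ...]
    mean: float
    sd: float
    n_areas: int


def coverage_summary(values: Sequence[float]) -> CoverageSummary:
    """Mean and sample (n-1) standard deviation over sensing areas."""
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ValueError("need at least one coverage value")
    arr = np.asarray(vals)
    sd = float(np.std(arr, ddof=1)) if len(vals) > 1 else 0.0
    return CoverageSummary(
        values=vals, mean=float(arr.mean()), sd=sd, n_areas=len(vals)
    )


def fit_report_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Kinetics report with rate constants on their conventional scales.

    Each input row needs name, ka, kd (SI units), and optionally
    coverage_mean/coverage_sd (ng/cm^2) and score; output columns express
    ka in 10^3 M^-1 s^-1, kd in 10^-3 s^-1 and K_A in 10^6 M^-1.
    """
    out = []
    for row in rows:
        ka, kd = float(row["ka"]), float(row["kd"])
        out.append(
            {
                "name": row["name"],
                "coverage_mean_ng_cm2": row.get("coverage_mean", np.nan),
                "coverage_sd_ng_cm2": row.get("coverage_sd", np.nan),
                "ka_1e3_per_M_s": ka / 1e3,
                "kd_1e-3_per_s": kd / 1e-3,
                "KA_1e6_per_M": binding_affinity(ka, kd) / 1e6,
                "score": row.get("score", np.nan),
            }
        )
    return pd.DataFrame(out)
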