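"""Non-compartmental analysis of concentration–time profiles.

Estimators follow standard NCA conventions:

* **Terminal slope** — log-linear least squares over the terminal points.
  Candidate windows are the last m, m+1, …, N positive-concentration points
  after Tmax with negative slope; the window maximizing the adjusted R² is
  selected, with the conventional 1e-4 tolerance resolving near-ties toward
  more points.  The minimum window m is 3 for sparse designs but never less
  than 10 % of the available points: on densely sampled profiles an
  unrestricted scan degenerates into selecting noise-dominated micro-windows
  whose R² is high by chance, which inflates the variance of ke instead of
  reducing it as sampling gets richer.  ``ke = −slope``, ``t½ = ln2/ke``.
* **AUC/AUMC** — linear-up/log-down trapezoid over the observed window, with
  exponential tail extrapolation ``C_last/ke`` (AUC) and
  ``C_last·t_last/ke + C_last/ke²`` (AUMC) when a terminal slope is
  available.  The extrapolated fraction is reported so heavy extrapolation
  (long half-life sampled over a short window) is visible.
* **Derived parameters** — ``MRT = AUMC/AUC``, ``CL = dose/AUC₀₋∞``,
  ``Vd = CL/ke``; these identities hold on every :class:`NCAResult` by
  construction.

By reporting convention Cmax/Tmax are taken from the first strictly positive
grid time onward (the t = 0 venous value after an IV bolus is a pre-mixing
artifact), with the earliest time winning ties.  Clearance is reported in
ml/min/kg and Vd in L/kg; all internal computation is in ml, hr and ng.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import ConcentrationTimeProfile

__all__ = [
    "TerminalFit",
    "AUCResult",
    "NCAResult",
    "InsufficientDataError",
    "NoTerminalPhaseError",
    "ExtrapolationUnavailableWarning",
    "terminal_slope",
    "auc",
    "pk_summary",
]

LN2 = float(np.log(2.0))
_ADJ_R2_TIE_TOL = 1e-4
#: Candidate terminal windows must cover at least this fraction of the
#: post-Tmax points (but never fewer than 3 points).
_MIN_WINDOW_FRACTION = 0.1


class InsufficientDataError(ValueError):
    """Too few usable points for the requested estimator."""


class NoTerminalPhaseError(ValueError):
    """Best terminal fit has a non-negative slope (no decline)."""


class ExtrapolationUnavailableWarning(UserWarning):
    """AUC tail could not be extrapolated (no terminal rate constant)."""


@dataclass(frozen=True)
class TerminalFit:
    ke_per_hr: float
    t_half_hr: float
    n_points: int
    r_squared: float
    adj_r_squared: float
    intercept_log_ng_ml: float


@dataclass(frozen=True)
class AUCResult:
    auc_0_t_ng_hr_ml: float
    auc_0_inf_ng_hr_ml: float | None
    aumc_0_t_ng_hr2_ml: float
    aumc_0_inf_ng_hr2_ml: float | None
    extrapolated_fraction: float | None


@dataclass(frozen=True)
class NCAResult:
    """The full PK parameter set of one profile."""

    cmax_ng_ml: float
    tmax_hr: float
    ke_per_hr: float
    t_half_hr: float
    auc_0_t_ng_hr_ml: float
    auc_0_inf_ng_hr_ml: float
    aumc_0_inf_ng_hr2_ml: float
    mrt_hr: float
    cl_ml_min_kg: float
    vd_l_kg: float
    extrapolated_fraction: float
    n_terminal_points: int
    r_squared_terminal: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cmax_ng_ml": self.cmax_ng_ml,
            "tmax_hr": self.tmax_hr,
            "ke_per_hr": self.ke_per_hr,
            "t_half_hr": self.t_half_hr,
            "auc_0_t_ng_hr_ml": self.auc_0_t_ng_hr_ml,
            "auc_0_inf_ng_hr_ml": self.auc_0_inf_ng_hr_ml,
            "aumc_0_inf_ng_hr2_ml": self.aumc_0_inf_ng_hr2_ml,
            "mrt_hr": self.mrt_hr,
            "cl_ml_min_kg": self.cl_ml_min_kg,
            "vd_l_kg": self.vd_l_kg,
            "extrapolated_fraction": self.extrapolated_fraction,
            "n_terminal_points": self.n_terminal_points,
            "r_squared_terminal": self.r_squared_terminal,
        }


def _tmax_index(times: np.ndarray, conc: np.ndarray, exclude_time_zero: bool) -> int:
    mask = conc > 0
    if exclude_time_zero and np.any(mask & (times > 0)):
        mask &= times > 0
    if not np.any(mask):
        raise InsufficientDataError("profile has no positive concentrations")
    cand = np.flatnonzero(mask)
    # earliest time achieving the maximum
    return int(cand[np.argmax(conc[cand])])


def terminal_slope(
    profile: ConcentrationTimeProfile, *, exclude_time_zero: bool = True
) -> TerminalFit:
    """Estimate the terminal elimination rate constant by log-linear fit.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 positive concentrations after Tmax.
    NoTerminalPhaseError
        The selected fit has a non-negative slope.
    """
    t = profile.times_hr
    c = profile.concentrations_ng_ml
    i_max = _tmax_index(t, c, exclude_time_zero)
    sel = np.flatnonzero((np.arange(t.size) > i_max) & (c > 0))
    if sel.size < 3:
        raise InsufficientDataError(
            f"need >= 3 positive concentrations after Tmax, found {sel.size}"
        )
    x = t[sel]
    y = np.log(c[sel])

    # Suffix sums: window m uses the last m points.  All windows evaluated at
    # once via reversed cumulative sums.
    xr, yr = x[::-1], y[::-1]
    n = np.arange(1, xr.size + 1, dtype=float)
    sx = np.cumsum(xr)
    sy = np.cumsum(yr)
    sxx = np.cumsum(xr * xr)
    syy = np.cumsum(yr * yr)
    sxy = np.cumsum(xr * yr)

    m = n[2:]
    cov = m * sxy[2:] - sx[2:] * sy[2:]
    var_x = m * sxx[2:] - sx[2:] ** 2
    var_y = m * syy[2:] - sy[2:] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cov / var_x
        r2 = np.where(var_y > 0, cov**2 / np.maximum(var_x * var_y, 1e-300), 0.0)
        adj = 1.0 - (1.0 - r2) * (m - 1.0) / (m - 2.0)
    adj = np.where(np.isfinite(adj), adj, -np.inf)
    # only declining windows describe a terminal phase
    adj = np.where(slope < 0, adj, -np.inf)
    m_min = max(3, int(np.ceil(_MIN_WINDOW_FRACTION * sel.size)))
    adj = np.where(m >= m_min, adj, -np.inf)
    if not np.any(np.isfinite(adj)):
        raise NoTerminalPhaseError("no candidate terminal window has a negative slope")

    best = float(np.max(adj))
    # prefer the longest window among (near-)ties
    i_best = int(np.flatnonzero(adj >= best - _ADJ_R2_TIE_TOL)[-1])
    m_best = int(m[i_best])
    slope_best = float(slope[i_best])
    ke = -slope_best
    intercept = (sy[2:][i_best] - slope_best * sx[2:][i_best]) / m_best
    return TerminalFit(
        ke_per_hr=ke,
        t_half_hr=LN2 / ke,
        n_points=m_best,
        r_squared=float(r2[i_best]),
        adj_r_squared=float(adj[i_best]),
        intercept_log_ng_ml=float(intercept),
    )


def _segment_areas(t: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment AUC and AUMC: linear-up, log-down."""
    t1, t2 = t[:-1], t[1:]
    c1, c2 = c[:-1], c[1:]
    dt = t2 - t1
    auc_lin = dt * (c1 + c2) / 2.0
    aumc_lin = dt / 6.0 * (c1 * (2.0 * t1 + t2) + c2 * (t1 + 2.0 * t2))
    logdown = (c1 > 0) & (c2 > 0) & (c2 < c1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(logdown, np.log(np.where(c2 > 0, c1 / np.maximum(c2, 1e-300), 1.0)) / dt, 1.0)
        auc_log = (c1 - c2) / k
        aumc_log = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    return np.where(logdown, auc_log, auc_lin), np.where(logdown, aumc_log, aumc_lin)


def auc(profile: ConcentrationTimeProfile, ke_per_hr: float | None = None) -> AUCResult:
    """AUC/AUMC by linear-up/log-down trapezoid with exponential tail.

    Without ``ke_per_hr`` and with a positive last concentration, the tail
    cannot be extrapolated: an :class:`ExtrapolationUnavailableWarning` is
    issued and the 0→∞ quantities are ``None``.
    """
    t = profile.times_hr
    c = profile.concentrations_ng_ml
    if t.size < 2:
        raise InsufficientDataError("need >= 2 points for quadrature")
    seg_auc, seg_aumc = _segment_areas(t, c)
    auc_0_t = float(np.sum(seg_auc))
    aumc_0_t = float(np.sum(seg_aumc))

    c_last = float(c[-1])
    t_last = float(t[-1])
    if c_last <= 0:
        return AUCResult(auc_0_t, auc_0_t, aumc_0_t, aumc_0_t, 0.0)
    if ke_per_hr is None:
        warnings.warn(
            "last concentration > 0 but no terminal rate constant supplied; "
            "0-to-infinity quantities omitted",
            ExtrapolationUnavailableWarning,
            stacklevel=2,
        )
        return AUCResult(auc_0_t, None, aumc_0_t, None, None)
    if not ke_per_hr > 0:
        raise ValueError("ke must be > 0")
    auc_tail = c_last / ke_per_hr
    aumc_tail = c_last * t_last / ke_per_hr + c_last / ke_per_hr**2
    auc_inf = auc_0_t + auc_tail
    return AUCResult(
        auc_0_t,
        auc_inf,
        aumc_0_t,
        aumc_0_t + aumc_tail,
        auc_tail / auc_inf,
    )


def pk_summary(
    profile: ConcentrationTimeProfile,
    dose_mg_per_kg: float,
    *,
    exclude_time_zero: bool = True,
) -> NCAResult:
    """Assemble the full NCA parameter set for one profile.

    ``dose_mg_per_kg`` is the administered IV bolus per kg body weight, so
    clearance comes out in ml/min/kg and Vd in L/kg without needing the
    absolute body weight.
    """
    if not dose_mg_per_kg > 0:
        raise ValueError("dose must be > 0")
    t = profile.times_hr
    c = profile.concentrations_ng_ml
    i_max = _tmax_index(t, c, exclude_time_zero)

    fit = terminal_slope(profile, exclude_time_zero=exclude_time_zero)
    areas = auc(profile, ke_per_hr=fit.ke_per_hr)
    auc_inf = areas.auc_0_inf_ng_hr_ml
    aumc_inf = areas.aumc_0_inf_ng_hr2_ml

    dose_ng_per_kg = dose_mg_per_kg * 1.0e6
    cl_ml_hr_kg = dose_ng_per_kg / auc_inf
    return NCAResult(
        cmax_ng_ml=float(c[i_max]),
        tmax_hr=float(t[i_max]),
        ke_per_hr=fit.ke_per_hr,
        t_half_hr=fit.t_half_hr,
        auc_0_t_ng_hr_ml=areas.auc_0_t_ng_hr_ml,
        auc_0_inf_ng_hr_ml=auc_inf,
        aumc_0_inf_ng_hr2_ml=aumc_inf,
        mrt_hr=aumc_inf / auc_inf,
        cl_ml_min_kg=cl_ml_hr_kg / 60.0,
        vd_l_kg=cl_ml_hr_kg / fit.ke_per_hr / 1000.0,
        extrapolated_fraction=areas.extrapolated_fraction,
        n_terminal_points=fit.n_points,
        r_squared_terminal=fit.r_squared,
    )
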