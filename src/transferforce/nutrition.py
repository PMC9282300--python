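"""Nutritional dependence of vital rates.

A food-limited sharing group pools production and redistributes by caloric
need, so every member experiences the same food ratio

    E = P_T / D_T,   P_T = sum_x P_x l_x,   D_T = sum_x D_x l_x.

Vital rates respond through the scalar

    Z(E, gamma) = E (gamma + 1) / (E + gamma),

with fertility multiplied by Z and mortality divided by Z.  Z(1, gamma) = 1:
at replete nutrition the baseline (maximal) rates apply.  Small gamma gives a
concave response (mild deprivation is nearly free); large gamma approaches
the linear response Z = E.

Calibration follows a two-step scheme: production is first scaled so that
the group is exactly replete (E = 1) under replete survivorship, then
reduced proportionally at every age until intrinsic growth falls to a target
baseline (1%/year by default).  The food ratio at stationarity (lambda = 1)
is E_min, below which the population declines toward collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .demography import demographic_summary
from .schedules import LifeHistoryProfile, SubsistenceProfile

logger = logging.getLogger(__name__)

_E_FLOOR = 1e-9


def _check_params(E: float, gamma: float) -> None:
    if not E > 0:
        raise ValueError(f"food ratio E must be positive, got {E}")
    if not gamma > 0:
        raise ValueError(f"curvature gamma must be positive, got {gamma}")


def vital_scalar(E: float, gamma: float) -> float:
    """Z = E(gamma+1)/(E+gamma); in (0, 1] for E in (0, 1]."""
    _check_params(E, gamma)
    return E * (gamma + 1.0) / (E + gamma)


def vital_scalar_derivative(E: float, gamma: float) -> float:
    """dZ/dE = gamma(gamma+1)/(E+gamma)^2 > 0."""
    _check_params(E, gamma)
    return gamma * (gamma + 1.0) / (E + gamma) ** 2


def apply_nutrition(lh0: LifeHistoryProfile, E: float, gamma: float) -> LifeHistoryProfile:
    """Degrade baseline vital rates to food ratio E:
    m_x = Z m_x^(0), q_x = min(q_x^(0)/Z, 1)."""
    Z = vital_scalar(E, gamma)
    q = lh0.q_x / Z
    if np.any(q[:-1] > 1.0):
        # Routine while root finders probe extreme E; debug level keeps
        # calibration runs quiet.
        n_clip = int(np.sum(q[:-1] > 1.0))
        logger.debug("mortality clipped at 1 for %d age class(es) (E=%.4f)", n_clip, E)
    q = np.minimum(q, 1.0)
    q[-1] = 1.0
    return LifeHistoryProfile(q_x=q, m_x=Z * lh0.m_x)


def dm_dE(m0: np.ndarray, E: float, gamma: float) -> np.ndarray:
    """Derivative of fertility m_x = Z m_x^(0) with respect to E:
    m_x^(0) gamma(gamma+1)/(E+gamma)^2."""
    return np.asarray(m0, dtype=float) * vital_scalar_derivative(E, gamma)


def dp_dE(q0: np.ndarray, E: float, gamma: float) -> np.ndarray:
    """Derivative of survival p_x = 1 - q_x^(0)/Z with respect to E.

    Exact algebra: d/dE (1 - q0/Z) = q0 Z'/Z^2 = q0 gamma / (E^2 (gamma+1)).
    """
    _check_params(E, gamma)
    return np.asarray(q0, dtype=float) * gamma / (E**2 * (gamma + 1.0))


def food_ratio(
    sub: SubsistenceProfile,
    lh0: LifeHistoryProfile,
    gamma: float,
    self_consistent: bool = False,
    l_x: np.ndarray | None = None,
) -> float:
    """Food ratio E = P_T/D_T of the sharing group.

    One-shot mode evaluates the ratio at a supplied survivorship (default:
    replete survivorship of ``lh0``).  Self-consistent mode solves
    E = P_T(l(E)) / D_T(l(E)) where l(E) is the survivorship implied by
    applying nutrition at E, by bracketed root finding to 1e-10.
    """
    P = sub.production()
    D = sub.D_x

    def ratio_at(lvec: np.ndarray) -> float:
        DT = float(D @ lvec)
        if DT <= 0:
            raise ValueError("total demand D_T must be positive")
        return float(P @ lvec) / DT

    if not self_consistent:
        lvec = lh0.survivorship() if l_x is None else np.asarray(l_x, dtype=float)
        return ratio_at(lvec)

    def residual(E: float) -> float:
        lvec = apply_nutrition(lh0, E, gamma).survivorship()
        return E - ratio_at(lvec)

    if residual(1.0) <= 0:  # replete or better: cap at E = 1
        return 1.0
    # The fixed-point equation can be bistable: a nourished branch and a
    # collapsed branch (starvation shortens lives, which lowers E further).
    # The operating point is the largest fixed point in (0, 1] — the branch a
    # population reached by gradual production reduction actually sits on —
    # so scan downward from E = 1 for the first sign change and refine it.
    grid = np.linspace(1.0, _E_FLOOR, 512)
    prev = grid[0]
    prev_val = residual(prev)
    for E in grid[1:]:
        val = residual(E)
        if prev_val > 0 and val <= 0:
            return float(brentq(residual, E, prev, xtol=1e-10, rtol=1e-12))
        prev, prev_val = E, val
    raise ValueError("no self-consistent food ratio in (0, 1]; recalibrate production")


@dataclass(frozen=True)
class CalibrationResult:
    """Output of the replete/baseline calibration."""

    replete_scale: float   # production multiplier giving E = 1 at replete l_x
    rho: float             # proportional reduction giving r = r_target
    E0: float              # baseline food ratio
    E_min: float           # food ratio at stationarity (lambda = 1)
    r_max: float           # intrinsic growth at E = 1
    r_target: float
    gamma: float

    def __post_init__(self):
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must lie in (0, 1], got {self.rho}")
        if not (self.E_min <= self.E0 <= 1.0 + 1e-12):
            raise ValueError(f"expected E_min <= E0 <= 1, got {self.E_min}, {self.E0}")


@dataclass(frozen=True)
class BaselineState:
    """A calibrated operating point: the food-limited group at its baseline
    food ratio, with everything the selection metrics need."""

    lh0: LifeHistoryProfile        # replete vital rates
    sub: SubsistenceProfile        # calibrated subsistence (scale = replete_scale * rho)
    gamma: float
    calibration: CalibrationResult

    @property
    def E0(self) -> float:
        return self.calibration.E0

    def vital_rates(self) -> LifeHistoryProfile:
        return apply_nutrition(self.lh0, self.E0, self.gamma)

    def survivorship(self) -> np.ndarray:
        return self.vital_rates().survivorship()

    def total_demand(self) -> float:
        return float(self.sub.D_x @ self.survivorship())

    def production(self) -> np.ndarray:
        return self.sub.production()


def _growth_at_scale(
    lh0: LifeHistoryProfile, sub: SubsistenceProfile, gamma: float, scale: float
) -> tuple[float, float]:
    """(r, E) with production scaled by ``scale`` and E solved
    self-consistently."""
    E = food_ratio(sub.with_scale(scale), lh0, gamma, self_consistent=True)
    lh = apply_nutrition(lh0, E, gamma)
    summ = demographic_summary(lh)
    return summ.r, E


def calibrate(
    lh0: LifeHistoryProfile,
    sub: SubsistenceProfile,
    gamma: float,
    r_target: float = 0.01,
    rescale_fertility_to: float | None = None,
) -> BaselineState:
    """Two-step calibration of the subsistence scale.

    1. ``replete_scale`` makes P_T = D_T under replete survivorship (E = 1).
    2. ``rho`` in (0, 1] reduces production proportionally at every age until
       the self-consistent intrinsic growth rate equals ``r_target``
       (bisection via brentq; r is strictly increasing in the scale).

    E_min (food ratio at lambda = 1) is solved on the same nutrition pathway.
    If ``rescale_fertility_to`` is given, baseline fertility is first
    multiplied by a constant so that r at E = 1 equals that value.
    """
    _check_params(1.0, gamma)
    if rescale_fertility_to is not None:
        lam_target = float(np.exp(rescale_fertility_to))

        def fert_resid(c: float) -> float:
            lh_c = LifeHistoryProfile(q_x=lh0.q_x, m_x=c * lh0.m_x)
            return demographic_summary(lh_c).lam - lam_target

        c = float(brentq(fert_resid, 1e-6, 1e3, xtol=1e-12))
        lh0 = LifeHistoryProfile(q_x=lh0.q_x, m_x=c * lh0.m_x)

    l_replete = lh0.survivorship()
    PT = float(sub.P_x @ l_replete)
    DT = float(sub.D_x @ l_replete)
    if PT <= 0 or DT <= 0:
        raise ValueError("production and demand totals must be positive")
    replete_scale = DT / PT

    summ_replete = demographic_summary(lh0)
    r_max = summ_replete.r
    if r_target > r_max + 1e-12:
        raise ValueError(
            f"r_target={r_target} exceeds replete growth r_max={r_max:.5f}; not bracketed"
        )

    sub_replete = sub.with_scale(replete_scale)
    if abs(r_target - r_max) <= 1e-12:
        rho, E0 = 1.0, 1.0
    else:
        def resid(rho_try: float) -> float:
            r, _ = _growth_at_scale(lh0, sub_replete, gamma, replete_scale * rho_try)
            return r - r_target

        lo = 1e-6
        if resid(lo) > 0:
            raise ValueError("r_target not bracketed from below; population too robust")
        rho = float(brentq(resid, lo, 1.0, xtol=1e-12, rtol=1e-14))
        _, E0 = _growth_at_scale(lh0, sub_replete, gamma, replete_scale * rho)

    # E_min: food ratio at stationarity, directly on the nutrition pathway.
    def lam_resid(E: float) -> float:
        return demographic_summary(apply_nutrition(lh0, E, gamma)).lam - 1.0

    if lam_resid(_E_FLOOR) >= 0:
        E_min = _E_FLOOR
    else:
        E_min = float(brentq(lam_resid, _E_FLOOR, 1.0, xtol=1e-12))

    calib = CalibrationResult(
        replete_scale=replete_scale,
        rho=rho,
        E0=E0,
        E_min=E_min,
        r_max=r_max,
        r_target=r_target,
        gamma=gamma,
    )
    return BaselineState(
        lh0=lh0,
        sub=sub.with_scale(replete_scale * rho),
        gamma=gamma,
        calibration=calib,
    )
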