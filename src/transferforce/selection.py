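"""Selection on production transfers: the serial sensitivity chain.

The fitness sensitivity to per-capita production at age x decomposes into
three links — the sensitivity of lambda to each vital rate, the nutritional
response of each vital rate to the food ratio E, and the marginal effect of
age-x production on E (which is l_x / D_T under pooled need-based sharing):

    s_Px = r~_x k * [ sum_y s_{y+1,y} dp_y/dE + sum_y s_{1y} dm_y/dE ] * l_x / D_T

with r~_x = r_x / 0.5 the donor's relatedness to the group scaled against
the direct-offspring benchmark, and k the probability of reliable
cooperation.  The bracketed recipient sum is the same for donors of every
age; the donor's age enters only through l_x and r~_x, so under flat social
profiles the indirect contribution Delta-lambda_Px = P_x s_Px is exactly
proportional to P_x l_x.

All derivatives are evaluated at the calibrated baseline point (E_0,
baseline survivorship, baseline D_T) without re-equilibration — a first-order
expansion around the operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .demography import SensitivityTable, build_matrix, vital_sensitivities, reproductive_value
from .nutrition import BaselineState, dm_dE, dp_dE
from .schedules import SocialProfile


def recipient_sum(state: BaselineState, sens: SensitivityTable | None = None) -> float:
    """The donor-independent recipient sum S: nutritional fitness effects
    summed over recipients of all ages, via survival and fertility."""
    lh = state.vital_rates()
    if sens is None:
        sens = vital_sensitivities(build_matrix(lh.p_x, lh.m_x))
    dp = dp_dE(state.lh0.q_x, state.E0, state.gamma)
    dm = dm_dE(state.lh0.m_x, state.E0, state.gamma)
    return float(sens.s_px @ dp + sens.s_mx @ dm)


def production_sensitivity(
    state: BaselineState,
    social: SocialProfile,
    sens: SensitivityTable | None = None,
) -> np.ndarray:
    """s_Px = dlambda/dP_x per kcal/day of age-x production, kin- and
    cooperation-discounted."""
    S = recipient_sum(state, sens)
    l_x = state.survivorship()
    DT = state.total_demand()
    return social.scaled() * social.k * S * l_x / DT


def indirect_contribution(P_x: np.ndarray, s_Px: np.ndarray) -> np.ndarray:
    """Delta-lambda_Px = P_x * s_Px: the group growth attributable to age-x
    production transfers (equivalently, the first-order fitness lost if all
    age-x individuals stopped foraging)."""
    P = np.asarray(P_x, dtype=float)
    s = np.asarray(s_Px, dtype=float)
    if P.shape != s.shape:
        raise ValueError("P_x and s_Px length mismatch")
    return P * s


def production_elasticity(
    s_Px: np.ndarray, P_x: np.ndarray, lam: float, e_mx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw elasticity e_Px = s_Px P_x / lambda, and the same curve rescaled so
    its age-sum equals the total fertility elasticity (production
    elasticities do not share the unit-sum constraint of vital-rate
    elasticities, so the rescaling makes age profiles comparable)."""
    if not lam > 0:
        raise ValueError("lambda must be positive")
    raw = np.asarray(s_Px, dtype=float) * np.asarray(P_x, dtype=float) / lam
    total_raw = raw.sum()
    if total_raw <= 0:
        warnings.warn("total raw production elasticity is zero; scaled curve undefined")
        return raw, np.zeros_like(raw)
    scaled = raw * (np.asarray(e_mx, dtype=float).sum() / total_raw)
    return raw, scaled


def fertility_equivalent(s_Px: np.ndarray, P_x: np.ndarray, s_mx: np.ndarray) -> np.ndarray:
    """m_x* solving s_mx m_x* = s_Px P_x: the extra daughters per year at age
    x that would match the fitness contribution of age-x production.  NaN
    where the fertility sensitivity is zero."""
    s_m = np.asarray(s_mx, dtype=float)
    num = np.asarray(s_Px, dtype=float) * np.asarray(P_x, dtype=float)
    out = np.full_like(num, np.nan)
    np.divide(num, s_m, out=out, where=s_m > 0)
    return out


def tfr50(m_star: np.ndarray, start: int = 50, stop: int = 80) -> float:
    """Both-sex offspring equivalent of post-menopausal production: twice the
    sum of m_x* over ages ``start``..``stop`` inclusive (one-sex female
    model), unconditioned on survival."""
    m = np.asarray(m_star, dtype=float)
    hi = min(stop, len(m) - 1)
    if start > hi:
        return 0.0
    window = m[start : hi + 1]
    return float(2.0 * np.nansum(window))


def mean_age(schedule: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Schedule-weighted mean age sum(x v_x)/sum(v_x); ``weights`` (e.g. l_x
    or the stable structure) multiply the schedule first."""
    v = np.asarray(schedule, dtype=float)
    if weights is not None:
        v = v * np.asarray(weights, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("schedule sums to zero; mean age undefined")
    return float(np.arange(len(v)) @ v / total)


def mean_ages(
    m_x: np.ndarray,
    P_x: np.ndarray,
    D_x: np.ndarray,
    weighting: str = "formula",
    l_x: np.ndarray | None = None,
    w_x: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(x_M, x_P, x_D): mean ages of reproduction, production, and demand.

    ``formula`` applies the unweighted definition sum(x m_x)/sum(m_x) with
    production or demand substituted for fertility; ``survivorship`` and
    ``stable`` weight each schedule by l_x or the stable age structure for
    sensitivity analysis.
    """
    if weighting == "formula":
        wts = None
    elif weighting == "survivorship":
        if l_x is None:
            raise ValueError("survivorship weighting requires l_x")
        wts = l_x
    elif weighting == "stable":
        if w_x is None:
            raise ValueError("stable weighting requires w_x")
        wts = w_x
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return (mean_age(m_x, wts), mean_age(P_x, wts), mean_age(D_x, wts))


def cumulative_share(values: np.ndarray, cut_age: int) -> float:
    """Fraction of sum(values) contributed by ages strictly above
    ``cut_age``."""
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("values sum to zero; share undefined")
    if cut_age < 0:
        return 1.0
    return float(v[cut_age + 1 :].sum() / total)


def cumulative_shares(values: np.ndarray, cut_ages) -> np.ndarray:
    return np.array([cumulative_share(values, a) for a in cut_ages])


@dataclass(frozen=True)
class SelectionReport:
    """Per-age transfer-selection metrics at a calibrated baseline."""

    ages: np.ndarray
    lam: float
    E0: float
    gamma: float
    social: SocialProfile
    l_x: np.ndarray
    P_x: np.ndarray            # calibrated production (scale applied)
    D_x: np.ndarray
    m_x: np.ndarray            # baseline (nutrition-adjusted) fertility
    p_x: np.ndarray
    s_mx: np.ndarray
    s_px: np.ndarray
    e_mx: np.ndarray
    e_px_vital: np.ndarray     # survival elasticities of the Leslie matrix
    s_Px: np.ndarray
    dlambda_Px: np.ndarray
    e_Px_raw: np.ndarray
    e_Px_scaled: np.ndarray
    m_star: np.ndarray
    RV: np.ndarray

    @property
    def tfr50(self) -> float:
        return tfr50(self.m_star)

    @property
    def fertility_elasticity_share(self) -> float:
        """Sum of fertility elasticities as a fraction of all vital-rate
        elasticities (which sum to 1)."""
        return float(self.e_mx.sum())

    def production_shares(self, cut_ages=(30, 40, 50)) -> np.ndarray:
        """Survivorship-weighted production remaining after each cut age."""
        return cumulative_shares(self.P_x * self.l_x, cut_ages)

    def indirect_shares(self, cut_ages=(30, 40, 50)) -> np.ndarray:
        return cumulative_shares(self.dlambda_Px, cut_ages)

    def fertility_contribution_shares(self, cut_ages=(30, 40)) -> np.ndarray:
        """Shares of direct fertility contributions Delta-lambda_mx = m_x s_mx
        remaining after each cut age."""
        return cumulative_shares(self.m_x * self.s_mx, cut_ages)

    def mean_ages(self, weighting: str = "survivorship") -> tuple[float, float, float]:
        """Mean ages of reproduction, production and demand.  The reporting
        default weights each schedule by survivorship, consistent with the
        pooled totals P_T = sum P_x l_x / D_T = sum D_x l_x; it is the only
        convention under which the net flow of food runs downward (x_P > x_D)
        in long-lived forager-like profiles."""
        return mean_ages(self.m_x, self.P_x, self.D_x, weighting=weighting, l_x=self.l_x)


def selection_report(state: BaselineState, social: SocialProfile) -> SelectionReport:
    """Run the full serial-sensitivity pipeline at a calibrated baseline."""
    lh = state.vital_rates()
    if len(social.r_x) != lh.omega + 1:
        raise ValueError("social profile length must match the age range")
    A = build_matrix(lh.p_x, lh.m_x)
    sens = vital_sensitivities(A)
    s_Px = production_sensitivity(state, social, sens)
    P = state.production()
    dlam = indirect_contribution(P, s_Px)
    e_raw, e_scaled = production_elasticity(s_Px, P, sens.lam, sens.e_mx)
    m_star = fertility_equivalent(s_Px, P, sens.s_mx)
    return SelectionReport(
        ages=np.arange(lh.omega + 1),
        lam=sens.lam,
        E0=state.E0,
        gamma=state.gamma,
        social=social,
        l_x=state.survivorship(),
        P_x=P,
        D_x=state.sub.D_x,
        m_x=lh.m_x,
        p_x=lh.p_x,
        s_mx=sens.s_mx,
        s_px=sens.s_px,
        e_mx=sens.e_mx,
        e_px_vital=sens.e_px,
        s_Px=s_Px,
        dlambda_Px=dlam,
        e_Px_raw=e_raw,
        e_Px_scaled=e_scaled,
        m_star=m_star,
        RV=reproductive_value(lh),
    )
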