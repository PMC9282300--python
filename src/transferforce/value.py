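"""Productive value: the transfer analogue of Fisher's reproductive value.

Reproductive value discounts the reproduction remaining over the life
course; productive value (PV) does the same for the fitness contributed by
future production transfers.  The per-age contribution replaces l_y m_y by
Delta-R_Py, the drop in net reproductive rate when age-y production is
removed from the pooled budget (propagated through the nutrition pathway):

    PV_x = r~_x k (lambda^(x-1) / l_x) sum_{y >= x} lambda^(-y) Delta-R_Py.

PV is a scaled (shape) metric: curves are compared after normalization to
their own maximum, and the normalized shape is insensitive to the nutrition
curvature gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import demographic_summary, reproductive_value
from .nutrition import BaselineState, apply_nutrition, food_ratio
from .schedules import SocialProfile, SubsistenceProfile


def delta_R0(state: BaselineState, full_equilibration: bool = False) -> np.ndarray:
    """Delta-R_Py = R0(baseline) - R0(production at age y zeroed), for all y.

    The food ratio after removing age-y production is recomputed one-shot
    with baseline survivorship (a local perturbation of the pooled budget);
    set ``full_equilibration`` to re-solve E self-consistently instead.
    """
    l_base = state.survivorship()
    P = state.production()
    D = state.sub.D_x
    DT = float(D @ l_base)
    PT = float(P @ l_base)
    R0_base = demographic_summary(state.vital_rates()).R0

    n = len(P)
    out = np.zeros(n)
    for y in range(n):
        if P[y] == 0.0:
            continue
        if full_equilibration:
            P_mod = state.sub.P_x.copy()
            P_mod[y] = 0.0
            sub_mod = SubsistenceProfile(P_x=P_mod, D_x=D, scale=state.sub.scale)
            E_star = food_ratio(sub_mod, state.lh0, state.gamma, self_consistent=True)
        else:
            E_star = (PT - P[y] * l_base[y]) / DT
        E_star = max(E_star, 1e-12)
        lh_star = apply_nutrition(state.lh0, E_star, state.gamma)
        out[y] = R0_base - demographic_summary(lh_star).R0
    return out


def productive_value(
    dR: np.ndarray,
    lam: float,
    l_x: np.ndarray,
    social: SocialProfile,
) -> np.ndarray:
    """PV_x from precomputed Delta-R_Py, at growth rate lambda and baseline
    survivorship l_x.  NaN where l_x = 0 (value conditional on survival to an
    unreachable age is undefined); exactly 0 beyond the last productive age.
    """
    dR = np.asarray(dR, dtype=float)
    n = len(dR)
    y = np.arange(n, dtype=float)
    tail = np.cumsum((lam ** (-y) * dR)[::-1])[::-1]  # sum_{y>=x} lam^-y dR_y
    pv = np.full(n, np.nan)
    ok = np.asarray(l_x) > 0
    x = np.arange(n, dtype=float)
    pv[ok] = (
        social.scaled()[ok]
        * social.k
        * lam ** (x[ok] - 1.0)
        / np.asarray(l_x)[ok]
        * tail[ok]
    )
    pv[(tail == 0.0) & ok] = 0.0
    return pv


@dataclass(frozen=True)
class ProductiveValueReport:
    ages: np.ndarray
    PV: np.ndarray
    PV_normalized: np.ndarray
    dR: np.ndarray
    RV: np.ndarray
    lam: float
    social: SocialProfile


def productive_value_report(
    state: BaselineState, social: SocialProfile, full_equilibration: bool = False
) -> ProductiveValueReport:
    """Compute PV alongside RV at a calibrated baseline."""
    lh = state.vital_rates()
    summ = demographic_summary(lh)
    dR = delta_R0(state, full_equilibration=full_equilibration)
    pv = productive_value(dR, summ.lam, summ.l_x, social)
    peak = np.nanmax(pv) if np.any(np.isfinite(pv)) else np.nan
    pv_norm = pv / peak if peak and peak > 0 else np.full_like(pv, np.nan)
    return ProductiveValueReport(
        ages=np.arange(len(dR)),
        PV=pv,
        PV_normalized=pv_norm,
        dR=dR,
        RV=reproductive_value(lh),
        lam=summ.lam,
        social=social,
    )
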