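"""Leslie-matrix projection, demographic summaries, and eigenvalue
sensitivities/elasticities of the population growth rate.

Bookkeeping is birth-pulse with a pre-breeding census: fertility m_x sits
directly in the first row (F_x = m_x) and survival p_x on the subdiagonal,
so the sensitivity of lambda to fertility at age x is the (0, x) entry
sensitivity and the sensitivity to survival from x to x+1 is the (x+1, x)
entry sensitivity.  Under this convention the Euler-Lotka identity is
sum_x lambda^-(x+1) l_x m_x = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedules import LifeHistoryProfile


class EigensolveError(RuntimeError):
    """Dominant eigenpair could not be extracted."""


def build_matrix(p_x: np.ndarray, m_x: np.ndarray) -> np.ndarray:
    """Leslie matrix: A[0, x] = m_x, A[x+1, x] = p_x, zeros elsewhere."""
    p = np.asarray(p_x, dtype=float)
    m = np.asarray(m_x, dtype=float)
    if p.shape != m.shape:
        raise ValueError(f"p_x and m_x length mismatch: {p.shape} vs {m.shape}")
    n = len(m)
    A = np.zeros((n, n))
    A[0, :] = m
    if n > 1:
        A[np.arange(1, n), np.arange(n - 1)] = p[:-1]
    return A


def dominant_eigen(A: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Dominant eigenvalue with right (w) and left (v) eigenvectors.

    Returns (lambda, w, v) with w >= 0 summing to 1 and v >= 0 with v[0] = 1.
    For a nilpotent matrix (no reproduction) lambda = 0 and uniform vectors
    are returned.
    """
    vals, right = np.linalg.eig(A)
    # Perron root: among eigenvalues tied in modulus (periodic life cycles
    # produce complex/negative partners of equal modulus), take the one with
    # the largest real part.
    mod = np.abs(vals)
    cand = np.flatnonzero(mod >= mod.max() * (1.0 - 1e-9))
    idx = int(cand[np.argmax(vals[cand].real)])
    lam = vals[idx]
    if abs(lam) == 0.0:
        n = A.shape[0]
        return 0.0, np.full(n, 1.0 / n), np.ones(n)
    if abs(lam.imag) > 1e-9 * abs(lam):
        raise EigensolveError(f"dominant eigenvalue is complex: {lam}")
    lam = float(lam.real)
    w = np.real(right[:, idx])
    # Left eigenvector from the transpose.
    valsT, left = np.linalg.eig(A.T)
    jdx = int(np.argmin(np.abs(valsT - lam)))
    v = np.real(left[:, jdx])
    if w.sum() < 0:
        w = -w
    if v.sum() < 0:
        v = -v
    w = np.clip(w, 0.0, None)
    v = np.clip(v, 0.0, None)
    w = w / w.sum()
    if v[0] <= 0:
        raise EigensolveError("left eigenvector vanishes at age 0")
    v = v / v[0]
    return lam, w, v


@dataclass(frozen=True)
class DemographicSummary:
    lam: float          # asymptotic growth rate per year (dominant eigenvalue)
    r: float            # intrinsic growth rate log(lambda)
    l_x: np.ndarray     # survivorship to age x, l_0 = 1
    R0: float           # net reproductive rate, sum l_x m_x
    e0: float           # life expectancy at birth (discrete: sum l_x)
    TFR: float          # total fertility rate, sum m_x
    w_x: np.ndarray     # stable age distribution (sums to 1)
    v_x: np.ndarray     # reproductive values, v_0 = 1

    def as_text(self) -> str:
        lines = [
            f"lambda  {self.lam:.6f}",
            f"r       {self.r:.6f}",
            f"R0      {self.R0:.4f}",
            f"e0      {self.e0:.2f}",
            f"TFR     {self.TFR:.3f}",
        ]
        return "\n".join(lines)


def demographic_summary(lh: LifeHistoryProfile) -> DemographicSummary:
    """Growth rate, life-table quantities, stable structure and reproductive
    value for a life-history profile."""
    A = build_matrix(lh.p_x, lh.m_x)
    lam, w, v = dominant_eigen(A)
    l_x = lh.survivorship()
    R0 = float(l_x @ lh.m_x)
    return DemographicSummary(
        lam=lam,
        r=float(np.log(lam)) if lam > 0 else -np.inf,
        l_x=l_x,
        R0=R0,
        e0=float(l_x.sum()),
        TFR=float(lh.m_x.sum()),
        w_x=w,
        v_x=v,
    )


@dataclass(frozen=True)
class SensitivityTable:
    """Sensitivities and elasticities of lambda to the Leslie-matrix vital
    rates: s_mx = dlambda/dm_x (first-row entries), s_px = dlambda/dp_x
    (subdiagonal entries; the final class has no survival transition and gets
    0 there)."""

    lam: float
    s_mx: np.ndarray
    s_px: np.ndarray
    e_mx: np.ndarray
    e_px: np.ndarray

    @property
    def total_fertility_elasticity(self) -> float:
        return float(self.e_mx.sum())

    @property
    def total_elasticity(self) -> float:
        return float(self.e_mx.sum() + self.e_px.sum())


def vital_sensitivities(A: np.ndarray) -> SensitivityTable:
    """Eigenvalue sensitivities s_ij = v_i w_j / <v, w> for the structurally
    nonzero entries, and the matching elasticities e_ij = (a_ij/lambda) s_ij.

    Elasticities over all nonzero entries sum to 1 (the classic conservation
    property for the dominant eigenvalue of a nonnegative matrix).
    """
    lam, w, v = dominant_eigen(A)
    if lam <= 0:
        raise EigensolveError("sensitivities undefined for non-growing nilpotent matrix")
    denom = float(v @ w)
    n = A.shape[0]
    s_mx = v[0] * w / denom
    s_px = np.zeros(n)
    s_px[: n - 1] = v[1:] * w[: n - 1] / denom
    e_mx = A[0, :] * s_mx / lam
    e_px = np.zeros(n)
    e_px[: n - 1] = A[np.arange(1, n), np.arange(n - 1)] * s_px[: n - 1] / lam
    return SensitivityTable(lam=lam, s_mx=s_mx, s_px=s_px, e_mx=e_mx, e_px=e_px)


def reproductive_value(lh: LifeHistoryProfile) -> np.ndarray:
    """Fisher's reproductive value v_x, scaled so v_0 = 1.

    Ages with no remaining reproduction (sum of future l_y m_y from x on is
    zero) are set exactly to 0.
    """
    A = build_matrix(lh.p_x, lh.m_x)
    _, _, v = dominant_eigen(A)
    l_x = lh.survivorship()
    future = np.cumsum((l_x * lh.m_x)[::-1])[::-1]
    v = v.copy()
    v[future <= 0] = 0.0
    return v


def euler_lotka_residual(lh: LifeHistoryProfile, lam: float) -> float:
    """sum_x lambda^-(x+1) l_x m_x - 1 at the supplied lambda."""
    l_x = lh.survivorship()
    x = np.arange(len(l_x))
    return float(np.sum(lam ** -(x + 1.0) * l_x * lh.m_x) - 1.0)
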