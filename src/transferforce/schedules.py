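"""Age-indexed schedules and life-history / subsistence profiles.

Everything downstream runs on four schedules defined on contiguous 1-year
age classes 0..omega: survival p_x (or mortality q_x), fertility m_x
(daughters per female per year), caloric production P_x and caloric demand
D_x (kcal/day).  This module reads and writes them as flat CSV, synthesizes
stylized "chimp-like" and "human-like" profiles, builds counterfactual
composites, and constructs age profiles of mean relatedness to the sharing
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ProfileValidationError(ValueError):
    """Raised when a schedule or profile violates its invariants."""


def _as_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ProfileValidationError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ProfileValidationError(f"{name} has non-finite value at age {bad}")
    return arr


@dataclass(frozen=True)
class AgeSchedule:
    """A real-valued quantity on contiguous integer ages 0..omega."""

    values: np.ndarray
    start_age: int = 0

    def __post_init__(self):
        object.__setattr__(self, "values", _as_vector(self.values, "schedule"))
        if self.start_age != 0:
            raise ProfileValidationError("schedules must start at age 0")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(len(self.values))

    @property
    def omega(self) -> int:
        return len(self.values) - 1

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class LifeHistoryProfile:
    """Baseline (replete) vital rates: mortality q_x and fertility m_x.

    The rates held here are interpreted as the nutritionally replete rates
    q_x^(0), m_x^(0); the nutrition module degrades them via the scalar Z.
    """

    q_x: np.ndarray
    m_x: np.ndarray

    def __post_init__(self):
        q = _as_vector(self.q_x, "q_x")
        m = _as_vector(self.m_x, "m_x")
        if len(q) != len(m):
            raise ProfileValidationError("q_x and m_x must have equal length")
        if np.any((q < 0) | (q > 1)):
            bad = int(np.flatnonzero((q < 0) | (q > 1))[0])
            raise ProfileValidationError(f"q_x out of [0, 1] at age {bad}")
        if not np.isclose(q[-1], 1.0):
            raise ProfileValidationError(
                f"life table must close: q at final age {len(q) - 1} must be 1, got {q[-1]}"
            )
        if np.any(m < 0):
            bad = int(np.flatnonzero(m < 0)[0])
            raise ProfileValidationError(f"m_x negative at age {bad}")
        object.__setattr__(self, "q_x", q)
        object.__setattr__(self, "m_x", m)

    @property
    def p_x(self) -> np.ndarray:
        return 1.0 - self.q_x

    @property
    def omega(self) -> int:
        return len(self.q_x) - 1

    def survivorship(self) -> np.ndarray:
        """l_x = prod_{y<x} p_y, with l_0 = 1."""
        return np.concatenate([[1.0], np.cumprod(self.p_x[:-1])])


@dataclass(frozen=True)
class SubsistenceProfile:
    """Caloric production P_x and demand D_x (kcal/day) by age.

    ``scale`` is a positive multiplier applied to P_x; calibration sets it so
    that survivorship-weighted production meets demand at replete nutrition.
    """

    P_x: np.ndarray
    D_x: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        P = _as_vector(self.P_x, "P_x")
        D = _as_vector(self.D_x, "D_x")
        if len(P) != len(D):
            raise ProfileValidationError("P_x and D_x must have equal length")
        if np.any(P < 0):
            bad = int(np.flatnonzero(P < 0)[0])
            raise ProfileValidationError(f"P_x negative at age {bad}")
        if np.any(D < 0):
            bad = int(np.flatnonzero(D < 0)[0])
            raise ProfileValidationError(f"D_x negative at age {bad}")
        if not self.scale > 0:
            raise ProfileValidationError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "P_x", P)
        object.__setattr__(self, "D_x", D)

    @property
    def omega(self) -> int:
        return len(self.P_x) - 1

    def production(self) -> np.ndarray:
        """Effective production schedule, scale applied."""
        return self.scale * self.P_x

    def with_scale(self, scale: float) -> "SubsistenceProfile":
        return replace(self, scale=float(scale))


@dataclass(frozen=True)
class SocialProfile:
    """Mean relatedness r_x of an age-x donor to the sharing group, and the
    cooperation probability k (compliance with the need-based sharing norm)."""

    r_x: np.ndarray
    k: float = 1.0

    def __post_init__(self):
        r = _as_vector(self.r_x, "r_x")
        if np.any((r < 0) | (r > 0.5)):
            bad = int(np.flatnonzero((r < 0) | (r > 0.5))[0])
            raise ProfileValidationError(f"r_x out of [0, 0.5] at age {bad}")
        if not 0.0 <= self.k <= 1.0:
            raise ProfileValidationError(f"k must lie in [0, 1], got {self.k}")
        object.__setattr__(self, "r_x", r)

    def scaled(self) -> np.ndarray:
        """Relatedness re-expressed against the direct-offspring benchmark
        r = 0.5, so a group of full offspring gives weight 1."""
        return self.r_x / 0.5


# ---------------------------------------------------------------------------
# CSV I/O

_COLUMNS = ("age", "px", "mx", "Px", "Dx")


def read_profiles(path) -> tuple[LifeHistoryProfile, SubsistenceProfile]:
    """Read a profile table with header ``age,px,mx,Px,Dx`` (``qx`` accepted
    in place of ``px``), one row per age, ages contiguous from 0."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    has_p = "px" in cols
    has_q = "qx" in cols
    required = {"age", "mx", "Px", "Dx"}
    missing = sorted(required - cols)
    if missing or not (has_p or has_q):
        if not (has_p or has_q):
            missing = missing + ["px (or qx)"]
        raise ProfileValidationError(f"missing column(s): {', '.join(missing)}")
    ages = df["age"].to_numpy()
    expected = np.arange(len(ages))
    if not np.array_equal(ages, expected):
        bad = ages[ages != expected[: len(ages)]] if len(ages) else ages
        first_bad = int(np.asarray(bad).ravel()[0]) if len(np.atleast_1d(bad)) else -1
        raise ProfileValidationError(
            f"ages must be contiguous from 0; first offending age: {first_bad}"
        )
    if has_q:
        q = df["qx"].to_numpy(dtype=float)
    else:
        q = 1.0 - df["px"].to_numpy(dtype=float)
    lh = LifeHistoryProfile(q_x=q, m_x=df["mx"].to_numpy(dtype=float))
    sub = SubsistenceProfile(P_x=df["Px"].to_numpy(dtype=float), D_x=df["Dx"].to_numpy(dtype=float))
    return lh, sub


def write_profiles(path, lh: LifeHistoryProfile, sub: SubsistenceProfile) -> None:
    """Write the canonical CSV (unscaled P_x; scale is calibration state)."""
    df = pd.DataFrame(
        {
            "age": np.arange(lh.omega + 1),
            "px": lh.p_x,
            "mx": lh.m_x,
            "Px": sub.P_x,
            "Dx": sub.D_x,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic profiles

def _siler_mortality(ages: np.ndarray, a1, b1, a2, a3, b3) -> np.ndarray:
    """Annual mortality from a Siler hazard: infant decline + constant +
    Gompertz senescence."""
    hazard = a1 * np.exp(-b1 * ages) + a2 + a3 * np.exp(b3 * ages)
    q = 1.0 - np.exp(-hazard)
    q[-1] = 1.0
    return q


def _logistic(x, center, width):
    return 1.0 / (1.0 + np.exp(-(x - center) / width))


_SYNTH_DEFAULTS = {
    # Early foraging self-sufficiency (~age 5), early production peak, small
    # adult surplus vanishing by the 40s, high adult mortality, no
    # reproductive cessation.
    "chimp-like": dict(
        omega=60,
        siler=(0.15, 1.0, 0.020, 0.0008, 0.115),
        fert=dict(first=12, peak=19, width=14.0, level=0.20, cessation=None),
        prod=dict(rise_center=4.0, rise_width=1.3, fall_center=33.0, fall_width=6.0, amp=2350.0),
        demand=dict(adult=1750.0, infant=950.0, rise_center=7.0, rise_width=3.0, old_decline=0.0),
    ),
    # Net-consumer childhood for ~two decades, production peak in the
    # 30s-40s, surplus sustained past 60, lower adult mortality, reproductive
    # cessation near age 50.
    "human-like": dict(
        omega=90,
        siler=(0.16, 1.1, 0.008, 0.00015, 0.094),
        fert=dict(first=17, peak=26, width=11.0, level=0.18, cessation=50),
        prod=dict(rise_center=17.5, rise_width=4.2, fall_center=66.0, fall_width=8.0, amp=4700.0),
        demand=dict(adult=2500.0, infant=900.0, rise_center=9.0, rise_width=4.0, old_decline=0.10),
    ),
}


def synth_profiles(
    kind: str,
    omega: int | None = None,
    params: dict | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[LifeHistoryProfile, SubsistenceProfile]:
    """Generate stylized vital-rate and subsistence schedules.

    ``kind`` selects between a chimpanzee-like regime (early self-sufficiency,
    small adult surplus, high adult mortality, reproduction until death) and a
    human forager-like regime (long dependent childhood, mid-life production
    peak with surplus past 60, lower adult mortality, reproductive cessation
    near 50).  Deterministic given ``seed``; multiplicative lognormal noise on
    P_x only, and only when ``noise_sd`` > 0.
    """
    if kind not in _SYNTH_DEFAULTS:
        raise ProfileValidationError(f"unknown kind {kind!r}; use 'chimp-like' or 'human-like'")
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _SYNTH_DEFAULTS[kind].items()}
    if params:
        for key, val in params.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if omega is None:
        omega = cfg["omega"]
    if omega < 10:
        raise ProfileValidationError("omega must be at least 10")
    ages = np.arange(omega + 1, dtype=float)

    q = _siler_mortality(ages, *cfg["siler"])

    f = cfg["fert"]
    m = f["level"] * np.exp(-((ages - f["peak"]) ** 2) / (2 * f["width"] ** 2))
    m[ages < f["first"]] = 0.0
    if f["cessation"] is not None:
        m[ages >= f["cessation"]] = 0.0

    p = cfg["prod"]
    P = p["amp"] * _logistic(ages, p["rise_center"], p["rise_width"]) * (
        1.0 - _logistic(ages, p["fall_center"], p["fall_width"])
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        P = P * rng.lognormal(mean=-0.5 * noise_sd**2, sigma=noise_sd, size=P.shape)

    d = cfg["demand"]
    D = d["infant"] + (d["adult"] - d["infant"]) * _logistic(ages, d["rise_center"], d["rise_width"])
    if d["old_decline"] > 0:
        D = D * (1.0 - d["old_decline"] * _logistic(ages, 0.8 * omega, 5.0))

    lh = LifeHistoryProfile(q_x=q, m_x=m)
    sub = SubsistenceProfile(P_x=P, D_x=D)
    return lh, sub


# ---------------------------------------------------------------------------
# Counterfactual composites

def permute_counterfactual(
    lh: LifeHistoryProfile, sub: SubsistenceProfile
) -> tuple[LifeHistoryProfile, SubsistenceProfile]:
    """Combine a life history with a (possibly foreign) subsistence profile.

    Age ranges are reconciled by truncation to the shared range; the life
    table is re-closed at the new omega.
    """
    n = min(lh.omega, sub.omega) + 1
    if n <= 0:
        raise ProfileValidationError("no overlapping age range")
    q = lh.q_x[:n].copy()
    q[-1] = 1.0
    lh2 = LifeHistoryProfile(q_x=q, m_x=lh.m_x[:n])
    sub2 = SubsistenceProfile(P_x=sub.P_x[:n], D_x=sub.D_x[:n], scale=sub.scale)
    return lh2, sub2


# ---------------------------------------------------------------------------
# Relatedness profiles

#: Default half-span of the linear relatedness ramp (difference between the
#: endpoint and the age-mean), as a fraction of the requested level.
RAMP_RELATIVE_SPAN = 0.5


def relatedness_profile(
    shape: str, level: float, omega: int, k: float = 1.0
) -> SocialProfile:
    """Build an age profile of mean relatedness to the focal sharing group.

    ``constant`` gives r_x = level at every age.  ``increasing`` and
    ``decreasing`` give linear ramps whose age-mean equals ``level``; the ramp
    runs from level*(1 - RAMP_RELATIVE_SPAN) to level*(1 + RAMP_RELATIVE_SPAN),
    clipped into [0, 0.5] by shrinking the span if needed.
    """
    if not 0.0 <= level <= 0.5:
        raise ProfileValidationError(f"relatedness level must lie in [0, 0.5], got {level}")
    n = omega + 1
    if shape == "constant":
        r = np.full(n, level)
    elif shape in ("increasing", "decreasing"):
        span = RAMP_RELATIVE_SPAN * level
        span = min(span, 0.5 - level, level)  # keep endpoints inside [0, 0.5]
        ramp = np.linspace(level - span, level + span, n)
        r = ramp if shape == "increasing" else ramp[::-1].copy()
    else:
        raise ProfileValidationError(
            f"unknown relatedness shape {shape!r}; use constant/increasing/decreasing"
        )
    return SocialProfile(r_x=r, k=k)
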