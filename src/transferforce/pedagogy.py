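"""Fitness contributions of information transfers (pedagogy).

Teaching accelerates pupils' skill acquisition at a production cost to
teachers.  Production is skill-based: a biomechanical capacity curve M_x
times a saturating skill stock S_x raised to a niche-dependent weight w,
P_x = amp * M_x * S_x^w.  A pedagogy regime (phi, theta, a, b, t) taxes
teacher production by phi on ages [b, b+t) and multiplies the pupils' skill
accumulation rate by (1 + theta) on ages [a, a+t).  At a regime steady
state every cohort passes through both roles, so the cross-sectional
production schedule carries both effects; survivorship weighting happens in
the pooled totals P_T and D_T downstream.

The fitness consequence is propagated through the nutrition pathway: the
modified production schedule shifts the group food ratio, vital rates, and
hence intrinsic growth r, and the gain is discounted by the teacher's
relatedness to the group (against the direct-offspring benchmark) and the
cooperation probability k.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .demography import demographic_summary
from .nutrition import BaselineState, apply_nutrition, calibrate, food_ratio
from .schedules import LifeHistoryProfile, SocialProfile, SubsistenceProfile, _logistic


def load_presets() -> dict:
    """Skill-production preset constants (shipped as package config)."""
    text = resources.files(__package__).joinpath("pedagogy_presets.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class PedagogyRegime:
    """(phi, theta, a, b, t): teacher production cost, pupil skill-rate
    boost, pupil onset age, teacher onset age, duration (years)."""

    phi: float = 0.0
    theta: float = 0.0
    pupil_age: int = 10
    teacher_age: int = 30
    duration: int = 10

    def validate(self, omega: int) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        if self.pupil_age + self.duration > omega:
            raise ValueError("instruction window extends past omega")
        if self.teacher_age < self.pupil_age:
            raise ValueError("teachers must be at least as old as pupils")


NULL_REGIME = PedagogyRegime(phi=0.0, theta=0.0)


@dataclass(frozen=True)
class SkillProductionModel:
    """P_x = amp * M_x * S_x^w with saturating skill accumulation."""

    w: float
    rho_s: float
    s0: float
    amp: float
    cap_rise_center: float
    cap_rise_width: float
    cap_fall_center: float
    cap_fall_width: float

    @classmethod
    def preset(cls, name: str) -> "SkillProductionModel":
        presets = load_presets()
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
        return cls(**presets[name])

    def capacity(self, ages: np.ndarray) -> np.ndarray:
        return _logistic(ages, self.cap_rise_center, self.cap_rise_width) * (
            1.0 - _logistic(ages, self.cap_fall_center, self.cap_fall_width)
        )

    def skill(
        self,
        omega: int,
        regime: PedagogyRegime = NULL_REGIME,
        l_x: np.ndarray | None = None,
    ) -> np.ndarray:
        """Skill stock by age: S_{x+1} = S_x + rate_x (1 - S_x), with the
        rate boosted by (1 + theta) while under instruction.

        Instruction requires a living teacher: a pupil cohort starting at age
        a is paired with a teacher cohort at age b, and in instruction year j
        the boost is scaled by the fraction l_{b+j}/l_b of teachers still
        alive (``l_x`` supplies the survivorship; omitted, teachers are
        treated as immortal).
        """
        S = np.empty(omega + 1)
        S[0] = self.s0
        a, b, t = regime.pupil_age, regime.teacher_age, regime.duration
        for x in range(omega):
            rate = self.rho_s
            if regime.theta > 0 and a <= x < a + t:
                avail = 1.0
                if l_x is not None:
                    j = x - a
                    ta = min(b + j, omega)
                    avail = l_x[ta] / l_x[b] if l_x[b] > 0 else 0.0
                rate *= 1.0 + regime.theta * avail
            S[x + 1] = S[x] + rate * (1.0 - S[x])
        return S

    def production(
        self,
        omega: int,
        regime: PedagogyRegime = NULL_REGIME,
        l_x: np.ndarray | None = None,
    ) -> np.ndarray:
        """Cross-sectional production schedule under a pedagogy regime."""
        ages = np.arange(omega + 1, dtype=float)
        P = self.amp * self.capacity(ages) * self.skill(omega, regime, l_x) ** self.w
        if regime.phi > 0:
            b, t = regime.teacher_age, regime.duration
            lo, hi = b, min(b + t, omega + 1)
            P[lo:hi] *= 1.0 - regime.phi
        return P


def apply_pedagogy(
    model: SkillProductionModel,
    regime: PedagogyRegime,
    omega: int,
    l_x: np.ndarray | None = None,
) -> np.ndarray:
    """Population production schedule under ``regime`` (boost + cost)."""
    regime.validate(omega)
    return model.production(omega, regime, l_x)


def skill_baseline_state(
    lh0: LifeHistoryProfile,
    D_x: np.ndarray,
    model: SkillProductionModel,
    gamma: float,
    r_target: float = 0.01,
) -> BaselineState:
    """Calibrate a skill-model production profile against a life history and
    demand schedule to the target baseline growth."""
    P0 = model.production(lh0.omega)
    sub = SubsistenceProfile(P_x=P0, D_x=np.asarray(D_x, dtype=float))
    return calibrate(lh0, sub, gamma, r_target=r_target)


def _growth_with_production(state: BaselineState, P_x: np.ndarray) -> float:
    """Self-consistent intrinsic growth with the calibrated scale applied to
    an alternative raw production schedule."""
    sub = SubsistenceProfile(P_x=P_x, D_x=state.sub.D_x, scale=state.sub.scale)
    E = food_ratio(sub, state.lh0, state.gamma, self_consistent=True)
    return demographic_summary(apply_nutrition(state.lh0, E, state.gamma)).r


def pedagogy_fitness_gain(
    state: BaselineState,
    model: SkillProductionModel,
    regime: PedagogyRegime,
    social: SocialProfile,
) -> float:
    """Change in intrinsic growth r from adopting a pedagogy regime,
    discounted by the teacher's scaled relatedness and by k.

    ``state`` must be the calibrated baseline built from the same skill
    model with the null regime (see ``skill_baseline_state``), so the null
    regime returns exactly 0.
    """
    omega = state.lh0.omega
    regime.validate(omega)
    l_x = state.survivorship()
    P_base = model.production(omega)
    P_regime = apply_pedagogy(model, regime, omega, l_x)
    r_base = _growth_with_production(state, P_base)
    r_new = _growth_with_production(state, P_regime)
    b = min(regime.teacher_age, omega)
    discount = social.scaled()[b] * social.k
    return float(discount * (r_new - r_base))


@dataclass(frozen=True)
class TeacherAgeScan:
    teacher_ages: np.ndarray
    gains: np.ndarray          # delta-r per teacher age
    optimal_age: int
    optimal_gain: float
    break_even_ages: np.ndarray  # teacher ages where the gain crosses zero


def optimize_teacher_age(
    state: BaselineState,
    model: SkillProductionModel,
    social: SocialProfile,
    phi: float,
    theta: float,
    pupil_age: int,
    duration: int,
    teacher_ages=None,
) -> TeacherAgeScan:
    """Sweep the teacher onset age b and locate the fitness-maximizing age
    and the break-even ages (zero crossings of the gain curve)."""
    omega = state.lh0.omega
    if teacher_ages is None:
        teacher_ages = np.arange(pupil_age, omega - duration + 1)
    teacher_ages = np.asarray(teacher_ages, dtype=int)
    if len(teacher_ages) == 0:
        raise ValueError("empty teacher-age grid")
    gains = np.array(
        [
            pedagogy_fitness_gain(
                state,
                model,
                PedagogyRegime(phi=phi, theta=theta, pupil_age=pupil_age,
                               teacher_age=int(b), duration=duration),
                social,
            )
            for b in teacher_ages
        ]
    )
    best = int(np.argmax(gains))
    sign = np.sign(gains)
    crossings = np.flatnonzero(np.diff(sign) != 0)
    return TeacherAgeScan(
        teacher_ages=teacher_ages,
        gains=gains,
        optimal_age=int(teacher_ages[best]),
        optimal_gain=float(gains[best]),
        break_even_ages=teacher_ages[crossings],
    )
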