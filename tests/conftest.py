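import numpy as np
import pytest

import transferforce as tf
from transferforce.demography import build_matrix, dominant_eigen
from transferforce.nutrition import apply_nutrition

GAMMA = 0.3
R_TARGET = 0.01


@pytest.fixture(scope="session")
def human_profiles():
    return tf.synth_profiles("human-like", seed=1)


@pytest.fixture(scope="session")
def chimp_profiles():
    return tf.synth_profiles("chimp-like", seed=1)


@pytest.fixture(scope="session")
def human_state(human_profiles):
    lh, sub = human_profiles
    return tf.calibrate(lh, sub, GAMMA, r_target=R_TARGET)


@pytest.fixture(scope="session")
def chimp_state(chimp_profiles):
    lh, sub = chimp_profiles
    return tf.calibrate(lh, sub, GAMMA, r_target=R_TARGET)


@pytest.fixture(scope="session")
def offspring_social(human_state):
    """Benchmark social profile: every group member as related as direct
    offspring, full cooperation."""
    n = human_state.lh0.omega + 1
    return tf.SocialProfile(r_x=np.full(n, 0.5), k=1.0)


def numeric_dlambda_dP(state, ages, h_rel=1e-4):
    """One-shot numerical derivative of lambda with respect to P_x: perturb
    calibrated production at one age, recompute E with baseline survivorship,
    re-apply nutrition, re-solve the eigenproblem."""
    l_base = state.survivorship()
    P = state.production()
    DT = float(state.sub.D_x @ l_base)

    def lam_of(P_mod):
        E = float(P_mod @ l_base) / DT
        lh = apply_nutrition(state.lh0, E, state.gamma)
        return dominant_eigen(build_matrix(lh.p_x, lh.m_x))[0]

    out = {}
    for x in ages:
        h = h_rel * max(P[x], 1.0)
        Pp = P.copy(); Pp[x] += h
        Pm = P.copy(); Pm[x] -= h
        out[x] = (lam_of(Pp) - lam_of(Pm)) / (2 * h)
    return out
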