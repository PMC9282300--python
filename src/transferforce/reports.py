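"""Tabular report assembly shared by the CLI and scripts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nutrition import BaselineState
from .schedules import SocialProfile
from .selection import SelectionReport, selection_report
from .value import ProductiveValueReport, productive_value_report

PER_AGE_COLUMNS = [
    "age", "px", "mx", "Px", "Dx", "lx",
    "s_mx", "s_px", "e_mx", "e_px_scaled",
    "dlambda_Px", "m_star", "RV", "PV",
]


def per_age_table(rep: SelectionReport, pv: ProductiveValueReport) -> pd.DataFrame:
    """The canonical per-age output table."""
    return pd.DataFrame(
        {
            "age": rep.ages,
            "px": rep.p_x,
            "mx": rep.m_x,
            "Px": rep.P_x,
            "Dx": rep.D_x,
            "lx": rep.l_x,
            "s_mx": rep.s_mx,
            "s_px": rep.s_px,
            "e_mx": rep.e_mx,
            "e_px_scaled": rep.e_Px_scaled,
            "dlambda_Px": rep.dlambda_Px,
            "m_star": rep.m_star,
            "RV": rep.RV,
            "PV": pv.PV,
        }
    )[PER_AGE_COLUMNS]


def summary_block(state: BaselineState, rep: SelectionReport) -> dict:
    """Key scalar summaries of a calibrated run."""
    calib = state.calibration
    x_M, x_P, x_D = rep.mean_ages()
    prod_shares = rep.production_shares((30, 40, 50))
    fert_shares = rep.fertility_contribution_shares((30, 40))
    return {
        "lambda": rep.lam,
        "r": float(np.log(rep.lam)),
        "E0": calib.E0,
        "E_min": calib.E_min,
        "r_max": calib.r_max,
        "replete_scale": calib.replete_scale,
        "rho": calib.rho,
        "gamma": state.gamma,
        "k": rep.social.k,
        "mean_relatedness": float(np.mean(rep.social.r_x)),
        "x_M": x_M,
        "x_P": x_P,
        "x_D": x_D,
        "fertility_elasticity_share": rep.fertility_elasticity_share,
        "production_share_after_30": float(prod_shares[0]),
        "production_share_after_40": float(prod_shares[1]),
        "production_share_after_50": float(prod_shares[2]),
        "indirect_share_after_50": float(rep.indirect_shares((50,))[0]),
        "fertility_contribution_share_after_30": float(fert_shares[0]),
        "fertility_contribution_share_after_40": float(fert_shares[1]),
        "TFR_50": rep.tfr50,
    }


def summary_text(summary: dict) -> str:
    width = max(len(k) for k in summary)
    return "\n".join(f"{k.ljust(width)}  {v:.6g}" for k, v in summary.items())


def run_pipeline(
    state: BaselineState, social: SocialProfile
) -> tuple[SelectionReport, ProductiveValueReport, pd.DataFrame, dict]:
    """Selection metrics, productive value, per-age table and summary for a
    calibrated baseline."""
    rep = selection_report(state, social)
    pv = productive_value_report(state, social)
    table = per_age_table(rep, pv)
    return rep, pv, table, summary_block(state, rep)
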