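"""Control-referenced certainty scale for mMCD II classification.

Rather than hard-coding any absolute density cutoff, the classifier derives
its thresholds from a laboratory's own control series, measured with the
same counting method: by default a case is *within the control range* up to
control mean + 2 sd, *borderline* between that and the control maximum, and
*mMCD II* strictly above the control maximum. The cut expressions are fully
configurable in terms of the reference's mean, sd and max, so a site can
tighten or relax the certainty tiers without touching code.

``EXAMPLE_CONTROL_MAX_WSA_AUTO`` (2298 cells/mm³) is shipped purely as a
documented example of a control maximum observed in one published
temporal-lobe series under whole-slide automated counting; it is method- and
cohort-specific and is never used as a default decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WITHIN = "within_control_range"
BORDERLINE = "borderline"
MMCD_II = "mMCD_II"
TIER_ORDER = {WITHIN: 0, BORDERLINE: 1, MMCD_II: 2}

#: Example control maximum (cells/mm³) from a published series, WSA automated.
EXAMPLE_CONTROL_MAX_WSA_AUTO = 2298.0

DEFAULT_RULE = {"borderline": "mean + 2 * sd", "mmcd": "max"}


@dataclass
class ControlReference:
    """Summary of the control series used to anchor the certainty scale."""

    mean_Nv: float
    sd_Nv: float
    max_Nv: float
    n_controls: int
    method: str = "wsa_manual"


@dataclass
class MMCDCall:
    Nv: float
    tier: str
    thresholds: dict  # {"borderline": value, "mmcd": value}


def fit_control_reference(control_Nvs: list[float], method: str = "wsa_manual") -> ControlReference:
    """Mean, sd (ddof=1) and max of the control densities (≥ 2 required)."""
    vals = np.asarray(control_Nvs, dtype=float)
    if len(vals) < 2:
        raise ValueError("at least 2 control cases are required")
    return ControlReference(
        mean_Nv=float(vals.mean()),
        sd_Nv=float(vals.std(ddof=1)),
        max_Nv=float(vals.max()),
        n_controls=len(vals),
        method=method,
    )


def _eval_cut(expr: str, ref: ControlReference) -> float:
    ns = {"mean": ref.mean_Nv, "sd": ref.sd_Nv, "max": ref.max_Nv, "min": min}
    return float(eval(expr, {"__builtins__": {}}, ns))  # noqa: S307 - restricted namespace


def classify_case(Nv: float, ref: ControlReference, rule: dict | None = None) -> MMCDCall:
    """Assign a certainty tier to one case density.

    Default rule: Nv ≤ mean + 2 sd → within the control range;
    above that but ≤ control max → borderline; strictly above the control
    max → mMCD II (the boundary value itself stays borderline). The
    borderline cut is clipped to the mMCD cut so tiers stay monotone even
    when mean + 2 sd exceeds the control maximum.
    """
    if Nv < 0:
        raise ValueError("Nv must be >= 0")
    rule = rule or DEFAULT_RULE
    t_mmcd = _eval_cut(rule["mmcd"], ref)
    t_border = min(_eval_cut(rule["borderline"], ref), t_mmcd)
    if Nv > t_mmcd:
        tier = MMCD_II
    elif Nv > t_border:
        tier = BORDERLINE
    else:
        tier = WITHIN
    return MMCDCall(Nv=Nv, tier=tier, thresholds={"borderline": t_border, "mmcd": t_mmcd})


def classify_cohort(
    Nvs: dict[str, float], ref: ControlReference, rule: dict | None = None
) -> pd.DataFrame:
    """Classify a set of cases; returns a summary table indexed by case id."""
    rows = []
    for case_id, nv in Nvs.items():
        call = classify_case(nv, ref, rule=rule)
        rows.append(
            {
                "case_id": case_id,
                "Nv": call.Nv,
                "tier": call.tier,
                "threshold_borderline": call.thresholds["borderline"],
                "threshold_mmcd": call.thresholds["mmcd"],
            }
        )
    return pd.DataFrame(rows).set_index("case_id")
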