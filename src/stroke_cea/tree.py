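"""The 3-month pre-hospital identification decision tree.

Patients enter after an ischaemic stroke.  Accurate pre-hospital
identification (probability ``p_accurate``) is the gate to thrombolysis
within the 60-minute door-to-needle window (probability
``p_ivt_within_60min``); thrombolysed patients may suffer an adverse event
(``p_adverse_event``) whose outcome distribution replaces the thrombolysis
one.  Everyone else — accurately identified patients missing the window and
misidentified patients — receives usual care.  Each branch ends in a 90-day
modified Rankin Scale distribution; the tree's output is their
path-probability-weighted mixture, which becomes the initial state vector of
the long-term Markov model (90-day deaths enter the dead state directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import DEAD_STATE, ShortTermParams, _check_probability

__all__ = ["NinetyDayResult", "evaluate_tree", "short_term_expected_ivt_cost"]

#: Root-to-leaf branch labels in the order reported.
PATHS = ("ivt_no_adverse", "ivt_adverse", "accurate_usual_care", "inaccurate_usual_care")


@dataclass
class NinetyDayResult:
    """Mixture 90-day mRS distribution and the branch masses producing it."""

    mrs_distribution: np.ndarray
    path_probabilities: dict[str, float]
    ivt_fraction: float

    @property
    def death_mass(self) -> float:
        return float(self.mrs_distribution[DEAD_STATE])


def evaluate_tree(
    p_accurate: float, stp: ShortTermParams, tolerance: float = 0.05
) -> NinetyDayResult:
    """Evaluate the decision tree for one identification accuracy.

    Returns the normalized 90-day mRS mixture, the four root-to-leaf path
    probabilities and the fraction of the cohort receiving thrombolysis
    (``p_accurate * p_ivt_within_60min``).
    """
    _check_probability(p_accurate, "p_accurate")
    p_ivt = stp.p_ivt_within_60min
    p_ae = stp.p_adverse_event

    d_ivt = stp.dist_ivt.normalized(tolerance)
    d_ae = stp.dist_adverse.normalized(tolerance)
    d_uc = stp.dist_usual_care.normalized(tolerance)

    w_ivt_no_ae = p_accurate * p_ivt * (1.0 - p_ae)
    w_ivt_ae = p_accurate * p_ivt * p_ae
    w_acc_uc = p_accurate * (1.0 - p_ivt)
    w_inacc = 1.0 - p_accurate

    mixture = w_ivt_no_ae * d_ivt + w_ivt_ae * d_ae + (w_acc_uc + w_inacc) * d_uc
    return NinetyDayResult(
        mrs_distribution=mixture,
        path_probabilities={
            "ivt_no_adverse": w_ivt_no_ae,
            "ivt_adverse": w_ivt_ae,
            "accurate_usual_care": w_acc_uc,
            "inaccurate_usual_care": w_inacc,
        },
        ivt_fraction=p_accurate * p_ivt,
    )


def short_term_expected_ivt_cost(result: NinetyDayResult, ivt_cost: float) -> float:
    """Expected per-person year-1 thrombolysis cost add-on."""
    if ivt_cost < 0:
        raise ValueError(f"ivt_cost must be non-negative, got {ivt_cost}")
    return result.ivt_fraction * ivt_cost
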