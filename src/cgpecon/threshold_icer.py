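"""Exploratory long-term threshold analysis.

In the last-resort setting the comparator is "no further diagnostics"
with zero diagnostic cost, and treatment costs and benefits of patients
without a CGP-matched treatment cancel between the strategies.  The ICER
of CGP versus no diagnostics therefore reduces, per matched treatment, to

    ICER = (diagnostic cost per matched treatment + delta_cost) / delta_qaly

where ``delta_cost`` and ``delta_qaly`` are the incremental treatment
cost and QALY benefit attributed to one CGP-matched treatment.  The
required-QALY solver inverts this at a willingness-to-pay per QALY.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

#: commonly used willingness-to-pay threshold in Belgium, EUR per QALY
WTP_PER_QALY_DEFAULT = 40_000.0


@dataclass(frozen=True)
class IcerPoint:
    delta_cost: float                  # EUR per matched treatment
    delta_qaly: float                  # QALYs per matched treatment
    icer: float | None                 # EUR per QALY; None when delta_qaly <= 0
    diag_cost_per_matched: float

    @property
    def undefined(self) -> bool:
        return self.icer is None


def icer_curve(diag_cost_per_matched: float,
               delta_cost_values: Sequence[float],
               delta_qaly_grid: Sequence[float]) -> list[IcerPoint]:
    """One ICER curve per incremental-cost value, over a QALY-benefit grid."""
    points = []
    for delta_cost in delta_cost_values:
        for delta_qaly in delta_qaly_grid:
            if delta_qaly > 0:
                icer = (diag_cost_per_matched + delta_cost) / delta_qaly
            else:
                icer = None
            points.append(IcerPoint(
                delta_cost=float(delta_cost),
                delta_qaly=float(delta_qaly),
                icer=icer,
                diag_cost_per_matched=diag_cost_per_matched,
            ))
    return points


def required_qaly(diag_cost_per_matched: float, delta_cost: float,
                  wtp_per_qaly: float = WTP_PER_QALY_DEFAULT) -> float:
    """QALY benefit per matched treatment needed for the ICER to equal WTP.

    ``(diag_cost_per_matched + delta_cost) / wtp_per_qaly``; a negative
    numerator (cost savings exceeding diagnostic spend — dominance) is
    reported as 0 with a warning.
    """
    if wtp_per_qaly <= 0:
        raise ValueError(f"wtp_per_qaly must be > 0, got {wtp_per_qaly}")
    numerator = diag_cost_per_matched + delta_cost
    if numerator < 0:
        warnings.warn("negative incremental cost: CGP dominates, no QALY "
                      "benefit required", stacklevel=2)
        return 0.0
    return numerator / wtp_per_qaly
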