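"""Seizure-frequency outcomes and the responder rule.

Clinical response is quantified as the percent reduction in self-reported
seizure frequency relative to the pre-implant baseline, with the current
frequency taken as the average of two follow-up samplings.  Patients with
a reduction of at least 50% are "responders"; all others (including
patients who worsened, i.e. negative reduction) are "non-responders".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

RESPONDER_THRESHOLD_PCT = 50.0


def percent_reduction(baseline: float, followups: float | Sequence[float]) -> float:
    """Percent seizure-frequency reduction; positive means improvement.

    ``followups`` may be a single frequency or several samplings, which
    are averaged (arithmetic mean) before comparison with baseline.  E.g.
    7/wk at baseline falling to 3/wk is a 57.1% reduction.
    """
    if baseline <= 0:
        raise ValueError(f"baseline seizure frequency must be > 0, got {baseline}")
    arr = np.atleast_1d(np.asarray(followups, dtype=float))
    if arr.size < 1:
        raise ValueError("need at least one follow-up sampling")
    current = float(arr.mean())
    return 100.0 * (baseline - current) / baseline


def responder_label(reduction: float, threshold: float = RESPONDER_THRESHOLD_PCT) -> bool:
    """True iff the reduction meets the threshold (boundary inclusive)."""
    if not np.isfinite(reduction):
        raise ValueError(f"reduction must be finite, got {reduction}")
    return bool(reduction >= threshold)


@dataclass
class SubjectOutcome:
    """Per-patient clinical outcome and lead placement."""

    subject_id: str
    baseline_sz_per_wk: float
    followup1_sz_per_wk: float
    followup2_sz_per_wk: float
    lead_hemispheres: tuple[str, ...]
    lead_lobes: tuple[str, ...]
    stim_enabled: bool = True
    concurrent_resection: bool = False

    def __post_init__(self) -> None:
        if self.baseline_sz_per_wk <= 0:
            raise ValueError(
                f"{self.subject_id}: baseline seizure frequency must be > 0"
            )

    @property
    def percent_reduction(self) -> float:
        return percent_reduction(
            self.baseline_sz_per_wk,
            [self.followup1_sz_per_wk, self.followup2_sz_per_wk],
        )

    @property
    def responder(self) -> bool:
        return responder_label(self.percent_reduction)
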