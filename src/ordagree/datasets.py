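"""Built-in example data.

The canonical worked example throughout this package is a published 5 x 5
contingency table of physician-versus-patient ratings on the first item of
the Patient Participation Scale ("I helped my patient to understand all of
the information" / "My doctor helped me to understand all of the
information"), collected after 506 primary-care consultations in the
intervention arm of a shared-decision-making trial.  The scale runs from
1 ("totally agree", most favourable) to 5 ("totally disagree").

The table shows the data signature this package is built around: a strong
ceiling effect (90.5% of patients chose the best category), a small
systematic bias (physicians cluster one category lower), and near-empty
worst categories.  On such data chance-corrected agreement coefficients
collapse toward zero while almost every paired difference is within one
scale point — the "kappa paradox".
"""

from __future__ import annotations

import numpy as np

from .core import ContingencyTable, PairedRatings, RatingScale

__all__ = ["pps_scale", "participation_item1", "participation_item1_pairs"]

PPS_LABELS = (
    "totally agree",
    "agree",
    "neither nor",
    "disagree",
    "totally disagree",
)

# Rows: physician (rater A) category 1..5; columns: patient (rater B).
_ITEM1_COUNTS = np.array(
    [
        [264, 21, 4, 0, 0],
        [184, 16, 3, 1, 1],
        [5, 1, 0, 0, 0],
        [5, 0, 1, 0, 0],
        [0, 0, 0, 0, 0],
    ],
    dtype=np.int64,
)


def pps_scale() -> RatingScale:
    """The 5-point agreement scale used by the participation instrument."""
    return RatingScale(5, PPS_LABELS, lower_is_better=True)


def participation_item1() -> ContingencyTable:
    """Physician x patient contingency table for participation item 1 (n=506)."""
    return ContingencyTable(_ITEM1_COUNTS.copy(), pps_scale(), item_id="item1")


def participation_item1_pairs() -> PairedRatings:
    """The same data expanded to a pair list (encounter order arbitrary)."""
    return participation_item1().to_pairs()
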