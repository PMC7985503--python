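"""Phenotype and derived-environment scoring rules.

The outcome is a 12-item dichotomous neuroticism questionnaire (EPQ-R short
form style) summed to a 0-12 score, complete cases only.  Two kinds of derived
environment are supported: a truncated chronic-pain region count and plain
endorsement counts for multi-option items.  Ordinal environments are mapped to
consecutive integers starting at 0 in their listed level order, then analysed
as continuous downstream.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["neuroticism_sum", "chronic_pain_score", "count_endorsements", "N_ITEMS"]

N_ITEMS = 12

_AGREE = {1, True, "agree"}
_DISAGREE = {0, False, "disagree"}
_MISSING = {None, "missing"}


def _classify(item) -> Optional[int]:
    if isinstance(item, float) and np.isnan(item):
        return None
    if item in _AGREE:
        return 1
    if item in _DISAGREE:
        return 0
    if item in _MISSING:
        return None
    raise ValueError(f"unrecognised item response: {item!r}")


def neuroticism_sum(items: Sequence) -> Optional[int]:
    """Sum of agreed items over 12 dichotomous responses, or None if excluded.

    Responses may be 0/1, booleans, 'agree'/'disagree'/'missing', or NaN.
    Any missing item excludes the respondent (no imputation); the score of a
    complete respondent is the number of agreements, in [0, 12].
    """
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {len(items)}")
    coded = [_classify(it) for it in items]
    if any(c is None for c in coded):
        return None
    return int(sum(coded))


def chronic_pain_score(region_chronic: Sequence[bool], all_over_body: bool) -> int:
    """Truncated count of body regions with pain lasting 3+ months.

    No chronic region and no whole-body pain scores 0; one region 1; two
    regions 2; three or more regions, or pain all over the body, scores 3.
    The cap avoids assuming that many separate regions outweigh whole-body
    pain.  Returns an integer in {0, 1, 2, 3}.
    """
    n = int(sum(bool(r) for r in region_chronic))
    if all_over_body:
        return 3
    return min(n, 3)


def count_endorsements(option_flags: Sequence[bool], none_flag: bool = False) -> int:
    """Number of endorsed substantive options on a multi-option item.

    Endorsing 'none of the above' scores 0; co-endorsing it together with a
    substantive option is contradictory and rejected rather than silently
    resolved.
    """
    n = int(sum(bool(f) for f in option_flags))
    if none_flag:
        if n:
            raise ValueError("'none of the above' co-endorsed with options")
        return 0
    return n
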