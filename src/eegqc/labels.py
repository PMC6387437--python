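"""Quality-label vocabulary shared across the package.

Segments are graded on a three-level scale (low / medium / high quality);
medium-quality segments whose contamination is of muscular (EMG) origin carry
the refined label ``MED_MUSC``.  For the three-class classifiers, ``MED_MUSC``
is folded into ``MED_Q``; the muscular refinement re-splits it afterwards.
"""

from __future__ import annotations

LOW_Q = "LOW_Q"
MED_Q = "MED_Q"
MED_MUSC = "MED_MUSC"
HIGH_Q = "HIGH_Q"

#: The three coarse classes seen by the classifiers, ordered worst → best.
#: This ordering defines tie-breaking: ties resolve toward the worse quality,
#: so ambiguous segments are flagged rather than passed downstream.
CLASS_ORDER = (LOW_Q, MED_Q, HIGH_Q)

ALL_LABELS = (LOW_Q, MED_Q, MED_MUSC, HIGH_Q)

#: Rank used for worse-quality tie-breaking (lower = worse).
_QUALITY_RANK = {LOW_Q: 0, MED_Q: 1, MED_MUSC: 1, HIGH_Q: 2}


def coarse_label(label: str) -> str:
    """Map a 4-level label onto the 3-level classifier vocabulary.

    ``MED_MUSC`` is a refinement of ``MED_Q``: every muscular segment is also
    a medium-quality segment.
    """
    if label == MED_MUSC:
        return MED_Q
    if label not in ALL_LABELS:
        raise ValueError(f"unknown quality label: {label!r}")
    return label


def worst_of(candidates) -> str:
    """Return the worst-quality label among *candidates* (conservative tie rule)."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate labels")
    return min(candidates, key=lambda c: (_QUALITY_RANK[c], CLASS_ORDER.index(coarse_label(c))))
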