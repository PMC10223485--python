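"""Event-class alphabet shared by every stage of the pipeline.

Blocks of waist-worn IMU data are classified into one of three events:
daily-living activity (non-fall), a hazardous transition that may end in a
fall (pre-fall), and the fall itself.  The integer values are fixed because
they index the per-class ensemble sub-models and the metric tables.
"""

from __future__ import annotations

from enum import IntEnum


class ClassLabel(IntEnum):
    NON_FALL = 0
    PRE_FALL = 1
    FALL = 2


#: Tie-break order used both for block labeling and score fusion: a missed
#: fall is costlier than a false alarm, so the more severe event wins ties.
DEFAULT_TIE_BREAK: tuple[ClassLabel, ...] = (
    ClassLabel.FALL,
    ClassLabel.PRE_FALL,
    ClassLabel.NON_FALL,
)

N_CLASSES = len(ClassLabel)


def validate_labels(values) -> None:
    """Raise ``ValueError`` if any entry is outside the 3-class alphabet."""
    import numpy as np

    arr = np.asarray(values)
    if arr.size and (arr.min() < 0 or arr.max() > max(ClassLabel)):
        bad = arr[(arr < 0) | (arr > max(ClassLabel))][0]
        raise ValueError(
            f"label value {bad} outside the class alphabet "
            f"{{{', '.join(str(int(c)) for c in ClassLabel)}}}"
        )
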