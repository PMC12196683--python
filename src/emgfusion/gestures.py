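"""The seven-gesture vocabulary used throughout the package.

The gestures cover fundamental activities of daily living relevant to
subacute stroke rehabilitation: a resting baseline, whole-hand grasp,
wrist flexion/extension, hand opening, and two fine movements (index
pinch and thumbs up). Class order is fixed and defines the integer
label space of the classifier.
"""

from enum import Enum


class Gesture(str, Enum):
    REST = "rest"
    FIST = "fist"
    INDEX_PINCH = "index_pinch"
    WRIST_FLEXION = "wrist_flexion"
    WRIST_EXTENSION = "wrist_extension"
    FINGERS_OPENING = "fingers_opening"
    THUMBS_UP = "thumbs_up"


#: Canonical class order; index in this tuple is the integer label.
GESTURES: tuple[Gesture, ...] = tuple(Gesture)

#: gesture -> integer label
GESTURE_INDEX: dict[Gesture, int] = {g: i for i, g in enumerate(GESTURES)}


def as_gesture(value) -> Gesture:
    """Coerce a string or Gesture to a Gesture, with a helpful error."""
    if isinstance(value, Gesture):
        return value
    try:
        return Gesture(value)
    except ValueError:
        raise ValueError(f"unknown gesture {value!r}; expected one of "
                         f"{[g.value for g in GESTURES]}") from None
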