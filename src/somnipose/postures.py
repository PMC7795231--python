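"""Posture label vocabulary shared across the pipeline.

The five gross body orientations recognised by the system. The enum order
is the fixed class order used everywhere a deterministic tie-break over
classes is needed (vote ties, majority ties in forests).
"""

from __future__ import annotations

import enum


class PostureLabel(enum.Enum):
    """Gross body posture during a monitoring session."""

    STAND = "Stand"
    SUPINE = "Supine"
    RIGHT_LATERAL = "RightLateral"
    LEFT_LATERAL = "LeftLateral"
    PRONE = "Prone"

    def __str__(self) -> str:  # serialised form used in CSV outputs
        return self.value

    @classmethod
    def from_string(cls, s: str) -> "PostureLabel":
        for member in cls:
            if member.value == s:
                return member
        raise ValueError(f"unknown posture label: {s!r}")


#: Fixed class order (tie-break priority: earlier wins).
CLASS_ORDER: tuple[PostureLabel, ...] = (
    PostureLabel.STAND,
    PostureLabel.SUPINE,
    PostureLabel.RIGHT_LATERAL,
    PostureLabel.LEFT_LATERAL,
    PostureLabel.PRONE,
)

#: Index of each class in the fixed order.
CLASS_INDEX: dict[PostureLabel, int] = {c: i for i, c in enumerate(CLASS_ORDER)}

#: Postures that correspond to lying in bed (everything except standing).
LYING_POSTURES: tuple[PostureLabel, ...] = tuple(
    c for c in CLASS_ORDER if c is not PostureLabel.STAND
)
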