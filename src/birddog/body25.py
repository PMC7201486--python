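"""BODY_25 keypoint conventions and trial-side bookkeeping.

The BODY_25 landmark set is the 25-point body model emitted by the OpenPose
pose estimator: one (x, y, confidence) triplet per landmark, indexed in a
fixed order.  The bird-dog task lifts one arm and the contralateral leg, so
which wrist/elbow/ankle/knee belong to the *extended* limbs depends on the
trial side.
"""
from __future__ import annotations

import enum

#: Landmark names in BODY_25 index order.
KEYPOINT_NAMES: tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip",
    "RHip", "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar",
    "LBigToe", "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

N_KEYPOINTS = 25

NOSE = 0
NECK = 1
R_SHOULDER, R_ELBOW, R_WRIST = 2, 3, 4
L_SHOULDER, L_ELBOW, L_WRIST = 5, 6, 7
MID_HIP = 8
R_HIP, R_KNEE, R_ANKLE = 9, 10, 11
L_HIP, L_KNEE, L_ANKLE = 12, 13, 14


class Side(str, enum.Enum):
    """Which arm is lifted; the lifted leg is always contralateral."""

    LEFT_EXTENDED = "left_extended"
    RIGHT_EXTENDED = "right_extended"

    @classmethod
    def parse(cls, value: "Side | str") -> "Side":
        if isinstance(value, Side):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown side {value!r}; expected 'left_extended' or 'right_extended'"
            ) from None


def extended_keypoints(side: Side | str) -> dict[str, int]:
    """BODY_25 indices of the lifted arm's wrist/elbow and the lifted leg's ankle/knee."""
    side = Side.parse(side)
    if side is Side.LEFT_EXTENDED:
        return {"wrist": L_WRIST, "elbow": L_ELBOW, "ankle": R_ANKLE, "knee": R_KNEE}
    return {"wrist": R_WRIST, "elbow": R_ELBOW, "ankle": L_ANKLE, "knee": L_KNEE}


def supporting_keypoints(side: Side | str) -> dict[str, int]:
    """BODY_25 indices of the weight-bearing wrist and ankle (floor contacts)."""
    side = Side.parse(side)
    if side is Side.LEFT_EXTENDED:
        return {"wrist": R_WRIST, "ankle": L_ANKLE}
    return {"wrist": L_WRIST, "ankle": R_ANKLE}
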