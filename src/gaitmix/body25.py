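"""BODY_25 keypoint index constants and side lookups.

The 25-point skeleton produced by markerless pose estimation (nose,
neck, shoulders, elbows, wrists, hips, knees, ankles, eyes, ears, toes
and heels).  Indices follow the standard BODY_25 ordering.
"""

from __future__ import annotations

NOSE = 0
NECK = 1
R_SHOULDER = 2
R_ELBOW = 3
R_WRIST = 4
L_SHOULDER = 5
L_ELBOW = 6
L_WRIST = 7
MID_HIP = 8
R_HIP = 9
R_KNEE = 10
R_ANKLE = 11
L_HIP = 12
L_KNEE = 13
L_ANKLE = 14
R_EYE = 15
L_EYE = 16
R_EAR = 17
L_EAR = 18
L_BIG_TOE = 19
L_SMALL_TOE = 20
L_HEEL = 21
R_BIG_TOE = 22
R_SMALL_TOE = 23
R_HEEL = 24

N_KEYPOINTS = 25

#: joints used by the sagittal feature set, per camera-facing side
SIDE_JOINTS = {
    "right": {
        "shoulder": R_SHOULDER,
        "elbow": R_ELBOW,
        "wrist": R_WRIST,
        "hip": R_HIP,
        "knee": R_KNEE,
        "ankle": R_ANKLE,
        "big_toe": R_BIG_TOE,
        "small_toe": R_SMALL_TOE,
        "heel": R_HEEL,
        "ear": R_EAR,
        "eye": R_EYE,
    },
    "left": {
        "shoulder": L_SHOULDER,
        "elbow": L_ELBOW,
        "wrist": L_WRIST,
        "hip": L_HIP,
        "knee": L_KNEE,
        "ankle": L_ANKLE,
        "big_toe": L_BIG_TOE,
        "small_toe": L_SMALL_TOE,
        "heel": L_HEEL,
        "ear": L_EAR,
        "eye": L_EYE,
    },
}

#: midline points used regardless of camera side
CENTRAL_POINTS = (NOSE, NECK, MID_HIP)


def required_points(side: str) -> tuple[int, ...]:
    """Keypoints that must pass the confidence filter for a usable frame."""
    j = SIDE_JOINTS[side]
    return CENTRAL_POINTS + (
        j["shoulder"],
        j["elbow"],
        j["wrist"],
        j["hip"],
        j["knee"],
        j["ankle"],
        j["big_toe"],
        j["heel"],
        j["ear"],
    )
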