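"""Single source of truth for the package's physical and labelling conventions.

Channel order
    Every 3-channel array is ordered ``(0°, 45°, 90°)`` sensing units; CSV
    columns are ``t,ch0,ch45,ch90``. The 0° unit lies along the horizontal
    (medio-lateral) axis of the eyelid, the 90° unit along the vertical axis.

Sign conventions (eyelid compression -> negative ΔR/R)
    * upward gaze compresses the upper eyelid  -> negative 90°-unit signal
    * downward gaze stretches it               -> positive 90°-unit signal
    * adduction (gaze toward the nose)         -> negative 0°-unit signal
    * abduction (gaze away from the nose)      -> positive 0°-unit signal

    Spatial left/right therefore map to the 0°-unit sign through the side of
    the sensed eye: for a *right* eye, gazing right is abduction (positive),
    for a *left* eye it is adduction (negative).

Angles are degrees everywhere; ΔR/R and strain are dimensionless fractions.
"""

CHANNEL_NAMES = ("ch0", "ch45", "ch90")
CH0, CH45, CH90 = 0, 1, 2

#: Gaze angle (degrees) at which a direction prior's ``max_eyelid_strain`` is
#: reached; the biomechanical strain law is linear in angle up to here and is
#: extrapolated linearly for 18°–20°.
REFERENCE_MAX_ANGLE_DEG = 18.0

#: Hard ceiling on simulated gaze amplitude (degrees).
MAX_GAZE_ANGLE_DEG = 20.0

DEFAULT_SAMPLING_RATE = 50.0

DIRECTIONS_4 = ("up", "down", "right", "left")
DIRECTIONS_8 = (
    "up", "down", "right", "left",
    "up_left", "up_right", "down_left", "down_right",
)

#: Event kinds that are not gaze movements; the classifier folds both into a
#: single ninth category that routes to no angle regressor.
ARTIFACT_KINDS = ("blink", "expression")
ARTIFACT_CLASS = "blink_expression"

EYES = ("left", "right")


def fellow_eye(eye: str) -> str:
    if eye not in EYES:
        raise ValueError(f"unknown eye {eye!r}; expected one of {EYES}")
    return "left" if eye == "right" else "right"


def event_class(direction: str) -> str:
    """Map an annotated event direction/kind to its classifier label."""
    return ARTIFACT_CLASS if direction in ARTIFACT_KINDS else direction
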