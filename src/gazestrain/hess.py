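"""Digitized Hess screen test: chart geometry, per-position deviation
measurement, the symmetry/size/position diagnosis rules, and cover–uncover
interpretation.

Coordinates are gaze angles in degrees: +x toward the patient's right,
+y upward. Nasal/temporal resolve through the eye side: for the right eye the
nose is on its left (-x), for the left eye on its right (+x). The chart uses
the 3x3 grid of cardinal positions at 0°/±15°; on the physical screen one
5° grid square corresponds to 0.5 m viewing distance via a tangent projection.

Diagnosis follows the clinical symmetry / size / position reading of paired
charts:

1. *symmetry*: a chart-area ratio below a threshold marks paralytic strabismus;
2. *size*: the smaller chart belongs to the paretic eye;
3. *position*: the mean measured-minus-target shift of the deviating eye maps
   to eso/exo (nasal/temporal) and hyper/hypo deviations;
4. the extraocular muscle whose action field contains the position of maximal
   underaction on the paretic eye is implicated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CH0, CH90, fellow_eye
from .simulate import StrainRecording

__all__ = [
    "HessGeometry",
    "GazePointEstimate",
    "HessChart",
    "DiagnosisThresholds",
    "DiagnosisReport",
    "TropiaInference",
    "POSITION_DIRECTIONS",
    "position_targets",
    "angle_to_screen",
    "screen_to_angle",
    "build_hess_chart",
    "chart_area",
    "diagnose",
    "cover_uncover_interpret",
    "muscle_for_position",
    "synthetic_palsy_chart",
    "mirror_chart",
    "MUSCLES",
]

MUSCLES = (
    "medial rectus",
    "lateral rectus",
    "superior rectus",
    "inferior rectus",
    "superior oblique",
    "inferior oblique",
)

#: position_id -> direction label; id 1 is central fixation, 2–9 sweep the
#: outer ring clockwise from straight up.
POSITION_DIRECTIONS = {
    1: "center",
    2: "up",
    3: "up_right",
    4: "right",
    5: "down_right",
    6: "down",
    7: "down_left",
    8: "left",
    9: "up_left",
}

_UNIT_VECTORS = {
    "center": (0.0, 0.0),
    "up": (0.0, 1.0),
    "up_right": (1.0, 1.0),
    "right": (1.0, 0.0),
    "down_right": (1.0, -1.0),
    "down": (0.0, -1.0),
    "down_left": (-1.0, -1.0),
    "left": (-1.0, 0.0),
    "up_left": (-1.0, 1.0),
}


@dataclass(frozen=True)
class HessGeometry:
    """Screen geometry: tangent projection at a fixed viewing distance."""

    viewing_distance_m: float = 0.5
    grid_step_deg: float = 5.0
    inner_field_half_width_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.viewing_distance_m <= 0:
            raise ValueError("viewing distance must be > 0")
        if self.grid_step_deg <= 0:
            raise ValueError("grid step must be > 0")


def position_targets(geometry: HessGeometry | None = None) -> dict[int, tuple[float, float]]:
    """Target gaze (horizontal°, vertical°) for the nine cardinal positions."""
    geometry = geometry or HessGeometry()
    e = geometry.inner_field_half_width_deg
    return {
        pid: (ux * e, uy * e)
        for pid, name in POSITION_DIRECTIONS.items()
        for ux, uy in [_UNIT_VECTORS[name]]
    }


def angle_to_screen(horizontal_deg: float, vertical_deg: float,
                    geometry: HessGeometry | None = None) -> tuple[float, float]:
    """Tangent projection of a gaze angle onto the screen plane (meters)."""
    geometry = geometry or HessGeometry()
    if max(abs(horizontal_deg), abs(vertical_deg)) >= 90.0:
        raise ValueError("gaze angles must be below 90 degrees")
    d = geometry.viewing_distance_m
    return (d * math.tan(math.radians(horizontal_deg)),
            d * math.tan(math.radians(vertical_deg)))


def screen_to_angle(x_m: float, y_m: float,
                    geometry: HessGeometry | None = None) -> tuple[float, float]:
    geometry = geometry or HessGeometry()
    d = geometry.viewing_distance_m
    return (math.degrees(math.atan2(x_m, d)), math.degrees(math.atan2(y_m, d)))


@dataclass
class GazePointEstimate:
    position_id: int
    target_deg: tuple[float, float]
    measured_deg: tuple[float, float]
    n_repeats: int = 1
    dispersion_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.measured_deg).all() and np.isfinite(self.target_deg).all()):
            raise ValueError("gaze estimates must be finite")


@dataclass
class HessChart:
    """Per-eye measured gaze at the nine cardinal positions."""

    eye: str
    points: list[GazePointEstimate]
    geometry: HessGeometry = field(default_factory=HessGeometry)
    fixating_eye: str | None = None

    def __post_init__(self) -> None:
        if self.fixating_eye is None:
            self.fixating_eye = fellow_eye(self.eye)
        ids = sorted(p.position_id for p in self.points)
        if ids != list(range(1, 10)):
            raise ValueError("a Hess chart requires exactly the 9 cardinal positions")
        targets = position_targets(self.geometry)
        for p in self.points:
            if tuple(p.target_deg) != targets[p.position_id]:
                raise ValueError(
                    f"position {p.position_id} target {p.target_deg} does not match "
                    f"the {self.geometry.inner_field_half_width_deg}° grid"
                )

    def point(self, position_id: int) -> GazePointEstimate:
        return next(p for p in self.points if p.position_id == position_id)


def build_hess_chart(
    measurements: dict[int, list[tuple[float, float]]],
    eye: str,
    geometry: HessGeometry | None = None,
    fixating_eye: str | None = None,
) -> HessChart:
    """Average repeated decoded gaze points into one chart.

    ``measurements`` maps position_id (1–9) to >= 1 decoded (h°, v°) repeats;
    the measured point is their arithmetic mean and the dispersion the RMS
    distance to it.
    """
    geometry = geometry or HessGeometry()
    if sorted(measurements) != list(range(1, 10)):
        missing = sorted(set(range(1, 10)) - set(measurements))
        raise ValueError(f"chart requires all 9 positions; missing {missing}")
    targets = position_targets(geometry)
    points = []
    for pid in range(1, 10):
        reps = np.asarray(measurements[pid], dtype=float).reshape(-1, 2)
        if reps.shape[0] < 1:
            raise ValueError(f"position {pid} has no repeats")
        mean = reps.mean(axis=0)
        disp = float(np.sqrt(((reps - mean) ** 2).sum(axis=1).mean()))
        points.append(
            GazePointEstimate(
                position_id=pid,
                target_deg=targets[pid],
                measured_deg=(float(mean[0]), float(mean[1])),
                n_repeats=reps.shape[0],
                dispersion_deg=disp,
            )
        )
    return HessChart(eye=eye, points=points, geometry=geometry, fixating_eye=fixating_eye)


def chart_area(chart: HessChart) -> float:
    """Shoelace area (deg²) of the 8 outer measured points ordered by bearing."""
    pts = np.array([chart.point(pid).measured_deg for pid in range(2, 10)])
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


# ---------------------------------------------------------------------------
# diagnosis rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosisThresholds:
    """Numeric thresholds behind the symmetry/size/position judgement."""

    area_ratio: float = 0.85
    shift_deg: float = 2.0
    underaction_deg: float = 2.0


@dataclass
class DiagnosisReport:
    paralytic: bool
    paretic_eye: str | None
    horizontal_deviation: str  # eso | exo | none
    vertical_deviation: str  # hyper | hypo | none
    implicated_muscles: list[str]
    metrics: dict

    def __post_init__(self) -> None:
        if self.paralytic != bool(self.implicated_muscles):
            raise ValueError("implicated muscles must be non-empty iff paralytic")


@dataclass
class TropiaInference:
    tropia_present: bool
    deviating_eye: str | None
    deviation_type: str  # eso | exo | hyper | hypo | none
    fixating_eye: str | None

    def __post_init__(self) -> None:
        if (self.deviation_type == "none") == self.tropia_present:
            raise ValueError("deviation_type must be none iff no tropia")


#: Action field of each muscle per eye, keyed by outer-position direction.
#: Pure elevation/depression are assigned to the vertical recti (their field
#: spans the vertical midline); the obliques own the adducted vertical corners.
def muscle_for_position(direction: str, eye: str) -> str:
    nasal_x = -1.0 if eye == "right" else 1.0  # sign of x toward the nose
    ux, uy = _UNIT_VECTORS[direction]
    if uy == 0:
        return "medial rectus" if ux * nasal_x > 0 else "lateral rectus"
    adducted = ux * nasal_x > 0
    if uy > 0:
        return "inferior oblique" if adducted else "superior rectus"
    return "superior oblique" if adducted else "inferior rectus"


def _mean_shift(chart: HessChart) -> np.ndarray:
    diffs = [
        np.subtract(p.measured_deg, p.target_deg) for p in chart.points
    ]
    return np.mean(diffs, axis=0)


def _underactions(chart: HessChart) -> dict[str, float]:
    """Projected shortfall of the measured excursion toward each outer target."""
    out = {}
    for pid in range(2, 10):
        p = chart.point(pid)
        t = np.asarray(p.target_deg, dtype=float)
        t_norm = np.linalg.norm(t)
        that = t / t_norm
        out[POSITION_DIRECTIONS[pid]] = float(t_norm - np.dot(p.measured_deg, that))
    return out


def _horizontal_label(shift_x: float, eye: str) -> str:
    nasal_x = -1.0 if eye == "right" else 1.0
    return "eso" if shift_x * nasal_x > 0 else "exo"


def diagnose(
    left: HessChart,
    right: HessChart,
    thresholds: DiagnosisThresholds | None = None,
) -> DiagnosisReport:
    """Symmetry / size / position reading of a paired Hess chart."""
    thresholds = thresholds or DiagnosisThresholds()
    if left.eye != "left" or right.eye != "right":
        raise ValueError("charts must be passed as (left, right)")
    if left.geometry != right.geometry:
        raise ValueError("charts must share the same geometry")

    area_left, area_right = chart_area(left), chart_area(right)
    ratio = min(area_left, area_right) / max(area_left, area_right)
    paralytic = ratio < thresholds.area_ratio
    if paralytic:
        paretic_eye = "left" if area_left < area_right else "right"
        deviating = left if paretic_eye == "left" else right
    else:
        paretic_eye = None
        shifts = {"left": _mean_shift(left), "right": _mean_shift(right)}
        deviating_eye = max(shifts, key=lambda e: float(np.linalg.norm(shifts[e])))
        deviating = left if deviating_eye == "left" else right

    shift = _mean_shift(deviating)
    horizontal = (
        _horizontal_label(shift[0], deviating.eye)
        if abs(shift[0]) >= thresholds.shift_deg
        else "none"
    )
    vertical = (
        ("hyper" if shift[1] > 0 else "hypo")
        if abs(shift[1]) >= thresholds.shift_deg
        else "none"
    )

    under = _underactions(deviating)
    ranked = sorted(under.items(), key=lambda kv: kv[1], reverse=True)
    muscles = []
    if paralytic:
        muscles = [muscle_for_position(ranked[0][0], paretic_eye)]

    metrics = {
        "area_left_deg2": area_left,
        "area_right_deg2": area_right,
        "area_ratio": ratio,
        "mean_shift_deg": (float(shift[0]), float(shift[1])),
        "deviating_eye": deviating.eye,
        "underactions_deg": dict(ranked),
        "max_underaction_deg": ranked[0][1],
        "max_underaction_position": ranked[0][0],
    }
    return DiagnosisReport(
        paralytic=paralytic,
        paretic_eye=paretic_eye,
        horizontal_deviation=horizontal,
        vertical_deviation=vertical,
        implicated_muscles=muscles,
        metrics=metrics,
    )


# ---------------------------------------------------------------------------
# cover–uncover interpretation
# ---------------------------------------------------------------------------

def cover_uncover_interpret(
    recording: StrainRecording,
    cover_intervals: list[tuple[float, float]],
    sensed_eye: str,
    threshold: float = 0.0015,
    smooth_seconds: float = 0.25,
) -> TropiaInference:
    """Latent-deviation reading of a (filtered) recording of the sensed eye.

    A sustained directional deflection that begins within a covered interval
    and resolves at uncover reveals the refixation movement: abduction of the
    sensed eye means esotropia, adduction exotropia, a downward movement
    hypertropia, an upward movement hypotropia. The fixating eye is the
    covered fellow eye. The signal is smoothed over ``smooth_seconds`` before
    thresholding so single noise samples cannot trigger a detection; the
    default threshold sits below the smallest sustained deflection of interest
    (a downward refixation, capped at 4 % eyelid strain).
    """
    if not cover_intervals:
        raise ValueError("at least one cover interval is required")
    t = recording.time
    fs = recording.sampling_rate
    win = max(1, int(round(smooth_seconds * fs)))
    kernel = np.ones(win) / win
    smoothed = np.apply_along_axis(
        lambda ch: np.convolve(ch, kernel, mode="same"), 1, recording.channels
    )
    for t0, t1 in cover_intervals:
        if t0 < t[0] or t1 > t[-1] or t1 <= t0:
            raise ValueError(f"cover interval ({t0}, {t1}) outside recording span")
        mask = (t >= t0) & (t <= t1)
        seg = smoothed[:, mask]
        extrema = seg[np.arange(3), np.abs(seg).argmax(axis=1)]
        e0, e90 = extrema[CH0], extrema[CH90]
        if max(abs(e0), abs(e90)) < threshold:
            continue
        # resolved after uncover? compare a short post-interval window
        post = smoothed[:, (t > t1) & (t <= min(t1 + 1.0, t[-1]))]
        if post.size and np.abs(post).max() > 0.8 * max(abs(e0), abs(e90)):
            continue
        if abs(e0) >= abs(e90):
            abducting = e0 > 0
            deviation = "eso" if abducting else "exo"
        else:
            deviation = "hyper" if e90 > 0 else "hypo"  # moved down -> hyper
        return TropiaInference(
            tropia_present=True,
            deviating_eye=sensed_eye,
            deviation_type=deviation,
            fixating_eye=fellow_eye(sensed_eye),
        )
    return TropiaInference(
        tropia_present=False, deviating_eye=None, deviation_type="none",
        fixating_eye=None,
    )


# ---------------------------------------------------------------------------
# synthetic reference patterns
# ---------------------------------------------------------------------------

#: For each palsied muscle: (primary underaction direction as seen in
#: oculomotor terms, secondary directions, resting deviation of the eye).
#: "nasal"/"temporal" and adduction resolve through the eye side at build time.
_PALSY_PATTERNS = {
    "medial rectus": (("adduction", 0.0), ["up_add", "down_add"], ("temporal", 0.0)),
    "lateral rectus": (("abduction", 0.0), ["up_abd", "down_abd"], ("nasal", 0.0)),
    "superior rectus": (("up_abd", 0.0), ["up"], (None, -1.0)),
    "inferior rectus": (("down_abd", 0.0), ["down"], (None, 1.0)),
    "superior oblique": (("down_add", 0.0), ["down"], (None, 1.0)),
    "inferior oblique": (("up_add", 0.0), ["up"], (None, -1.0)),
}


def _resolve_direction(token: str, eye: str) -> str:
    nasal = "left" if eye == "right" else "right"
    temporal = fellow_eye(nasal)
    mapping = {
        "adduction": nasal,
        "abduction": temporal,
        "up": "up",
        "down": "down",
        "up_add": f"up_{nasal}",
        "up_abd": f"up_{temporal}",
        "down_add": f"down_{nasal}",
        "down_abd": f"down_{temporal}",
    }
    return mapping[token]


def synthetic_palsy_chart(
    muscle: str,
    eye: str = "right",
    severity_deg: float = 8.0,
    shift_deg: float = 4.0,
    geometry: HessGeometry | None = None,
) -> tuple[HessChart, HessChart]:
    """Synthetic paired charts emulating a typical single-muscle palsy.

    Returns ``(left_chart, right_chart)``; the fellow eye is on target. The
    paretic chart combines a global resting shift opposite the palsied
    muscle's action with a graded excursion shortfall (full at the muscle's
    primary action field, half at adjacent secondary fields, 20 % elsewhere).
    """
    if muscle not in MUSCLES:
        raise ValueError(f"unknown muscle {muscle!r}")
    geometry = geometry or HessGeometry()
    targets = position_targets(geometry)
    (primary_tok, _), secondary_toks, (shift_tok, shift_y) = _PALSY_PATTERNS[muscle]
    primary = _resolve_direction(primary_tok, eye)
    secondary = {_resolve_direction(tok, eye) for tok in secondary_toks}
    if shift_tok is not None:
        nasal_x = -1.0 if eye == "right" else 1.0
        sx = -nasal_x if shift_tok == "temporal" else nasal_x
        shift = np.array([sx * shift_deg, 0.0])
    else:
        shift = np.array([0.0, shift_y * shift_deg])

    measurements = {}
    for pid, name in POSITION_DIRECTIONS.items():
        target = np.asarray(targets[pid], dtype=float)
        measured = target + shift
        if name != "center":
            w = 1.0 if name == primary else (0.5 if name in secondary else 0.2)
            that = target / np.linalg.norm(target)
            measured = measured - w * severity_deg * that
        measurements[pid] = [tuple(measured)]
    paretic = build_hess_chart(measurements, eye=eye, geometry=geometry)
    fellow = build_hess_chart(
        {pid: [targets[pid]] for pid in range(1, 10)},
        eye=fellow_eye(eye),
        geometry=geometry,
    )
    return (fellow, paretic) if eye == "right" else (paretic, fellow)


def mirror_chart(chart: HessChart) -> HessChart:
    """Left-right mirror: negate horizontal coordinates and swap eye labels."""
    targets = position_targets(chart.geometry)
    mirrored_pid = {}
    for pid, name in POSITION_DIRECTIONS.items():
        ux, uy = _UNIT_VECTORS[name]
        flipped = (-ux, uy)
        mirrored_pid[pid] = next(
            q for q, qname in POSITION_DIRECTIONS.items() if _UNIT_VECTORS[qname] == flipped
        )
    points = []
    for p in chart.points:
        q = mirrored_pid[p.position_id]
        points.append(
            GazePointEstimate(
                position_id=q,
                target_deg=targets[q],
                measured_deg=(-p.measured_deg[0], p.measured_deg[1]),
                n_repeats=p.n_repeats,
                dispersion_deg=p.dispersion_deg,
            )
        )
    return HessChart(
        eye=fellow_eye(chart.eye),
        points=sorted(points, key=lambda p: p.position_id),
        geometry=chart.geometry,
        fixating_eye=chart.eye,
    )
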