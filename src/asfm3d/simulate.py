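"""Synthetic facial-motion sessions and patient cohorts with known truth.

The session simulator emulates what the capture hardware delivers: 21 facial
markers plus 4 helmet markers sampled at 30 Hz, a rest block followed by the
five standard expressions, controllable unilateral weakness, optional rigid
head motion, and Gaussian marker jitter. Every quantity the scoring pipeline
later estimates (per-expression amplitudes, peak speeds, attenuation of the
paralyzed side, resting ratios) is available as closed-form ground truth, so
pipeline tests never rely on hand-derived constants.

Each expression moves its analyzed landmark pair along a raised-cosine bump
d(t) = (A/2)(1 − cos 2πt/T): displacement returns to zero with zero
endpoint velocity, the peak displacement is A and the peak speed is πA/T.
The paralyzed-side amplitude is (1 − severity) × the contralateral one, so
the true distance and speed symmetry ratios both equal 1 − severity.

The default marker-jitter level (0.10 mm per axis) keeps the induced
velocity error of the default smoothing filter within the hardware's stated
maximal dynamic error of 5.8 mm/s; see docs/methods.md for the calibration.
The default expression amplitudes are physiologic plausibility values, not
measured ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ValidationError
from .io import REST, ExpressionSegment, TrajectorySet
from .landmarks import Expression, Side, default_protocol, default_scheme
from .prognosis import LinearPrognosticModel, RecoveryCriteria, classify_recovery
from .io import ClinicalRecord

# nominal rest geometry (mm): +x subject-right, +y superior, +z anterior
_RIGHT_FACE = {
    "A": (70.0, 0.0, -20.0),
    "B": (30.0, 55.0, 45.0),
    "C": (32.0, 35.0, 48.0),
    "D": (32.0, 25.0, 48.0),
    "E": (45.0, 30.0, 40.0),
    "F": (18.0, 30.0, 45.0),
    "G": (18.0, -5.0, 55.0),
    "H": (25.0, -35.0, 48.0),
}
_MIDLINE_FACE = {
    "I": (0.0, -15.0, 60.0),
    "J": (0.0, 50.0, 52.0),
    "K": (0.0, 20.0, 58.0),
    "II": (0.0, -25.0, 58.0),
    "III": (0.0, -45.0, 52.0),
}
#: rigid asymmetric tetrahedron well away from the face plane
_HELMET = {
    "HM1": (80.0, 70.0, -40.0),
    "HM2": (-75.0, 82.0, -48.0),
    "HM3": (6.0, 96.0, -82.0),
    "HM4": (12.0, 112.0, -12.0),
}

#: per-expression motion of the analyzed right-side landmark: unit direction
#: (mirrored in x for the left partner) — amplitudes live in the config
_DIRECTIONS = {
    Expression.BROW_ELEVATION: (0.0, 1.0, 0.0),        # brow up
    Expression.EYE_CLOSURE: (0.0, -1.0, 0.1),          # upper lid down
    Expression.SNARL: (0.1, 1.0, 0.0),                 # ala up
    Expression.OPEN_MOUTH_SMILE: (0.8, 0.6, 0.0),      # mouth corner up-out
    Expression.LIP_PUCKER: (-0.9, 0.1, 0.4),           # mouth corner medial-forward
}

DEFAULT_AMPLITUDES_MM = {
    Expression.BROW_ELEVATION: 8.0,   # brow
    Expression.EYE_CLOSURE: 10.0,     # eyelid
    Expression.SNARL: 6.0,            # ala of the nose
    Expression.OPEN_MOUTH_SMILE: 12.0,  # mouth corner
    Expression.LIP_PUCKER: 12.0,        # mouth corner
}


@dataclass(frozen=True)
class HeadMotion:
    """Rigid sinusoidal head movement applied to every marker."""

    rotation_deg: float = 0.0  # amplitude about the vertical axis
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frequency_hz: float = 0.4

    @property
    def enabled(self) -> bool:
        return self.rotation_deg != 0.0 or any(self.translation_mm)


@dataclass(frozen=True)
class SimulationConfig:
    severity: float = 0.0  # 0 healthy … 1 complete unilateral palsy
    paralyzed_side: Side = Side.RIGHT
    frame_rate: float = 30.0
    rest_duration_s: float = 1.0
    expression_duration_s: float = 2.0
    amplitudes_mm: dict[Expression, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES_MM)
    )
    head_motion: HeadMotion = HeadMotion()
    noise_sd_mm: float = 0.10
    #: desired right/left ratio per resting parameter (1.0 = symmetric)
    resting_ratios: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValidationError(f"severity must be in [0,1], got {self.severity}")
        if self.noise_sd_mm < 0:
            raise ValidationError("noise_sd_mm must be ≥ 0")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")


@dataclass(frozen=True)
class SessionTruth:
    """Closed-form ground truth behind a simulated session (pre-noise)."""

    severity: float
    distance_sr: float  # true SR of every expression: 1 − severity
    speed_sr: float
    peak_speed_mm_s: dict[Expression, float]  # contralateral side, πA/T
    resting_ratios: dict[str, float]


def _apply_resting_ratios(face: dict[str, np.ndarray], ratios: dict[str, float]) -> None:
    """Perturb right-side rest geometry to hit requested right/left ratios.

    Moves are ordered so each target is met exactly: G along I→G (G–I), then
    H along G→H (G–H), then E along H→E (E–H), and finally D placed in the
    C/E/D plane to satisfy both |CD| and ∠CED simultaneously.
    """
    from .scoring import RESTING_PARAMETER_NAMES, _angle_deg

    unknown = set(ratios) - set(RESTING_PARAMETER_NAMES)
    if unknown:
        raise ValidationError(f"unknown resting parameters: {sorted(unknown)}")

    def left_of(lab: str) -> np.ndarray:
        return face[lab.lower()] if lab not in ("I",) else face["I"]

    def move_along(target: str, anchor: str, name: str):
        r = ratios.get(name, 1.0)
        left_dist = float(np.linalg.norm(left_of(target) - left_of(anchor)))
        u = face[target] - face[anchor]
        n = np.linalg.norm(u)
        if n < 1e-9:
            raise DegenerateGeometryError(f"{name}: coincident anchor points")
        face[target] = face[anchor] + u / n * (r * left_dist)

    move_along("G", "I", "G-I")
    move_along("H", "G", "G-H")
    e_before = face["E"].copy()
    move_along("E", "H", "E-H")
    # carry C rigidly with E so the local eye geometry stays reachable for
    # the C-D / angle solve below (C enters only C-D and the angle)
    face["C"] = face["C"] + (face["E"] - e_before)

    # place D: distance |CD| = r_cd·|cd| and angle ∠CED = r_ang·∠ced
    r_cd = ratios.get("C-D", 1.0)
    r_ang = ratios.get("angle-CED", 1.0)
    C, E, D0 = face["C"], face["E"], face["D"]
    target_cd = r_cd * float(np.linalg.norm(face["c"] - face["d"]))
    target_ang = math.radians(
        r_ang * _angle_deg(face["e"], face["c"], face["d"])
    )
    ec = C - E
    ec_n = np.linalg.norm(ec)
    if ec_n < 1e-9:
        raise DegenerateGeometryError("C and E coincide")
    u1 = ec / ec_n
    w = D0 - E - np.dot(D0 - E, u1) * u1  # in-plane component ⊥ EC
    w_n = np.linalg.norm(w)
    if w_n < 1e-9:
        raise DegenerateGeometryError("C, E, D collinear: angle plane undefined")
    u2 = w / w_n
    ray = math.cos(target_ang) * u1 + math.sin(target_ang) * u2
    # solve |E + t·ray − C| = target_cd for t > 0
    b = -2.0 * float(np.dot(ray, C - E))
    c0 = float(np.dot(C - E, C - E)) - target_cd**2
    disc = b * b - 4.0 * c0
    if disc < 0:
        raise DegenerateGeometryError(
            "requested resting C-D/angle ratios are geometrically unreachable"
        )
    roots = [(-b + s * math.sqrt(disc)) / 2.0 for s in (+1, -1)]
    t = max((r for r in roots if r > 1e-9), default=None)
    if t is None:
        raise DegenerateGeometryError("no valid placement for lower-eyelid marker")
    face["D"] = E + t * ray


def _bump(n: int) -> np.ndarray:
    """Raised-cosine displacement profile on [0,1), peak 1 at the midpoint."""
    t = np.arange(n) / n
    return 0.5 * (1.0 - np.cos(2.0 * math.pi * t))


def simulate_session(config: SimulationConfig) -> tuple[TrajectorySet, SessionTruth]:
    """One synthetic capture session with its ground truth."""
    scheme = default_scheme()
    protocol = default_protocol()
    rate = config.frame_rate

    face: dict[str, np.ndarray] = {}
    for lab, p in _RIGHT_FACE.items():
        face[lab] = np.asarray(p, float)
        face[lab.lower()] = np.asarray(p, float) * np.array([-1.0, 1.0, 1.0])
    for lab, p in _MIDLINE_FACE.items():
        face[lab] = np.asarray(p, float)
    if config.resting_ratios:
        _apply_resting_ratios(face, config.resting_ratios)

    n_rest = round(config.rest_duration_s * rate)
    n_expr = round(config.expression_duration_s * rate)
    segments = [ExpressionSegment(REST, 0, n_rest)]
    start = n_rest
    for expr in protocol.expressions:
        segments.append(ExpressionSegment(expr.value, start, start + n_expr))
        start += n_expr
    n_frames = start

    labels = tuple(sorted(face)) + tuple(_HELMET)
    positions = np.empty((n_frames, len(labels), 3))
    for j, lab in enumerate(labels):
        positions[:, j, :] = face[lab] if lab in face else np.asarray(_HELMET[lab])

    atten = 1.0 - config.severity
    peak_speed: dict[Expression, float] = {}
    for expr in protocol.expressions:
        seg = next(s for s in segments if s.label == expr.value)
        amp = config.amplitudes_mm[expr]
        peak_speed[expr] = math.pi * amp / config.expression_duration_s
        profile = _bump(seg.n_frames)
        right_lab = protocol.analysis_map[expr]
        direction = np.asarray(_DIRECTIONS[expr], float)
        direction /= np.linalg.norm(direction)
        for side in (Side.RIGHT, Side.LEFT):
            lab = scheme.label_on_side(right_lab, side)
            d = direction if side is Side.RIGHT else direction * np.array([-1.0, 1.0, 1.0])
            a = amp * (atten if side is config.paralyzed_side else 1.0)
            j = labels.index(lab)
            positions[seg.start_frame : seg.end_frame, j, :] += (
                a * profile[:, None] * d[None, :]
            )

    if config.head_motion.enabled:
        hm = config.head_motion
        t = np.arange(n_frames) / rate
        phase = np.sin(2.0 * math.pi * hm.frequency_hz * t)
        center = np.mean([np.asarray(p) for p in _HELMET.values()], axis=0)
        for f in range(n_frames):
            R = Rotation.from_euler("y", hm.rotation_deg * phase[f], degrees=True).as_matrix()
            shift = np.asarray(hm.translation_mm) * phase[f]
            positions[f] = (positions[f] - center) @ R.T + center + shift

    if config.noise_sd_mm > 0:
        rng = np.random.default_rng(config.seed)
        positions = positions + rng.normal(0.0, config.noise_sd_mm, positions.shape)

    traj = TrajectorySet(
        frame_rate=rate,
        labels=labels,
        positions=positions,
        missing=np.zeros((n_frames, len(labels)), dtype=bool),
        helmet_labels=tuple(_HELMET),
        segments=segments,
        paralyzed_side=config.paralyzed_side,
    )
    truth = SessionTruth(
        severity=config.severity,
        distance_sr=atten,
        speed_sr=atten,
        peak_speed_mm_s=peak_speed,
        resting_ratios={**{n: 1.0 for n in ("G-H", "G-I", "C-D", "E-H", "angle-CED")},
                        **config.resting_ratios},
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def noise_sd_for_r2(model: LinearPrognosticModel, predictors: pd.DataFrame, r2: float) -> float:
    """Residual SD that yields an expected R² of ``r2`` on these predictors."""
    if not 0 < r2 < 1:
        raise ValidationError("target R² must lie in (0,1)")
    signal = np.zeros(len(predictors))
    for name, coef in model.coefficients.items():
        signal = signal + coef * predictors[name].to_numpy(float)
    var_signal = float(np.var(signal))
    if var_signal == 0:
        raise ValidationError("predictors carry no signal variance")
    return math.sqrt(var_signal * (1.0 - r2) / r2)


def simulate_cohort(
    n: int,
    model: LinearPrognosticModel,
    predictor_dists: dict[str, tuple[float, float, float, float]],
    noise_sd: float,
    seed: int,
    criteria: RecoveryCriteria = RecoveryCriteria(),
) -> pd.DataFrame:
    """Patient table with outcome = model(predictors) + Gaussian noise.

    ``predictor_dists`` maps predictor name → (mean, sd, low, high): a
    truncated-by-clipping normal draw. The outcome is clamped to [0,100]
    (it is an SFGS-like score) and each row is labeled good/poor by the
    recovery criteria. Deterministic per seed.
    """
    if n < 3:
        raise ValidationError(f"cohort needs n ≥ 3, got {n}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name in model.coefficients:
        if name not in predictor_dists:
            raise ValidationError(f"no distribution given for predictor {name!r}")
        mean, sd, low, high = predictor_dists[name]
        if sd <= 0 or high <= low:
            raise ValidationError(f"degenerate distribution for predictor {name!r}")
        cols[name] = np.clip(rng.normal(mean, sd, n), low, high)
    y = np.full(n, model.intercept)
    for name, coef in model.coefficients.items():
        y = y + coef * cols[name]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    y = np.clip(y, 0.0, 100.0)
    df = pd.DataFrame(cols)
    df.insert(0, "patient_id", [f"sim{i:03d}" for i in range(n)])
    df[model.outcome_name] = y
    df["recovery"] = [
        classify_recovery(
            ClinicalRecord(patient_id=pid, sfgs=float(v)), criteria
        )["sfgs"]
        for pid, v in zip(df["patient_id"], y)
    ]
    return df
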