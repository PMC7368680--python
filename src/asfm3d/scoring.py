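"""Symmetry ratios, resting abnormality score, and the gross facial-motion score.

The gross score follows the composite

    score = 0.7·D + 0.3·V − A

where D is 100 × the mean distance symmetry ratio over the five expression
analyses, V is 100 × the mean speed symmetry ratio, and A is the resting
abnormality score (4 points per abnormal resting-parameter pair, maximum
20). Symmetry ratios are paralyzed-side / contralateral-side kinematic
maxima, capped at 1 by default so over-movement of the paralyzed side cannot
push the score above symmetric. The raw composite can leave [0, 100] (a
complete palsy with every resting pair abnormal gives −20); the gross score
clamps it to [0, 100] while the raw value is retained.

Resting analysis compares five static measures between sides: the distances
G–H, G–I, C–D and E–H, and the angle ∠CED at the lateral canthus. Ratios
are right/left by convention; a ratio outside its normal reference interval
(established on healthy subjects; supplied by configuration) marks the pair
abnormal. The intervals shipped as defaults ([0.85, 1.18] for every pair)
are non-clinical placeholders — calibrate on a healthy cohort before any
clinical use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .kinematics import KinematicSummary, SmoothingConfig, expression_kinematics, rest_baseline
from .landmarks import (
    Expression,
    ExpressionProtocol,
    LandmarkScheme,
    Side,
    default_protocol,
    default_scheme,
)
from .io import TrajectorySet
from .stabilization import stabilize

DEFAULT_SR_CAP = 1.0
#: MMD below this (mm) is treated as "no reliable motion" when the ratio
#: would otherwise divide by noise
DEFAULT_NOISE_FLOOR_MM = 0.5

#: resting parameter definitions on the right side; left side uses mirrors
RESTING_DISTANCE_PAIRS = (("G-H", ("G", "H")), ("G-I", ("G", "I")),
                          ("C-D", ("C", "D")), ("E-H", ("E", "H")))
RESTING_ANGLE_NAME = "angle-CED"
RESTING_PARAMETER_NAMES = tuple(n for n, _ in RESTING_DISTANCE_PAIRS) + (RESTING_ANGLE_NAME,)


@dataclass(frozen=True)
class SrEntry:
    """One expression's symmetry ratios with provenance flags."""

    distance_sr: float
    speed_sr: float
    distance_capped: bool = False
    speed_capped: bool = False
    degenerate: bool = False  # 0/0 resolved to 1.0


@dataclass
class SymmetryRatios:
    entries: dict[Expression, SrEntry]
    cap: float = DEFAULT_SR_CAP

    def __post_init__(self):
        for e in self.entries.values():
            if e.distance_sr < 0 or e.speed_sr < 0:
                raise ValidationError("symmetry ratios must be non-negative")


@dataclass(frozen=True)
class RestingPair:
    """One bilateral resting measure (distance in mm or angle in degrees)."""

    name: str
    right: float
    left: float

    @property
    def ratio(self) -> float:
        if self.left <= 0 or self.right <= 0:
            raise DegenerateGeometryError(f"resting parameter {self.name}: non-positive value")
        return self.right / self.left


@dataclass
class RestingParameters:
    pairs: tuple[RestingPair, ...]

    def __post_init__(self):
        if tuple(p.name for p in self.pairs) != RESTING_PARAMETER_NAMES:
            raise ValidationError(
                f"resting parameters must be exactly {RESTING_PARAMETER_NAMES}"
            )

    def __iter__(self):
        return iter(self.pairs)


@dataclass(frozen=True)
class ReferenceIntervals:
    """Per-parameter normal range of the right/left ratio.

    The shipped default, ratio ∈ [0.85, 1.18] for all five parameters, is a
    placeholder: the healthy-cohort values behind the original system were
    never published. Boundary values count as normal.
    """

    intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {n: (0.85, 1.18) for n in RESTING_PARAMETER_NAMES}
    )

    def __post_init__(self):
        for name, (lo, hi) in self.intervals.items():
            if not (0 < lo < hi):
                raise ValidationError(f"{name}: need 0 < lower < upper, got ({lo},{hi})")
            if not (lo <= 1.0 <= hi):
                raise ValidationError(f"{name}: reference interval must contain 1.0")

    def is_normal(self, name: str, ratio: float) -> bool:
        lo, hi = self.intervals[name]
        return lo <= ratio <= hi

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in self.intervals.items()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceIntervals":
        return cls({k: (float(v[0]), float(v[1])) for k, v in json.loads(text).items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "ReferenceIntervals":
        return cls.from_json(Path(path).read_text())


@dataclass
class AsfmScore:
    """Full score breakdown: D, V, A, raw and clamped gross score."""

    d: float
    v: float
    a: int
    raw_score: float
    gross_score: float
    symmetry: SymmetryRatios
    resting: RestingParameters | None = None
    resting_abnormal: dict[str, bool] = field(default_factory=dict)

    # -- serialization (lossless JSON round-trip) ----------------------

    def to_dict(self) -> dict:
        doc = {
            "d": self.d,
            "v": self.v,
            "a": self.a,
            "raw_score": self.raw_score,
            "gross_score": self.gross_score,
            "symmetry": {
                "cap": self.symmetry.cap,
                "entries": {
                    expr.value: {
                        "distance_sr": e.distance_sr,
                        "speed_sr": e.speed_sr,
                        "distance_capped": e.distance_capped,
                        "speed_capped": e.speed_capped,
                        "degenerate": e.degenerate,
                    }
                    for expr, e in self.symmetry.entries.items()
                },
            },
            "resting": None,
        }
        if self.resting is not None:
            doc["resting"] = {
                "pairs": [
                    {"name": p.name, "right": p.right, "left": p.left, "ratio": p.ratio,
                     "abnormal": self.resting_abnormal.get(p.name)}
                    for p in self.resting
                ]
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "AsfmScore":
        sym = SymmetryRatios(
            entries={
                Expression(k): SrEntry(
                    distance_sr=v["distance_sr"],
                    speed_sr=v["speed_sr"],
                    distance_capped=v["distance_capped"],
                    speed_capped=v["speed_capped"],
                    degenerate=v["degenerate"],
                )
                for k, v in doc["symmetry"]["entries"].items()
            },
            cap=doc["symmetry"]["cap"],
        )
        resting = None
        flags: dict[str, bool] = {}
        if doc.get("resting"):
            resting = RestingParameters(
                tuple(RestingPair(p["name"], p["right"], p["left"]) for p in doc["resting"]["pairs"])
            )
            flags = {p["name"]: p["abnormal"] for p in doc["resting"]["pairs"]
                     if p["abnormal"] is not None}
        return cls(
            d=doc["d"], v=doc["v"], a=doc["a"],
            raw_score=doc["raw_score"], gross_score=doc["gross_score"],
            symmetry=sym, resting=resting, resting_abnormal=flags,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _one_ratio(paralyzed: float, contralateral: float, cap: float, floor: float):
    """(ratio, capped, degenerate) with the documented edge-case policy."""
    if contralateral <= floor:
        if paralyzed <= floor:
            return 1.0, False, True  # both immobile: symmetric by convention
        raise ValidationError(
            "contralateral motion below the noise floor while the paralyzed side "
            f"moves ({paralyzed:.2f} vs {contralateral:.2f} mm): unreliable reference"
        )
    ratio = paralyzed / contralateral
    if ratio > cap:
        return cap, True, False
    return ratio, False, False


def regional_symmetry(
    kin: KinematicSummary,
    scheme: LandmarkScheme,
    protocol: ExpressionProtocol,
    paralyzed_side: Side,
    *,
    cap: float = DEFAULT_SR_CAP,
    noise_floor_mm: float = DEFAULT_NOISE_FLOOR_MM,
) -> SymmetryRatios:
    """Distance and speed symmetry ratios per expression.

    SR = paralyzed-side maximum / contralateral-side maximum. Ratios above
    ``cap`` are capped and flagged; a 0/0 (both sides below the noise floor)
    resolves to 1.0 with a degenerate flag.
    """
    entries: dict[Expression, SrEntry] = {}
    for expr in protocol.expressions:
        right = protocol.analysis_map[expr]
        par = kin.get(scheme.label_on_side(right, paralyzed_side), expr)
        con = kin.get(scheme.label_on_side(right, paralyzed_side.opposite), expr)
        # the noise floor is an MMD concept; apply the distance-based
        # degeneracy decision to the speed ratio as well so one expression
        # cannot be half-degenerate
        d_sr, d_cap, degen = _one_ratio(par.mmd, con.mmd, cap, noise_floor_mm)
        if degen:
            s_sr, s_cap = 1.0, False
        else:
            s_sr = par.mms / con.mms if con.mms > 0 else cap
            s_cap = s_sr > cap or con.mms == 0
            s_sr = min(s_sr, cap)
        entries[expr] = SrEntry(d_sr, s_sr, d_cap, s_cap, degen)
    return SymmetryRatios(entries=entries, cap=cap)


def _angle_deg(vertex: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    u, w = np.asarray(p1, float) - vertex, np.asarray(p2, float) - vertex
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-9 or nw < 1e-9:
        raise DegenerateGeometryError("coincident points: angle undefined")
    c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return math.degrees(math.acos(c))


def resting_parameters(
    baseline: dict[str, np.ndarray], scheme: LandmarkScheme
) -> RestingParameters:
    """Five bilateral resting measures from rest-baseline positions.

    Distances are Euclidean; the angle is ∠CED in degrees (vertex at the
    lateral canthus E/e, rays toward the upper and lower eyelid C/c, D/d).
    """
    def pos(lab: str, side: Side) -> np.ndarray:
        key = lab if lab in scheme.midline else scheme.label_on_side(lab, side)
        if key not in baseline:
            raise ValidationError(f"rest baseline missing landmark {key!r}")
        return np.asarray(baseline[key], float)

    pairs = []
    for name, (l1, l2) in RESTING_DISTANCE_PAIRS:
        r = float(np.linalg.norm(pos(l1, Side.RIGHT) - pos(l2, Side.RIGHT)))
        l = float(np.linalg.norm(pos(l1, Side.LEFT) - pos(l2, Side.LEFT)))
        pairs.append(RestingPair(name, r, l))
    pairs.append(
        RestingPair(
            RESTING_ANGLE_NAME,
            _angle_deg(pos("E", Side.RIGHT), pos("C", Side.RIGHT), pos("D", Side.RIGHT)),
            _angle_deg(pos("E", Side.LEFT), pos("C", Side.LEFT), pos("D", Side.LEFT)),
        )
    )
    return RestingParameters(tuple(pairs))


def abnormal_flags(params: RestingParameters, ref: ReferenceIntervals) -> dict[str, bool]:
    return {p.name: not ref.is_normal(p.name, p.ratio) for p in params}


def resting_score(params: RestingParameters, ref: ReferenceIntervals) -> int:
    """A = 4 × number of resting pairs whose ratio leaves its normal interval."""
    return 4 * sum(abnormal_flags(params, ref).values())


def gross_score(
    sr: SymmetryRatios,
    a: int,
    resting: RestingParameters | None = None,
    resting_abnormal: dict[str, bool] | None = None,
) -> AsfmScore:
    """Compose D, V and A into the gross score 0.7·D + 0.3·V − A."""
    if a % 4 or not 0 <= a <= 20:
        raise ValidationError(f"resting score must be one of 0,4,…,20, got {a}")
    if len(sr.entries) != 5:
        raise ValidationError("need symmetry ratios for all five expressions")
    d = 100.0 * float(np.mean([e.distance_sr for e in sr.entries.values()]))
    v = 100.0 * float(np.mean([e.speed_sr for e in sr.entries.values()]))
    raw = 0.7 * d + 0.3 * v - a
    return AsfmScore(
        d=d, v=v, a=a,
        raw_score=raw,
        gross_score=float(min(100.0, max(0.0, raw))),
        symmetry=sr,
        resting=resting,
        resting_abnormal=resting_abnormal or {},
    )


def score_session(
    traj: TrajectorySet,
    scheme: LandmarkScheme | None = None,
    protocol: ExpressionProtocol | None = None,
    ref: ReferenceIntervals | None = None,
    *,
    cap: float = DEFAULT_SR_CAP,
    noise_floor_mm: float = DEFAULT_NOISE_FLOOR_MM,
    smoothing: SmoothingConfig = SmoothingConfig(),
) -> AsfmScore:
    """Full pipeline: stabilize → kinematics → symmetry + resting → gross score."""
    scheme = scheme or default_scheme()
    protocol = protocol or default_protocol()
    ref = ref or ReferenceIntervals()
    if traj.paralyzed_side is None:
        raise ValidationError("paralyzed side must be declared to score a session",
                              stage="score_session")

    def staged(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ValidationError, DegenerateGeometryError) as exc:
            if getattr(exc, "stage", None) is None:
                raise type(exc)(str(exc), stage=stage) from exc
            raise

    stab = staged("stabilize", stabilize, traj)
    kin = staged("kinematics", expression_kinematics, stab, scheme, protocol, smoothing)
    sr = staged(
        "regional_symmetry", regional_symmetry, kin, scheme, protocol,
        traj.paralyzed_side, cap=cap, noise_floor_mm=noise_floor_mm,
    )
    needed = sorted({s.label_on_side(lab, side) if lab not in s.midline else lab
                     for s in (scheme,)
                     for lab in ("C", "D", "E", "G", "H", "I")
                     for side in (Side.RIGHT, Side.LEFT)})
    base = staged("rest_baseline", rest_baseline, stab, needed)
    resting = staged("resting_parameters", resting_parameters, base, scheme)
    flags = abnormal_flags(resting, ref)
    a = 4 * sum(flags.values())
    return gross_score(sr, a, resting, flags)
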