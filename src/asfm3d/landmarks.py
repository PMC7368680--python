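"""The 21-point facial landmark scheme and the five-expression protocol.

The marker set covers every facial-nerve branch with 8 bilateral pairs
(uppercase = subject's right side, lowercase = left) plus 5 midline points.
Two of the midline labels are Roman numerals ("II", "III"); they are plain
landmark identifiers here and must never be conflated with House-Brackmann
grades, which live in their own enum (:class:`HBGrade`).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError


class Side(str, enum.Enum):
    """Subject side. Paralyzed/contralateral logic always resolves through
    the scheme plus a declared :class:`Side`, never by label case."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def opposite(self) -> "Side":
        return Side.LEFT if self is Side.RIGHT else Side.RIGHT


class HBGrade(enum.IntEnum):
    """House-Brackmann facial function grade (I normal … VI total paralysis).

    A distinct type from landmark labels: the scheme's midline markers "II"
    and "III" are strings, these are integers with Roman-numeral names.
    """

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5
    VI = 6

    @classmethod
    def parse(cls, value) -> "HBGrade":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return cls(int(value))
        name = str(value).strip().upper()
        try:
            return cls[name]
        except KeyError:
            raise ValidationError(f"not a House-Brackmann grade: {value!r}")


class Expression(str, enum.Enum):
    """The five standard voluntary expressions, in protocol order."""

    BROW_ELEVATION = "brow_elevation"
    EYE_CLOSURE = "eye_closure"
    OPEN_MOUTH_SMILE = "open_mouth_smile"
    SNARL = "snarl"
    LIP_PUCKER = "lip_pucker"


@dataclass(frozen=True)
class LandmarkScheme:
    """Named facial points with left/right pairing and midline roles.

    Parameters
    ----------
    pair_map
        Maps each right-side label (uppercase by convention) to its
        left-side partner.
    midline
        Labels lying on the facial midline; they mirror onto themselves.
    anatomical_name
        Human-readable description per label.
    """

    pair_map: dict[str, str]
    midline: frozenset[str]
    anatomical_name: dict[str, str]

    def __post_init__(self):
        rights = set(self.pair_map)
        lefts = set(self.pair_map.values())
        if len(lefts) != len(rights):
            raise ValidationError("pair_map is not a bijection")
        if rights & lefts:
            raise ValidationError("a label appears on both sides of pair_map")
        if set(self.midline) & (rights | lefts):
            raise ValidationError("midline labels may not appear in pair_map")
        for lab in self.labels:
            if not self.anatomical_name.get(lab):
                raise ValidationError(f"label {lab!r} has no anatomical name")

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.pair_map) | frozenset(self.pair_map.values()) | self.midline

    @property
    def right_labels(self) -> frozenset[str]:
        return frozenset(self.pair_map)

    @property
    def left_labels(self) -> frozenset[str]:
        return frozenset(self.pair_map.values())

    def mirror_label(self, label: str) -> str:
        """Bilateral partner of ``label``; midline labels map to themselves."""
        if label in self.midline:
            return label
        if label in self.pair_map:
            return self.pair_map[label]
        inverse = {v: k for k, v in self.pair_map.items()}
        if label in inverse:
            return inverse[label]
        raise ValidationError(f"unknown landmark label: {label!r}")

    def side_of(self, label: str) -> Side | None:
        """Side a label sits on, or None for midline."""
        if label in self.midline:
            return None
        if label in self.pair_map:
            return Side.RIGHT
        if label in set(self.pair_map.values()):
            return Side.LEFT
        raise ValidationError(f"unknown landmark label: {label!r}")

    def label_on_side(self, right_label: str, side: Side) -> str:
        """Resolve a pair, named by its right-side label, to one side."""
        if right_label not in self.pair_map:
            raise ValidationError(f"{right_label!r} is not a right-side paired label")
        return right_label if side is Side.RIGHT else self.pair_map[right_label]

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "pair_map": self.pair_map,
                "midline": sorted(self.midline),
                "anatomical_name": self.anatomical_name,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LandmarkScheme":
        doc = json.loads(text)
        return cls(
            pair_map=dict(doc["pair_map"]),
            midline=frozenset(doc["midline"]),
            anatomical_name=dict(doc["anatomical_name"]),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "LandmarkScheme":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class ExpressionProtocol:
    """Which bilateral landmark pair each expression is analyzed with.

    ``analysis_map`` values are right-side labels of pairs in the scheme;
    the mouth corner (H/h) is analyzed twice, once by the open mouth smile
    and once by the lip pucker.
    """

    expressions: tuple[Expression, ...] = (
        Expression.BROW_ELEVATION,
        Expression.EYE_CLOSURE,
        Expression.OPEN_MOUTH_SMILE,
        Expression.SNARL,
        Expression.LIP_PUCKER,
    )
    analysis_map: dict[Expression, str] = field(
        default_factory=lambda: {
            Expression.BROW_ELEVATION: "B",
            Expression.EYE_CLOSURE: "C",
            Expression.SNARL: "G",
            Expression.OPEN_MOUTH_SMILE: "H",
            Expression.LIP_PUCKER: "H",
        }
    )

    def __post_init__(self):
        if len(self.expressions) != 5:
            raise ValidationError("protocol must contain exactly 5 expressions")
        if set(self.analysis_map) != set(self.expressions):
            raise ValidationError("analysis_map must cover exactly the protocol expressions")

    def validate_against(self, scheme: LandmarkScheme) -> None:
        for expr, lab in self.analysis_map.items():
            if lab not in scheme.pair_map:
                raise ValidationError(
                    f"expression {expr.value} maps to {lab!r}, not a bilateral pair"
                )


def default_scheme() -> LandmarkScheme:
    """The standard 21-point scheme: 8 bilateral pairs + 5 midline points."""
    names = {
        "A": "tragus parallel to the upper wall of the external acoustic canal (right)",
        "a": "tragus parallel to the upper wall of the external acoustic canal (left)",
        "B": "central position above the eyebrow (right)",
        "b": "central position above the eyebrow (left)",
        "C": "center of the upper eyelid (right)",
        "c": "center of the upper eyelid (left)",
        "D": "center of the lower eyelid (right)",
        "d": "center of the lower eyelid (left)",
        "E": "angulus oculi temporalis (right)",
        "e": "angulus oculi temporalis (left)",
        "F": "angulus oculi medialis (right)",
        "f": "angulus oculi medialis (left)",
        "G": "ala of the nose (right)",
        "g": "ala of the nose (left)",
        "H": "corner of the mouth (right)",
        "h": "corner of the mouth (left)",
        "I": "root of the columella nasi",
        "J": "center of the eyebrows",
        "K": "bony-cartilaginous junction along the nasal dorsum",
        "II": "philtrum",
        "III": "center of the lower lip",
    }
    return LandmarkScheme(
        pair_map={r: r.lower() for r in "ABCDEFGH"},
        midline=frozenset({"I", "J", "K", "II", "III"}),
        anatomical_name=names,
    )


def default_protocol() -> ExpressionProtocol:
    return ExpressionProtocol()


def mirror_label(scheme: LandmarkScheme, label: str) -> str:
    """Functional alias for :meth:`LandmarkScheme.mirror_label`."""
    return scheme.mirror_label(label)
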