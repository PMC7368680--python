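"""Readers/writers for marker trajectories, clinical tables and score reports.

Canonical internal units are millimeters and seconds throughout (speeds in
mm/s, accelerations in mm/s²). Frame intervals are 0-based half-open
``[start, end)``.

Trajectory input comes either as TRC (the tab-separated motion-capture ASCII
dialect, with an optional ``<basename>.segments.json`` sidecar carrying
expression segmentation and the paralyzed side) or as a long-format CSV with
columns ``frame,label,x,y,z`` plus an explicit config.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputFormatError, ValidationError
from .landmarks import Expression, HBGrade, Side

REST = "rest"
_SEGMENT_LABELS = {REST} | {e.value for e in Expression}

#: mm per unit, for the unit strings TRC headers use
_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


@dataclass(frozen=True)
class ExpressionSegment:
    """Half-open frame interval [start_frame, end_frame) holding one task."""

    label: str
    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.label not in _SEGMENT_LABELS:
            raise ValidationError(f"unknown segment label {self.label!r}")
        if not self.start_frame < self.end_frame:
            raise ValidationError(
                f"segment {self.label!r}: start {self.start_frame} must be < end {self.end_frame}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class TrajectorySet:
    """Frame-indexed 3D marker positions for face + helmet markers.

    Attributes
    ----------
    labels
        All marker labels, facial and helmet, in column order.
    positions
        Array of shape (n_frames, n_labels, 3), millimeters. Entries where
        ``missing`` is True are NaN.
    missing
        Boolean mask, shape (n_frames, n_labels).
    helmet_labels
        Markers rigidly attached to the reference helmet (≥3 for
        stabilization); disjoint from facial labels.
    segments
        Non-overlapping expression segments; a fully annotated session has
        exactly one ``rest`` segment plus the five expressions.
    """

    frame_rate: float
    labels: tuple[str, ...]
    positions: np.ndarray
    missing: np.ndarray
    helmet_labels: tuple[str, ...] = ()
    segments: list[ExpressionSegment] = field(default_factory=list)
    paralyzed_side: Side | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.frame_rate <= 0:
            raise ValidationError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError("positions must have shape (n_frames, n_labels, 3)")
        if self.positions.shape[:2] != self.missing.shape:
            raise ValidationError("positions and missing mask disagree on shape")
        if self.positions.shape[1] != len(self.labels):
            raise ValidationError("positions second axis must match number of labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate marker labels")
        present = ~self.missing
        if not np.all(np.isfinite(self.positions[present])):
            raise ValidationError("non-finite coordinates outside the missing mask")
        self._check_segments()

    def _check_segments(self) -> None:
        taken = np.zeros(self.n_frames, dtype=bool)
        rest_count = 0
        for seg in self.segments:
            if seg.start_frame < 0 or seg.end_frame > self.n_frames:
                raise ValidationError(
                    f"segment {seg.label!r} [{seg.start_frame},{seg.end_frame}) "
                    f"outside [0,{self.n_frames})"
                )
            if taken[seg.start_frame : seg.end_frame].any():
                raise ValidationError(f"segment {seg.label!r} overlaps another segment")
            taken[seg.start_frame : seg.end_frame] = True
            rest_count += seg.label == REST
        if self.segments and rest_count != 1:
            raise ValidationError(f"expected exactly one 'rest' segment, found {rest_count}")

    # -- accessors -----------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def facial_labels(self) -> tuple[str, ...]:
        helmet = set(self.helmet_labels)
        return tuple(l for l in self.labels if l not in helmet)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"marker {label!r} not in trajectory set")

    def get(self, label: str) -> np.ndarray:
        """(n_frames, 3) positions for one marker (NaN where missing)."""
        return self.positions[:, self.index(label), :]

    def get_missing(self, label: str) -> np.ndarray:
        return self.missing[:, self.index(label)]

    def segment(self, label: str) -> ExpressionSegment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise ValidationError(f"no segment labeled {label!r}")

    @property
    def rest(self) -> ExpressionSegment:
        return self.segment(REST)

    def with_positions(self, positions: np.ndarray, missing: np.ndarray | None = None) -> "TrajectorySet":
        return replace(
            self,
            positions=positions,
            missing=self.missing.copy() if missing is None else missing,
            segments=list(self.segments),
        )


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------


def read_trc(path: str | Path, *, sidecar: bool = True) -> TrajectorySet:
    """Parse a TRC motion-capture file into a :class:`TrajectorySet`.

    Header fields DataRate / NumFrames / NumMarkers / Units are honored and
    coordinates converted to millimeters. Blank coordinate cells become
    missing entries. If ``<basename>.segments.json`` exists next to the file
    (and ``sidecar`` is true) it supplies segments, helmet labels and the
    paralyzed side; otherwise the session is a single unlabeled block.
    """
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputFormatError(f"cannot read {path}: {exc}")
    if len(lines) < 5:
        raise InputFormatError(f"{path}: truncated TRC file ({len(lines)} lines)")

    keys = lines[1].rstrip("\n").split("\t")
    vals = lines[2].rstrip("\n").split("\t")
    header = dict(zip(keys, vals))
    for required in ("DataRate", "NumFrames", "NumMarkers", "Units"):
        if required not in header or header[required] == "":
            raise InputFormatError(f"{path}: line 3 missing header field {required}")
    try:
        rate = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
    except ValueError as exc:
        raise InputFormatError(f"{path}: line 3: unparsable header value ({exc})")
    units = header["Units"].strip().lower()
    if units not in _UNIT_TO_MM:
        raise InputFormatError(f"{path}: line 3: unsupported units {header['Units']!r}")
    scale = _UNIT_TO_MM[units]

    marker_row = lines[3].rstrip("\n").split("\t")
    labels = [c.strip() for c in marker_row[2:] if c.strip()]
    if len(labels) != n_markers:
        raise InputFormatError(
            f"{path}: line 4 names {len(labels)} markers but header declares {n_markers}"
        )

    positions = np.full((n_frames, n_markers, 3), np.nan)
    missing = np.ones((n_frames, n_markers), dtype=bool)
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise InputFormatError(
            f"{path}: header declares {n_frames} frames but {len(data_lines)} data rows found"
        )
    for i, ln in enumerate(data_lines):
        cells = ln.rstrip("\n").split("\t")
        coords = cells[2 : 2 + 3 * n_markers]
        if len(cells) - 2 < 3 * n_markers:
            # Trailing blanks may be dropped by the writer; pad.
            coords = coords + [""] * (3 * n_markers - len(coords))
        if len(cells) - 2 > 3 * n_markers:
            raise InputFormatError(
                f"{path}: line {i + 6}: {len(cells) - 2} coordinate cells for "
                f"{n_markers} markers (expected {3 * n_markers})"
            )
        for m in range(n_markers):
            triplet = coords[3 * m : 3 * m + 3]
            if any(c.strip() == "" for c in triplet):
                continue
            try:
                xyz = [float(c) for c in triplet]
            except ValueError:
                raise InputFormatError(f"{path}: line {i + 6}: non-numeric coordinate")
            positions[i, m] = np.asarray(xyz) * scale
            missing[i, m] = False

    segments: list[ExpressionSegment] = []
    helmet: tuple[str, ...] = ()
    side: Side | None = None
    sidecar_path = path.with_suffix(".segments.json")
    if sidecar and sidecar_path.exists():
        doc = json.loads(sidecar_path.read_text())
        segments = [
            ExpressionSegment(s["label"], int(s["start_frame"]), int(s["end_frame"]))
            for s in doc.get("segments", [])
        ]
        helmet = tuple(doc.get("helmet_labels", ()))
        if doc.get("paralyzed_side") is not None:
            side = Side(doc["paralyzed_side"])

    return TrajectorySet(
        frame_rate=rate,
        labels=tuple(labels),
        positions=positions,
        missing=missing,
        helmet_labels=helmet,
        segments=segments,
        paralyzed_side=side,
    )


def write_trc(traj: TrajectorySet, path: str | Path, *, sidecar: bool = True) -> None:
    """Write a TrajectorySet as TRC (mm) plus its segments sidecar."""
    path = Path(path)
    n, m = traj.n_frames, len(traj.labels)
    out = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{traj.frame_rate:g}\t{traj.frame_rate:g}\t{n}\t{m}\tmm\t{traj.frame_rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(traj.labels),
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m)),
    ]
    for i in range(n):
        cells = [str(i + 1), f"{i / traj.frame_rate:.6f}"]
        for j in range(m):
            if traj.missing[i, j]:
                cells.extend(["", "", ""])
            else:
                cells.extend(f"{v:.6f}" for v in traj.positions[i, j])
        out.append("\t".join(cells))
    path.write_text("\n".join(out) + "\n")
    if sidecar:
        doc = {
            "segments": [
                {"label": s.label, "start_frame": s.start_frame, "end_frame": s.end_frame}
                for s in traj.segments
            ],
            "helmet_labels": list(traj.helmet_labels),
            "paralyzed_side": traj.paralyzed_side.value if traj.paralyzed_side else None,
        }
        path.with_suffix(".segments.json").write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Long-format CSV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CsvTrajectoryConfig:
    """Metadata a long-format trajectory CSV does not carry itself."""

    frame_rate: float = 30.0
    helmet_labels: tuple[str, ...] = ()
    paralyzed_side: Side | None = None
    segments: tuple[ExpressionSegment, ...] = ()


def read_trajectory_csv(path: str | Path, config: CsvTrajectoryConfig) -> TrajectorySet:
    """Read frame,label,x,y,z rows (mm); empty coordinates mean missing."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise InputFormatError(f"cannot read {path}: {exc}")
    required = {"frame", "label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    dupes = df.duplicated(subset=["frame", "label"])
    if dupes.any():
        first = df[dupes].iloc[0]
        raise InputFormatError(
            f"{path}: duplicate (frame,label) row ({int(first['frame'])}, {first['label']})"
        )
    labels = tuple(pd.unique(df["label"]).astype(str))
    n_frames = int(df["frame"].max()) + 1
    positions = np.full((n_frames, len(labels), 3), np.nan)
    missing = np.ones((n_frames, len(labels)), dtype=bool)
    col = {lab: j for j, lab in enumerate(labels)}
    frames = df["frame"].to_numpy(dtype=int)
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    ok = np.isfinite(xyz).all(axis=1)
    for i in range(len(df)):
        j = col[str(df["label"].iat[i])]
        if ok[i]:
            positions[frames[i], j] = xyz[i]
            missing[frames[i], j] = False
    return TrajectorySet(
        frame_rate=config.frame_rate,
        labels=labels,
        positions=positions,
        missing=missing,
        helmet_labels=config.helmet_labels,
        segments=list(config.segments),
        paralyzed_side=config.paralyzed_side,
    )


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient visit's clinical covariates."""

    patient_id: str
    visit: str = "final"  # month1 | month2 | final
    enog_degeneration: float | None = None  # percent, 0-100
    sfgs: float | None = None  # 0-100
    hbgs: HBGrade | None = None
    asfm_gross: float | None = None
    paralyzed_side: Side | None = None

    def __post_init__(self):
        if self.enog_degeneration is not None and not 0 <= self.enog_degeneration <= 100:
            raise ValidationError(
                f"ENoG degeneration {self.enog_degeneration} outside [0,100]"
            )
        if self.sfgs is not None and not 0 <= self.sfgs <= 100:
            raise ValidationError(f"SFGS score {self.sfgs} outside [0,100]")


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """One row per patient-visit; unknown cells blank."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise InputFormatError(f"{path}: missing patient_id column")
    records = []
    for _, row in df.iterrows():
        def opt(name):
            v = row.get(name)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

        hb = opt("hbgs")
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                visit=str(opt("visit") or "final"),
                enog_degeneration=None if opt("enog_degeneration") is None else float(row["enog_degeneration"]),
                sfgs=None if opt("sfgs") is None else float(row["sfgs"]),
                hbgs=None if hb is None else HBGrade.parse(hb),
                asfm_gross=None if opt("asfm_gross") is None else float(row["asfm_gross"]),
                paralyzed_side=None if opt("paralyzed_side") is None else Side(str(row["paralyzed_side"])),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Score reports
# ---------------------------------------------------------------------------


def write_report(score, path: str | Path, prognosis: Mapping | None = None) -> None:
    """Serialize an AsfmScore (plus optional prognostic outputs) to JSON.

    Round-trips losslessly through :func:`read_report`.
    """
    doc = score.to_dict()
    if prognosis is not None:
        doc["prognosis"] = dict(prognosis)
    path = Path(path)
    try:
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise InputFormatError(f"cannot write report to {path}: {exc}")


def read_report(path: str | Path):
    from .scoring import AsfmScore  # deferred: scoring imports io types

    doc = json.loads(Path(path).read_text())
    return AsfmScore.from_dict(doc)
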