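"""Read/write pose-tracking tables and cohort manifests.

Tracking tables use the common markerless-pose-estimation export dialect:
a comma-separated file with three header rows (scorer, bodyparts, coords),
a leading frame-index column, and per body part three columns ``x``, ``y``,
``likelihood`` in that order.  Missing samples are empty cells; on read they
surface as NaN coordinates with confidence 0.  All format decisions live in
this module so that externally produced tables drop in unchanged.

The cohort manifest is a YAML (or JSON) file listing every trial of an
experiment — mouse, session, object/pairing condition, within-session order,
exclusion flag, and per-camera-side file paths — together with the trial
timeline, the per-eye toward-threat sign convention, and the stroke-interval
law used by the generator.  Schema::

    format_version: 1
    seed: <int or null>
    timeline: {pairing_start, threat_onset, threat_hold, frame_rate}
    toward_threat_sign: {right: 1.0, left: -1.0}
    interval_law: {family, min_interval, max_interval, rate}
    trials:
      - mouse_id: m01
        session_index: 1
        object_condition: artificial_limb   # artificial_limb | block | none
        pairing_condition: synchronous      # synchronous | asynchronous | none
        trial_order_within_session: 1
        excluded: false
        files: {right: m01_s1_..._right.csv, left: ...}   # paths relative to
                                                          # the manifest file
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import PointTrack, TrialTimeline, validate_conditions
from .errors import ManifestError, ParameterError, TrackingFormatError

_HEADER_LEVELS = ("scorer", "bodyparts", "coords")
_COORDS = ("x", "y", "likelihood")


@dataclass
class TrackingTable:
    """A validated pose-tracking table (one trial, one camera side)."""

    scorer: str
    bodyparts: tuple
    data: pd.DataFrame  # columns: MultiIndex (scorer, bodypart, coord)

    @classmethod
    def from_points(cls, scorer: str, points: Mapping[str, PointTrack]) -> "TrackingTable":
        """Build a table from named :class:`PointTrack` series."""
        if not points:
            raise ParameterError("at least one body part is required")
        lengths = {name: len(p) for name, p in points.items()}
        if len(set(lengths.values())) > 1:
            raise ParameterError(f"ragged body-part lengths: {lengths}")
        cols, arrays = [], []
        for name, p in points.items():
            for coord, arr in zip(_COORDS, (p.x, p.y, p.confidence)):
                cols.append((scorer, name, coord))
                arrays.append(np.asarray(arr, dtype=float))
        columns = pd.MultiIndex.from_tuples(cols, names=_HEADER_LEVELS)
        n = len(arrays[0])
        data = pd.DataFrame(
            np.column_stack(arrays) if n else np.empty((0, len(cols))),
            columns=columns,
            index=pd.RangeIndex(n),
        )
        return cls(scorer=scorer, bodyparts=tuple(points), data=data)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def point(self, name: str) -> PointTrack:
        if name not in self.bodyparts:
            raise KeyError(f"unknown body part {name!r}; table has {self.bodyparts}")
        sub = self.data[self.scorer][name]
        return PointTrack(
            x=sub["x"].to_numpy(),
            y=sub["y"].to_numpy(),
            confidence=sub["likelihood"].to_numpy(),
        )

    def points(self) -> dict:
        return {name: self.point(name) for name in self.bodyparts}

    def equals(self, other: "TrackingTable") -> bool:
        return (
            self.scorer == other.scorer
            and self.bodyparts == other.bodyparts
            and self.data.equals(other.data)
        )


def _validate_columns(columns: pd.MultiIndex, where: str) -> tuple:
    """Validate the (scorer, bodyparts, coords) column structure."""
    if list(columns.names) != list(_HEADER_LEVELS):
        raise TrackingFormatError(
            f"{where}: header rows must be labelled {_HEADER_LEVELS}, "
            f"got {tuple(columns.names)}"
        )
    scorers = {c[0] for c in columns}
    if len(scorers) != 1:
        raise TrackingFormatError(f"{where}: expected a single scorer, got {sorted(scorers)}")
    scorer = next(iter(scorers))
    # body parts must appear in contiguous blocks of exactly (x, y, likelihood)
    parts: list = []
    tuples = list(columns)
    i = 0
    while i < len(tuples):
        part = tuples[i][1]
        block = tuples[i : i + 3]
        coords = tuple(c[2] for c in block)
        if len(block) < 3 or any(c[1] != part for c in block) or coords != _COORDS:
            raise TrackingFormatError(
                f"{where}: body part {part!r} must have exactly the columns "
                f"{_COORDS} in order, got {coords} starting at column {i + 1}"
            )
        if part in parts:
            raise TrackingFormatError(f"{where}: duplicate body part {part!r}")
        parts.append(part)
        i += 3
    return scorer, tuple(parts)


def read_tracking_table(path) -> TrackingTable:
    """Read and validate a tracking table in the three-header-row CSV dialect.

    Missing samples (empty cells) become NaN coordinates with confidence 0.
    Raises :class:`TrackingFormatError` naming the offending row/column for
    any deviation from the dialect.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise TrackingFormatError(f"{path}: cannot parse as tracking CSV: {exc}") from exc
    scorer, parts = _validate_columns(df.columns, str(path))
    for col in df.columns:
        if len(df) and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise TrackingFormatError(
                f"{path}: non-numeric cell in column {col} at frame {row}"
            )
    n = len(df)
    if n and not np.array_equal(np.asarray(df.index), np.arange(n)):
        raise TrackingFormatError(f"{path}: frame indices must be contiguous from 0")
    df = df.astype(float)
    df.index = pd.RangeIndex(n)
    # surface missing samples: NaN x/y or NaN likelihood -> confidence 0
    for part in parts:
        sub = df[scorer][part]
        like = sub["likelihood"].to_numpy(copy=True)
        missing = np.isnan(sub["x"].to_numpy()) | np.isnan(sub["y"].to_numpy()) | np.isnan(like)
        like[missing] = 0.0
        if like.size and (like.min() < 0 or like.max() > 1):
            raise TrackingFormatError(
                f"{path}: likelihood out of [0, 1] for body part {part!r}"
            )
        df[(scorer, part, "likelihood")] = like
    return TrackingTable(scorer=scorer, bodyparts=parts, data=df)


def write_tracking_table(table: TrackingTable, path) -> None:
    """Write ``table`` in the same dialect read by :func:`read_tracking_table`.

    Values are written at full precision (shortest round-tripping repr).
    """
    path = Path(path)
    df = table.data.copy()
    df.columns = pd.MultiIndex.from_tuples(list(df.columns), names=_HEADER_LEVELS)
    df.index = pd.RangeIndex(len(df))
    try:
        df.to_csv(path)
    except OSError as exc:
        raise OSError(f"cannot write tracking table to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

@dataclass
class TrialEntry:
    """One trial of the cohort design, as recorded in the manifest."""

    mouse_id: str
    session_index: int
    object_condition: str
    pairing_condition: str
    trial_order_within_session: int
    excluded: bool = False
    files: dict = field(default_factory=dict)  # side -> relative path or None

    def __post_init__(self) -> None:
        validate_conditions(self.object_condition, self.pairing_condition)

    @property
    def key(self) -> tuple:
        return (
            self.mouse_id,
            self.session_index,
            self.object_condition,
            self.pairing_condition,
        )

    def to_dict(self) -> dict:
        return {
            "mouse_id": self.mouse_id,
            "session_index": self.session_index,
            "object_condition": self.object_condition,
            "pairing_condition": self.pairing_condition,
            "trial_order_within_session": self.trial_order_within_session,
            "excluded": self.excluded,
            "files": dict(self.files),
        }


@dataclass
class Manifest:
    """Cohort design: trial list plus the conventions analysis must not guess."""

    timeline: TrialTimeline
    toward_threat_sign: dict
    trials: list
    interval_law: dict = field(default_factory=dict)
    seed: int | None = None
    base_dir: Path | None = None  # directory the file paths are relative to

    def __post_init__(self) -> None:
        seen = set()
        for t in self.trials:
            if t.key in seen:
                raise ManifestError(f"duplicate trial entry {t.key}")
            seen.add(t.key)

    @property
    def mouse_ids(self) -> tuple:
        return tuple(sorted({t.mouse_id for t in self.trials}))

    @property
    def n_mice(self) -> int:
        return len(self.mouse_ids)

    def active_trials(self) -> list:
        return [t for t in self.trials if not t.excluded]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_dict() for t in self.trials])

    def resolve(self, relpath: str) -> Path:
        base = self.base_dir if self.base_dir is not None else Path(".")
        return base / relpath

    def check_files(self) -> list:
        """Return the list of referenced-but-missing tracking files."""
        missing = []
        for t in self.active_trials():
            for side, rel in t.files.items():
                if rel is not None and not self.resolve(rel).exists():
                    missing.append((t.key, side, rel))
        return missing

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "seed": self.seed,
            "timeline": self.timeline.to_dict(),
            "toward_threat_sign": dict(self.toward_threat_sign),
            "interval_law": dict(self.interval_law),
            "trials": [t.to_dict() for t in self.trials],
        }


def write_manifest(manifest: Manifest, path) -> None:
    path = Path(path)
    doc = manifest.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def read_manifest(path, check_files: bool = False) -> Manifest:
    """Parse and validate a cohort manifest (YAML or JSON by extension)."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest file not found: {path}")
    text = path.read_text()
    try:
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ManifestError(f"{path}: cannot parse manifest: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ManifestError(f"{path}: manifest must be a mapping")
    timeline = (
        TrialTimeline.from_dict(doc["timeline"]) if "timeline" in doc else TrialTimeline()
    )
    sign = {str(k): float(v) for k, v in (doc.get("toward_threat_sign") or {}).items()}
    trials = []
    for i, row in enumerate(doc.get("trials") or []):
        try:
            trials.append(
                TrialEntry(
                    mouse_id=str(row["mouse_id"]),
                    session_index=int(row["session_index"]),
                    object_condition=str(row["object_condition"]),
                    pairing_condition=str(row["pairing_condition"]),
                    trial_order_within_session=int(row["trial_order_within_session"]),
                    excluded=bool(row.get("excluded", False)),
                    files=dict(row.get("files") or {}),
                )
            )
        except (KeyError, ValueError, ParameterError) as exc:
            raise ManifestError(f"{path}: invalid trial entry #{i}: {exc}") from exc
    manifest = Manifest(
        timeline=timeline,
        toward_threat_sign=sign,
        trials=trials,
        interval_law=dict(doc.get("interval_law") or {}),
        seed=doc.get("seed"),
        base_dir=path.parent,
    )
    if check_files:
        missing = manifest.check_files()
        if missing:
            raise ManifestError(f"{path}: missing tracking files: {missing[:5]}")
    return manifest
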