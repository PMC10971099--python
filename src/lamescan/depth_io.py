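"""I/O for the overhead time-of-flight camera's CSV depth dialect.

The corridor camera streams distance measurements (metres) that are stored
one frame per CSV row: 23,232 comma-separated values that reshape row-major
into a 132 x 176 raster.  Ground-truth annotations (bounding boxes, track
identities, lameness labels) travel as JSON-lines, one record per frame.

Values are kept in metres end to end; zero-distance dropout pixels are
preserved as-is so that downstream stages can decide how to treat them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Raster geometry of the sensor.
FRAME_ROWS = 132
FRAME_COLS = 176
FRAME_PIXELS = FRAME_ROWS * FRAME_COLS

#: Labels recognised in ground-truth records.
COW_LABELS = ("lame", "sound")
NOISE_LABELS = ("human",)


class MalformedFrameError(ValueError):
    """A CSV row does not parse into a full 132 x 176 depth frame."""


@dataclass
class DepthFrame:
    """One depth raster: camera-to-surface distance in metres per pixel.

    Parameters
    ----------
    index
        Non-negative frame number within the session.
    values
        ``(132, 176)`` array of finite, non-negative distances in metres.
    session
        Opaque session tag (e.g. ``"2022-09-03-AM"``).
    """

    index: int
    values: np.ndarray
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (FRAME_ROWS, FRAME_COLS):
            raise ValueError(
                f"depth frame must be {FRAME_ROWS}x{FRAME_COLS}, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"frame {self.index}: non-finite depth values")
        if np.any(self.values < 0):
            raise ValueError(f"frame {self.index}: negative depth values")
        if self.index < 0:
            raise ValueError("frame index must be non-negative")


def read_depth_csv(path: str | Path, session: str = "") -> list[DepthFrame]:
    """Read a headerless depth CSV: one frame per row, 23,232 fields.

    Row ``k`` becomes the frame with index ``k``; fields fill the raster
    row-major (all 176 columns of raster row 0, then raster row 1, ...).

    Raises
    ------
    MalformedFrameError
        If a row has the wrong field count or a non-numeric field; the
        message names the offending row (and column).
    """
    path = Path(path)
    frames: list[DepthFrame] = []
    with path.open("r", newline="") as fh:
        for row_idx, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != FRAME_PIXELS:
                raise MalformedFrameError(
                    f"row {row_idx}: expected {FRAME_PIXELS} fields, "
                    f"got {len(fields)}"
                )
            try:
                flat = np.array(fields, dtype=float)
            except ValueError:
                col = _first_bad_field(fields)
                raise MalformedFrameError(
                    f"row {row_idx}, field {col}: "
                    f"non-numeric value {fields[col]!r}"
                ) from None
            frames.append(
                DepthFrame(
                    index=row_idx,
                    values=flat.reshape(FRAME_ROWS, FRAME_COLS),
                    session=session,
                )
            )
    return frames


def _first_bad_field(fields: Sequence[str]) -> int:
    for i, f in enumerate(fields):
        try:
            float(f)
        except ValueError:
            return i
    return -1  # pragma: no cover - caller only reaches this on a bad row


def write_depth_csv(frames: Iterable[DepthFrame], path: str | Path) -> Path:
    """Write frames in the CSV dialect that :func:`read_depth_csv` inverts.

    Values are written with six decimals, so a round trip preserves them
    to 1e-6 m (sub-millimetre, below sensor resolution).
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        for frame in frames:
            flat = frame.values.reshape(-1)
            fh.write(",".join(f"{v:.6f}" for v in flat))
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Ground truth (JSON-lines)
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthObject:
    """One annotated object in one frame.

    ``box`` is ``[x_min, y_min, x_max, y_max]`` in 0-based half-open pixel
    coordinates (x = column, y = row).  ``body_offset`` is simulator
    metadata: the column of the animal's tail end in frame coordinates
    (possibly negative), which locates the visible window of the full
    dorsal profile.
    """

    box: tuple[int, int, int, int]
    track_id: int
    label: str
    body_offset: int | None = None

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (0 <= x0 < x1 <= FRAME_COLS and 0 <= y0 < y1 <= FRAME_ROWS):
            raise ValueError(f"box {self.box} outside the {FRAME_ROWS}x{FRAME_COLS} frame")
        if self.label not in COW_LABELS + NOISE_LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def is_cow(self) -> bool:
        return self.label in COW_LABELS


@dataclass
class FrameGroundTruth:
    frame_index: int
    objects: list[GroundTruthObject] = field(default_factory=list)


def write_ground_truth(records: Iterable[FrameGroundTruth], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            payload = {
                "frame_index": rec.frame_index,
                "objects": [
                    {
                        "box": list(obj.box),
                        "track_id": obj.track_id,
                        "label": obj.label,
                        **(
                            {"body_offset": obj.body_offset}
                            if obj.body_offset is not None
                            else {}
                        ),
                    }
                    for obj in rec.objects
                ],
            }
            fh.write(json.dumps(payload) + "\n")
    return path


def read_ground_truth(path: str | Path) -> list[FrameGroundTruth]:
    records: list[FrameGroundTruth] = []
    with Path(path).open("r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            payload = json.loads(line)
            records.append(
                FrameGroundTruth(
                    frame_index=int(payload["frame_index"]),
                    objects=[
                        GroundTruthObject(
                            box=tuple(obj["box"]),
                            track_id=int(obj["track_id"]),
                            label=obj["label"],
                            body_offset=obj.get("body_offset"),
                        )
                        for obj in payload["objects"]
                    ],
                )
            )
    return records


@dataclass
class SessionManifest:
    """Bookkeeping for one milking-passage session."""

    frames: list[int]
    cow_count: int
    ground_truth: list[FrameGroundTruth] | None = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frame indices must be strictly increasing")
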