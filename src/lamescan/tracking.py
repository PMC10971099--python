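"""IOU-based multi-object tracking of detected cows.

Association is by bounding-box Intersection over Union between the current
frame's detections and each live track's last box: pairs at or above the
IOU threshold keep their track identity (the track's current box becomes
the matched detection's box - no motion model), unmatched detections open
new tracks numbered sequentially 1, 2, 3, ..., and a track that goes
unmatched for ``patience`` consecutive frames is closed.  Matching is
greedy in descending IOU with fully specified tie-breaks (lower track id,
then leftmost detection), so identical inputs always produce identical
assignments; Hungarian (optimal) assignment is available behind a flag.

Completed tracks can be archived to disk, one folder per track id holding
that cow's masked depth frames, mirroring how the deployed system files
each animal's frames for later feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import depth_io
from .depth_io import DepthFrame
from .detection import InstanceRegion, extract_depth_region

Box = Sequence[float]


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over Union of two half-open pixel boxes, in [0, 1]."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("degenerate (zero-area) box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


@dataclass
class Track:
    """Persistent identity: ordered (frame index, region) observations."""

    track_id: int
    observations: list[tuple[int, InstanceRegion]] = field(default_factory=list)

    @property
    def last_box(self) -> tuple[int, int, int, int]:
        return self.observations[-1][1].box

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.observations]

    def append(self, frame_index: int, region: InstanceRegion) -> None:
        if self.observations and frame_index <= self.observations[-1][0]:
            raise ValueError("frame indices within a track must increase")
        self.observations.append((frame_index, region))


class IouTracker:
    """Stateful frame-by-frame tracker.

    Parameters
    ----------
    iou_threshold
        Minimum IOU for a detection to inherit a track id (default 0.5,
        the conventional MOT value; slow corridor traffic keeps true
        inter-frame IOU well above it).
    patience
        Number of consecutive missed frames after which a track closes
        (default 1: a single miss closes the track, matching a corridor
        where visible animals are detected every frame).
    assignment
        ``"greedy"`` (deterministic descending-IOU) or ``"hungarian"``.
    """

    def __init__(
        self,
        iou_threshold: float = 0.5,
        patience: int = 1,
        assignment: str = "greedy",
    ):
        if not 0.0 < iou_threshold <= 1.0:
            raise ValueError("iou_threshold must lie in (0, 1]")
        if patience < 1:
            raise ValueError("patience must be at least 1")
        if assignment not in ("greedy", "hungarian"):
            raise ValueError("assignment must be 'greedy' or 'hungarian'")
        self.iou_threshold = iou_threshold
        self.patience = patience
        self.assignment = assignment
        self.next_id = 1
        self._active: list[Track] = []
        self._misses: dict[int, int] = {}
        self._closed: list[Track] = []

    @property
    def tracks(self) -> list[Track]:
        """All tracks seen so far, ordered by id."""
        return sorted(self._active + self._closed, key=lambda t: t.track_id)

    def _match_greedy(
        self, ious: np.ndarray, regions: Sequence[InstanceRegion]
    ) -> list[tuple[int, int]]:
        pairs = [
            (ti, ri)
            for ti in range(ious.shape[0])
            for ri in range(ious.shape[1])
            if ious[ti, ri] >= self.iou_threshold
        ]
        pairs.sort(
            key=lambda p: (
                -ious[p],
                self._active[p[0]].track_id,
                regions[p[1]].box[0],
                p[1],
            )
        )
        used_t: set[int] = set()
        used_r: set[int] = set()
        matches = []
        for ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            matches.append((ti, ri))
            used_t.add(ti)
            used_r.add(ri)
        return matches

    def _match_hungarian(self, ious: np.ndarray) -> list[tuple[int, int]]:
        ti, ri = linear_sum_assignment(-ious)
        return [
            (int(t), int(r))
            for t, r in zip(ti, ri)
            if ious[t, r] >= self.iou_threshold
        ]

    def step(
        self, frame_index: int, regions: Sequence[InstanceRegion]
    ) -> list[int]:
        """Assign track ids to this frame's cow regions.

        Returns the assigned ids aligned with ``regions``; new tracks get
        the next sequential ids in detection order.
        """
        for r in regions:
            if r.kind != "cow":
                raise ValueError(
                    "tracker input must be cow regions; run noise_filter first"
                )
        ious = np.zeros((len(self._active), len(regions)))
        for ti, track in enumerate(self._active):
            for ri, region in enumerate(regions):
                ious[ti, ri] = iou(track.last_box, region.box)

        if self.assignment == "greedy":
            matches = self._match_greedy(ious, regions)
        else:
            matches = self._match_hungarian(ious)

        assigned: dict[int, int] = {}
        matched_tracks: set[int] = set()
        for ti, ri in matches:
            track = self._active[ti]
            track.append(frame_index, regions[ri])
            assigned[ri] = track.track_id
            matched_tracks.add(ti)
            self._misses[track.track_id] = 0

        survivors: list[Track] = []
        for ti, track in enumerate(self._active):
            if ti in matched_tracks:
                survivors.append(track)
                continue
            self._misses[track.track_id] = self._misses.get(track.track_id, 0) + 1
            if self._misses[track.track_id] >= self.patience:
                self._closed.append(track)
            else:
                survivors.append(track)
        self._active = survivors

        for ri, region in enumerate(regions):
            if ri in assigned:
                continue
            track = Track(track_id=self.next_id)
            self.next_id += 1
            track.append(frame_index, region)
            self._active.append(track)
            assigned[ri] = track.track_id
        self._active.sort(key=lambda t: t.track_id)
        return [assigned[ri] for ri in range(len(regions))]


def track_frames(
    frame_regions: Iterable[tuple[int, Sequence[InstanceRegion]]],
    iou_threshold: float = 0.5,
    patience: int = 1,
    assignment: str = "greedy",
) -> tuple[list[Track], list[tuple[int, int, int]]]:
    """Track a whole sequence; returns (tracks, assignment triples).

    The triples are ``(frame_index, region_ordinal, track_id)``.
    """
    tracker = IouTracker(iou_threshold, patience, assignment)
    assignments = []
    for frame_index, regions in frame_regions:
        ids = tracker.step(frame_index, regions)
        assignments.extend(
            (frame_index, ri, tid) for ri, tid in enumerate(ids)
        )
    return tracker.tracks, assignments


# ---------------------------------------------------------------------------
# Per-track archiving
# ---------------------------------------------------------------------------

def archive_tracks(
    tracks: Iterable[Track],
    frames: Mapping[int, DepthFrame],
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Save each track into its own folder named after the track id.

    Every observation becomes a single-row depth CSV of the masked depth
    grid (mask x depth), alongside a JSON manifest of frames, boxes and
    pixel sums.  Refuses to overwrite an existing non-empty id folder
    unless ``force``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    track_ids = []
    for track in tracks:
        tdir = out_dir / str(track.track_id)
        if tdir.exists() and any(tdir.iterdir()) and not force:
            raise FileExistsError(
                f"track folder {tdir} exists and is not empty (use force)"
            )
        tdir.mkdir(exist_ok=True)
        manifest = {"track_id": track.track_id, "observations": []}
        for frame_index, region in track.observations:
            masked = extract_depth_region(frames[frame_index], region)
            name = f"frame_{frame_index:06d}.csv"
            depth_io.write_depth_csv(
                [DepthFrame(index=frame_index, values=masked)], tdir / name
            )
            manifest["observations"].append(
                {
                    "frame_index": frame_index,
                    "file": name,
                    "box": list(region.box),
                    "pixel_sum": region.pixel_sum,
                }
            )
        (tdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        track_ids.append(track.track_id)
    (out_dir / "tracks.json").write_text(json.dumps({"track_ids": track_ids}))
    return out_dir


def load_archive(
    archive_dir: str | Path,
) -> dict[int, list[tuple[int, np.ndarray, tuple[int, int, int, int]]]]:
    """Reload an archive: track id -> [(frame_index, masked grid, box)]."""
    archive_dir = Path(archive_dir)
    listing = json.loads((archive_dir / "tracks.json").read_text())
    out: dict[int, list] = {}
    for tid in listing["track_ids"]:
        tdir = archive_dir / str(tid)
        manifest = json.loads((tdir / "manifest.json").read_text())
        obs = []
        for entry in manifest["observations"]:
            frame = depth_io.read_depth_csv(tdir / entry["file"])[0]
            obs.append(
                (entry["frame_index"], frame.values, tuple(entry["box"]))
            )
        out[tid] = obs
    return out
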