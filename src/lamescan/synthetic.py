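"""Synthetic overhead depth scenes of a dairy corridor with known ground truth.

The simulator emulates the acquisition geometry of an overhead time-of-flight
camera mounted 3 m above a flat concrete passage: background pixels sit at
the camera height, and each cow is a smooth height surface (1.0-1.5 m tall)
traversing the field of view along the corridor axis.  Lame cows carry an
arched (mid-body depressed) dorsal line whose maximum falls below the 1.2 m
boundary; sound cows carry a straight dorsal line above it.  Occasional
human-sized blobs reproduce the farmer walking the passage - tall but with a
footprint small enough that the pixel-sum noise filter rejects them.

Cows are *separable* surfaces, ``height(r, c) = dorsal(c) * cross(r)`` with
``cross`` peaking at exactly 1 on the lane row, so the per-column maximum of
a rendered cow equals its dorsal profile analytically.  That makes the
feature extractor's oracle exact: on a noise-free scene the backbone profile
must reproduce :func:`dorsal_profile` to machine precision.

Visibility convention: an object is rendered (and ground-truthed) only while
at least ``min_visible_cols`` columns of its body are inside the frame, the
same way multi-object-tracking benchmarks gate ground truth on visibility.
This keeps every ground-truth footprint large enough to clear the detector's
minimum area and the pixel-sum threshold, so detector and ground truth agree
frame-by-frame by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .depth_io import (
    FRAME_COLS,
    FRAME_ROWS,
    DepthFrame,
    FrameGroundTruth,
    GroundTruthObject,
)

#: Dorsal-height boundary (m) separating lame from sound templates.
LAME_CUTOFF_M = 1.2

#: Fraction of body length used by the nose/tail taper of the dorsal curve.
TAPER_FRAC = 0.15

#: Maximum relative mid-body depression at arch = 1.
ARCH_DEPTH_FRAC = 0.25

# Human blob constants: tall, narrow footprint (13 rows x 9 cols = 117 px,
# pixel sum a few hundred metre-pixels, far below the 4000 filter).
HUMAN_HEIGHT_M = 1.7
HUMAN_COLS = 9
HUMAN_ROWS = 13
HUMAN_SPEED = 6

#: First track id handed to human blobs (cows count up from 1).
_HUMAN_ID_BASE = 1001


class SceneConfigurationError(ValueError):
    """The requested scene violates a simulator assumption."""


@dataclass(frozen=True)
class CowTemplate:
    """Parametric cow body used by the renderer.

    Parameters
    ----------
    peak_height_m
        Maximum dorsal height above the floor (m).  Templates below
        :data:`LAME_CUTOFF_M` are labelled lame, the rest sound.
    arch
        Arch coefficient in [0, 1]: 0 gives a straight (flat) dorsal line,
        1 depresses the mid-body by ``ARCH_DEPTH_FRAC`` relative to the
        shoulder/hip peaks.
    length_px, width_px
        Body extent in columns / rows.  The default length exceeds the
        176-column frame so full-width bounding boxes arise mid-traversal.
    speed_px_per_frame
        Horizontal displacement per frame along the corridor.
    """

    peak_height_m: float
    arch: float = 0.0
    length_px: int = 240
    width_px: int = 57
    speed_px_per_frame: int = 8

    def __post_init__(self) -> None:
        if self.peak_height_m <= 0:
            raise ValueError("peak_height_m must be positive")
        if not 0.0 <= self.arch <= 1.0:
            raise ValueError("arch must lie in [0, 1]")
        if self.length_px < 2 or self.width_px < 3:
            raise ValueError("degenerate body dimensions")
        if self.speed_px_per_frame <= 0:
            raise ValueError("speed must be positive")

    @property
    def label(self) -> str:
        """Lameness label implied by the 1.2 m dorsal-height convention."""
        return "lame" if self.peak_height_m < LAME_CUTOFF_M else "sound"

    @property
    def half_width(self) -> int:
        return self.width_px // 2


@dataclass(frozen=True)
class CowPlacement:
    template: CowTemplate
    entry_frame: int
    lane_row: int


@dataclass(frozen=True)
class HumanPlacement:
    entry_frame: int
    lane_row: int


@dataclass
class SceneConfig:
    """Full description of one synthetic corridor scene."""

    n_frames: int
    cows: list[CowPlacement] = field(default_factory=list)
    humans: list[HumanPlacement] = field(default_factory=list)
    camera_height_m: float = 3.0
    noise_sd_m: float = 0.0
    seed: int = 0
    min_visible_cols: int = 56

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be non-negative")
        for cow in self.cows:
            if cow.template.peak_height_m >= self.camera_height_m:
                raise ValueError(
                    "camera_height_m must exceed every cow peak height"
                )


def dorsal_profile(template: CowTemplate) -> np.ndarray:
    """Along-body dorsal height curve (length ``length_px``, metres).

    The curve is a tapered plateau (sine ramps over ``TAPER_FRAC`` of the
    body at nose and tail) multiplied by an arch depression - a smooth
    ``sin^2`` bump centred mid-body that lowers the back relative to the
    shoulder and hip.  The curve is renormalised so its discrete maximum
    equals ``peak_height_m`` exactly.
    """
    length = template.length_px
    t = (np.arange(length) + 0.5) / length
    edge = np.minimum(t, 1.0 - t)
    envelope = np.sin(0.5 * np.pi * np.clip(edge / TAPER_FRAC, 0.0, 1.0))
    sag = 1.0 - ARCH_DEPTH_FRAC * template.arch * np.sin(np.pi * t) ** 2
    raw = envelope * sag
    return template.peak_height_m * raw / raw.max()


def cross_profile(width_px: int) -> np.ndarray:
    """Transverse (row-wise) body shape: an elliptical dome peaking at 1.

    Returns ``2*(width_px//2) + 1`` samples; the centre sample is exactly 1
    so the rendered column maximum sits on the lane row.
    """
    half = width_px // 2
    dr = np.arange(-half, half + 1, dtype=float)
    return np.sqrt(1.0 - (dr / (half + 1)) ** 2)


def _cow_head(placement: CowPlacement, frame: int, min_visible: int) -> int:
    """Column just past the cow's nose at ``frame`` (head moves rightward)."""
    return min_visible + placement.template.speed_px_per_frame * (
        frame - placement.entry_frame
    )


def _cow_active(placement: CowPlacement, frame: int, min_visible: int) -> bool:
    if frame < placement.entry_frame:
        return False
    head = _cow_head(placement, frame, min_visible)
    tail = head - placement.template.length_px
    visible = min(head, FRAME_COLS) - max(tail, 0)
    return visible >= min_visible


def _human_x0(placement: HumanPlacement, frame: int) -> int:
    return 2 + HUMAN_SPEED * (frame - placement.entry_frame)


def _human_active(placement: HumanPlacement, frame: int) -> bool:
    if frame < placement.entry_frame:
        return False
    x0 = _human_x0(placement, frame)
    return x0 + HUMAN_COLS <= FRAME_COLS - 2


def _human_surface() -> np.ndarray:
    col = np.sin(np.pi * (np.arange(HUMAN_COLS) + 0.5) / HUMAN_COLS)
    row = np.sin(np.pi * (np.arange(HUMAN_ROWS) + 0.5) / HUMAN_ROWS)
    return HUMAN_HEIGHT_M * np.outer(row, col)


def _validate_lanes(config: SceneConfig) -> None:
    # Lane rows must keep the body inside the raster.
    for cow in config.cows:
        half = cow.template.half_width
        if cow.lane_row - half < 0 or cow.lane_row + half >= FRAME_ROWS:
            raise SceneConfigurationError(
                f"cow lane row {cow.lane_row} puts the body outside the frame"
            )
    for human in config.humans:
        half = HUMAN_ROWS // 2
        if human.lane_row - half < 0 or human.lane_row + half >= FRAME_ROWS:
            raise SceneConfigurationError(
                f"human lane row {human.lane_row} outside the frame"
            )
    # The tracker assumes no occlusion: concurrently active cows must keep
    # at least one background row between their lanes (8-connectivity).
    for i, a in enumerate(config.cows):
        for b in config.cows[i + 1 :]:
            concurrent = any(
                _cow_active(a, f, config.min_visible_cols)
                and _cow_active(b, f, config.min_visible_cols)
                for f in range(config.n_frames)
            )
            if not concurrent:
                continue
            gap = abs(a.lane_row - b.lane_row) - (
                a.template.half_width + b.template.half_width
            )
            if gap < 2:
                raise SceneConfigurationError(
                    f"cow lanes at rows {a.lane_row} and {b.lane_row} "
                    "overlap while both cows are in view"
                )


def render_scene(
    config: SceneConfig,
) -> tuple[list[DepthFrame], list[FrameGroundTruth]]:
    """Render a scene into depth frames plus exact ground truth.

    Background pixels sit at ``camera_height_m``; objects are painted as
    height surfaces (depth = camera height - height) and i.i.d. Gaussian
    sensor noise of SD ``noise_sd_m`` is added to every pixel.  Ground-truth
    boxes tightly bound each object's nonzero-height footprint.  The same
    config (seed included) reproduces the scene bit-for-bit.
    """
    _validate_lanes(config)
    rng = np.random.default_rng(config.seed)
    human_surface = _human_surface()

    frames: list[DepthFrame] = []
    truth: list[FrameGroundTruth] = []
    for f in range(config.n_frames):
        height = np.zeros((FRAME_ROWS, FRAME_COLS))
        objects: list[GroundTruthObject] = []

        for cow_id, cow in enumerate(config.cows, start=1):
            if not _cow_active(cow, f, config.min_visible_cols):
                continue
            tpl = cow.template
            head = _cow_head(cow, f, config.min_visible_cols)
            tail = head - tpl.length_px
            c0, c1 = max(tail, 0), min(head, FRAME_COLS)
            profile = dorsal_profile(tpl)[c0 - tail : c1 - tail]
            cross = cross_profile(tpl.width_px)
            r0 = cow.lane_row - tpl.half_width
            r1 = cow.lane_row + tpl.half_width + 1
            patch = cross[:, None] * profile[None, :]
            height[r0:r1, c0:c1] = np.maximum(height[r0:r1, c0:c1], patch)
            objects.append(
                GroundTruthObject(
                    box=(c0, r0, c1, r1),
                    track_id=cow_id,
                    label=tpl.label,
                    body_offset=tail,
                )
            )

        for k, human in enumerate(config.humans):
            if not _human_active(human, f):
                continue
            x0 = _human_x0(human, f)
            r0 = human.lane_row - HUMAN_ROWS // 2
            r1, x1 = r0 + HUMAN_ROWS, x0 + HUMAN_COLS
            height[r0:r1, x0:x1] = np.maximum(
                height[r0:r1, x0:x1], human_surface
            )
            objects.append(
                GroundTruthObject(
                    box=(x0, r0, x1, r1),
                    track_id=_HUMAN_ID_BASE + k,
                    label="human",
                )
            )

        depth = config.camera_height_m - height
        if config.noise_sd_m > 0:
            depth = depth + rng.normal(
                0.0, config.noise_sd_m, size=depth.shape
            )
        np.clip(depth, 0.0, None, out=depth)
        frames.append(DepthFrame(index=f, values=depth))
        truth.append(FrameGroundTruth(frame_index=f, objects=objects))
    return frames, truth


# ---------------------------------------------------------------------------
# Benchmark suites
# ---------------------------------------------------------------------------

#: Lane rows for single-cow scenes (body half-width 28 fits rows 2..130).
_SUITE_LANES = (30, 66, 102)


@dataclass(frozen=True)
class LabelledScene:
    """One single-cow scene with its template-level lameness label."""

    scene_id: int
    config: SceneConfig
    template: CowTemplate
    label: str


@dataclass
class BenchmarkSuite:
    train: list[LabelledScene]
    test: list[LabelledScene]

    @property
    def scenes(self) -> list[LabelledScene]:
        return self.train + self.test


def make_benchmark_suite(
    seed: int,
    n_lame: int,
    n_sound: int,
    *,
    n_frames: int = 24,
    noise_sd_m: float = 0.01,
    test_fraction: float = 0.25,
) -> BenchmarkSuite:
    """Generate a labelled set of single-cow corridor scenes.

    Lame cows draw dorsal peaks from U(0.95, 1.05) m with pronounced arches;
    sound cows from U(1.35, 1.45) m with near-straight backs - a +/-0.15 m
    margin either side of the 1.2 m boundary, about what separates a clearly
    arched-back cow from an upright one.  Each cow traverses its own scene
    (single corridor, no occlusion) under moderate sensor noise.  The
    train/test split is stratified by cow, never by frame, so no animal
    contributes frames to both splits.
    """
    if n_lame < 1 or n_sound < 1:
        raise ValueError("need at least one cow per class")
    rng = np.random.default_rng(seed)

    def build(label: str, count: int, start_id: int) -> list[LabelledScene]:
        scenes = []
        for i in range(count):
            if label == "lame":
                peak = rng.uniform(0.95, 1.05)
                arch = rng.uniform(0.5, 1.0)
            else:
                peak = rng.uniform(1.35, 1.45)
                arch = rng.uniform(0.0, 0.15)
            tpl = CowTemplate(peak_height_m=peak, arch=arch)
            config = SceneConfig(
                n_frames=n_frames,
                cows=[
                    CowPlacement(
                        template=tpl,
                        entry_frame=0,
                        lane_row=_SUITE_LANES[i % len(_SUITE_LANES)],
                    )
                ],
                noise_sd_m=noise_sd_m,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scenes.append(
                LabelledScene(
                    scene_id=start_id + i,
                    config=config,
                    template=tpl,
                    label=label,
                )
            )
        return scenes

    lame = build("lame", n_lame, 0)
    sound = build("sound", n_sound, n_lame)

    def split(scenes: list[LabelledScene]) -> tuple[list, list]:
        order = rng.permutation(len(scenes))
        n_test = max(1, round(test_fraction * len(scenes)))
        test_idx = set(order[:n_test].tolist())
        train = [s for i, s in enumerate(scenes) if i not in test_idx]
        test = [s for i, s in enumerate(scenes) if i in test_idx]
        return train, test

    lame_train, lame_test = split(lame)
    sound_train, sound_test = split(sound)
    return BenchmarkSuite(
        train=lame_train + sound_train, test=lame_test + sound_test
    )
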