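"""Backbone height-profile feature extraction.

A tracked cow's masked depth frame is turned into a 176-long feature
vector in four steps:

1. keep only frames whose bounding box spans the full 176-column width
   (the cow fills the corridor axis, so every column sees the body);
2. re-express depth as height above the floor,
   ``height = distance - depth``, clamped below at zero;
3. smooth the height field with a 2-D Gaussian (sigma in pixels);
4. take the per-column maximum over the 132 rows - the highest dorsal
   point at each position along the corridor, i.e. the backbone line.

A sound cow's backbone line is straight and predominantly above 1.2 m; a
lame cow's is arched and predominantly below it, which is what the
classifiers downstream exploit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .depth_io import FRAME_COLS, DepthFrame
from .detection import InstanceRegion, extract_depth_region
from .tracking import Track

#: Reference distance (m) from which heights are measured.  The sensor's
#: calibrated floor reference, slightly below the 3.0 m mounting height;
#: override with the true camera height when working with simulated scenes.
DEFAULT_DISTANCE_M = 2.8


@dataclass(frozen=True)
class GaussianSpec:
    """Discrete 2-D Gaussian filter: SD ``sigma`` (px) and kernel radius.

    Radius defaults to ``ceil(3 * sigma)``; the discrete kernel is
    normalised to unit sum, so constant fields pass through unchanged.
    """

    sigma: float = 1.0
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.radius is not None and self.radius < 1:
            raise ValueError("radius must be at least 1")

    @property
    def effective_radius(self) -> int:
        return self.radius if self.radius is not None else math.ceil(3 * self.sigma)

    def kernel(self) -> np.ndarray:
        """The normalised discrete kernel (for inspection/tests)."""
        r = self.effective_radius
        ax = np.arange(-r, r + 1, dtype=float)
        xx, yy = np.meshgrid(ax, ax)
        k = np.exp(-(xx**2 + yy**2) / (2 * self.sigma**2))
        return k / k.sum()


@dataclass
class HeightField:
    """Heights above the floor (m), zero outside the cow mask."""

    values: np.ndarray
    frame_index: int = -1


@dataclass
class BackboneProfile:
    """Per-column maximum heights (m): the cow's dorsal line, length 176."""

    heights: np.ndarray
    track_id: int | None = None
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)

    @property
    def max_height(self) -> float:
        return float(self.heights.max())


def select_full_width_frames(
    track: Track,
) -> list[tuple[int, InstanceRegion]]:
    """Observations whose bounding box spans all 176 columns, in order."""
    return [
        (f, r)
        for f, r in track.observations
        if r.box[0] == 0 and r.box[2] == FRAME_COLS
    ]


def height_transform(
    masked_depth: np.ndarray,
    distance: float = DEFAULT_DISTANCE_M,
    mask: np.ndarray | None = None,
    frame_index: int = -1,
) -> HeightField:
    """Depth-to-height transform: ``distance - depth`` inside the mask.

    Outside-mask pixels are zero; in-mask heights are clamped below at
    zero (a pixel measured below the floor reference is sensor noise).
    If ``mask`` is omitted it is inferred from the nonzero pixels of
    ``masked_depth``.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    masked_depth = np.asarray(masked_depth, dtype=float)
    if mask is None:
        mask = masked_depth > 0
    heights = np.where(mask, np.clip(distance - masked_depth, 0.0, None), 0.0)
    return HeightField(values=heights, frame_index=frame_index)


def gaussian_smooth(field: HeightField, spec: GaussianSpec) -> HeightField:
    """2-D Gaussian smoothing with reflective borders; shape unchanged."""
    smoothed = ndimage.gaussian_filter(
        field.values,
        sigma=spec.sigma,
        mode="reflect",
        radius=spec.effective_radius,
    )
    return HeightField(values=smoothed, frame_index=field.frame_index)


def backbone_profile(
    field: HeightField,
    track_id: int | None = None,
) -> BackboneProfile:
    """Per-column maximum over rows: the highest dorsal point per column.

    The maximum is taken over the whole column including background zeros;
    cow heights are positive, so in-body columns report the dorsal surface
    and out-of-body columns report zero.
    """
    return BackboneProfile(
        heights=field.values.max(axis=0),
        track_id=track_id,
        frame_index=field.frame_index,
    )


def featurize_track(
    track: Track,
    frames: Mapping[int, DepthFrame],
    distance: float = DEFAULT_DISTANCE_M,
    spec: GaussianSpec = GaussianSpec(),
) -> list[BackboneProfile]:
    """Full feature chain for one track.

    Full-width frames only; each surviving frame yields one length-176
    backbone profile.  An empty selection (the cow never filled the frame)
    returns an empty list and emits a warning.
    """
    if not track.observations:
        raise ValueError("empty track")
    selected = select_full_width_frames(track)
    if not selected:
        warnings.warn(
            f"track {track.track_id}: no full-width frames; no features",
            stacklevel=2,
        )
        return []
    profiles = []
    for frame_index, region in selected:
        masked = extract_depth_region(frames[frame_index], region)
        field = height_transform(
            masked, distance=distance, mask=region.mask, frame_index=frame_index
        )
        field = gaussian_smooth(field, spec)
        profiles.append(backbone_profile(field, track_id=track.track_id))
    return profiles


def feature_table(
    profiles: Sequence[BackboneProfile],
    labels: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Tabulate profiles: track_id, frame_index, h_000..h_175 [, label]."""
    rows = []
    for p in profiles:
        row = {"track_id": p.track_id, "frame_index": p.frame_index}
        row.update({f"h_{j:03d}": p.heights[j] for j in range(len(p.heights))})
        if labels is not None:
            row["label"] = labels.get(p.track_id)
        rows.append(row)
    return pd.DataFrame(rows)
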