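"""Per-frame cow instance detection on depth rasters.

The deployed system delegates instance segmentation to a fine-tuned deep
detector; this module abstracts that step behind a detector interface
(any callable mapping a depth frame to binary masks) and supplies two
implementations:

* :func:`reference_detect` - a height-threshold / connected-component
  detector that is exact on simulated scenes and serves as the test
  reference;
* :class:`MaskDirectoryDetector` - loads externally produced mask rasters
  (e.g. exported from a trained segmentation model) from disk.

Whatever produces the masks, the downstream chain is the same: regions are
summarised (tight box + pixel sum), the pixel-sum noise filter discards
human-sized false detections (a region is kept only when its summed masked
depth exceeds the threshold, default 4000 metre-pixels), and the surviving
masks are multiplied into the depth raster to extract per-cow depth regions.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Protocol

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .depth_io import FRAME_COLS, FRAME_ROWS, DepthFrame

#: Default pixel-sum threshold (metre-pixels): regions with summed masked
#: depth strictly greater than this are kept as cows.
NOISE_THRESHOLD = 4000.0

#: Default minimum connected-component area (pixels) to suppress speckle.
MIN_COMPONENT_AREA = 50

#: 8-connectivity structuring element for component labelling.
_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class DetectorInterface(Protocol):
    """Contract for pluggable detectors: frame in, binary masks out."""

    def __call__(self, frame: DepthFrame) -> list[np.ndarray]: ...


@dataclass(frozen=True)
class InstanceRegion:
    """One detected object in one frame.

    ``box`` is the tight ``[x_min, y_min, x_max, y_max]`` bound of the mask
    (half-open); ``pixel_sum`` is the sum of the masked depth values in
    metre-pixels - the quantity the noise filter thresholds.
    """

    frame_index: int
    mask: np.ndarray
    box: tuple[int, int, int, int]
    pixel_sum: float
    kind: str = "cow"

    @classmethod
    def from_mask(
        cls, frame: DepthFrame, mask: np.ndarray, kind: str = "cow"
    ) -> "InstanceRegion":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (FRAME_ROWS, FRAME_COLS):
            raise ValueError(f"mask shape {mask.shape} does not match the frame")
        if not mask.any():
            raise ValueError("empty mask")
        return cls(
            frame_index=frame.index,
            mask=mask,
            box=mask_bbox(mask),
            pixel_sum=float(frame.values[mask].sum()),
            kind=kind,
        )

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open bounding box ``(x_min, y_min, x_max, y_max)``."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return (int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


def reference_detect(
    frame: DepthFrame,
    camera_height_m: float = 3.0,
    fg_delta_m: float = 0.3,
    min_area: int = MIN_COMPONENT_AREA,
) -> list[np.ndarray]:
    """Height-threshold detector: foreground is anything standing proud of
    the floor by more than ``fg_delta_m`` metres.

    8-connected foreground components of at least ``min_area`` pixels become
    masks, ordered largest first (ties by first raster pixel).
    """
    if fg_delta_m <= 0:
        raise ValueError("fg_delta_m must be positive")
    fg = (camera_height_m - frame.values) > fg_delta_m
    labels, n = ndimage.label(fg, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    order = sorted(
        (i for i in range(1, n + 1) if areas[i - 1] >= min_area),
        key=lambda i: (-areas[i - 1], int(np.argmax(labels.reshape(-1) == i))),
    )
    return [labels == i for i in order]


def detect_frame(
    frame: DepthFrame,
    detector: Callable[[DepthFrame], list[np.ndarray]] | None = None,
    **detector_kwargs,
) -> list[InstanceRegion]:
    """Run a detector and wrap its masks as :class:`InstanceRegion` objects."""
    if detector is None:
        masks = reference_detect(frame, **detector_kwargs)
    else:
        masks = detector(frame)
    return [InstanceRegion.from_mask(frame, m) for m in masks]


def noise_filter(
    regions: Iterable[InstanceRegion], threshold: float = NOISE_THRESHOLD
) -> list[InstanceRegion]:
    """Pixel-sum noise rejection.

    A region is kept as a cow only when its summed masked depth is strictly
    greater than ``threshold``; otherwise it is re-labelled ``rejected`` and
    excluded from tracking.  Order is preserved and the operation is
    idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [
        dataclasses.replace(
            r, kind="cow" if r.pixel_sum > threshold else "rejected"
        )
        for r in regions
    ]


def extract_depth_region(
    frame: DepthFrame, region: InstanceRegion
) -> np.ndarray:
    """Mask multiplication: depth values inside the mask, zero elsewhere."""
    return frame.values * region.mask


class MaskDirectoryDetector:
    """Detector fed by externally produced mask rasters.

    Masks live in one directory as 0/255 images named
    ``<frame_index>_<k>.png`` (any raster format imageio reads); ``k``
    orders multiple instances within a frame.
    """

    _NAME = re.compile(r"^(\d+)_(\d+)\.[A-Za-z]+$")

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        if not self.directory.is_dir():
            raise FileNotFoundError(f"mask directory {self.directory} not found")
        self._index: dict[int, list[Path]] = {}
        for path in sorted(self.directory.iterdir()):
            m = self._NAME.match(path.name)
            if m:
                self._index.setdefault(int(m.group(1)), []).append(path)
        for paths in self._index.values():
            paths.sort(key=lambda p: int(self._NAME.match(p.name).group(2)))

    def __call__(self, frame: DepthFrame) -> list[np.ndarray]:
        masks = []
        for path in self._index.get(frame.index, []):
            raster = np.asarray(iio.imread(path))
            if raster.ndim == 3:  # collapse any colour channels
                raster = raster[..., 0]
            if raster.shape != (FRAME_ROWS, FRAME_COLS):
                raise ValueError(
                    f"{path.name}: mask shape {raster.shape} does not match "
                    f"the {FRAME_ROWS}x{FRAME_COLS} frame"
                )
            masks.append(raster > 0)
        return masks


# ---------------------------------------------------------------------------
# Text serialisation of masks (run-length by row) for stage outputs
# ---------------------------------------------------------------------------

def mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    """Encode a binary mask as ``[row, start, stop]`` column runs."""
    runs = []
    for r in np.flatnonzero(mask.any(axis=1)):
        row = mask[r]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            runs.append([int(r), int(start), int(stop)])
    return runs


def runs_to_mask(runs: Iterable[Iterable[int]]) -> np.ndarray:
    mask = np.zeros((FRAME_ROWS, FRAME_COLS), dtype=bool)
    for r, start, stop in runs:
        mask[r, start:stop] = True
    return mask
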