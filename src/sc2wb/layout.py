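"""Array geometry, scan I/O and lane-profile extraction.

The microwell array geometry is known by fabrication (well diameter/depth,
pitch along and across the separation axis), so lanes are located from the
configured :class:`ArrayLayout` rather than detected from the image.  Each
well owns a rectangular bi-directional lane spanning
``separation_length_per_side`` on either side of the well center along the
separation axis and one transverse pitch across.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``; the separation axis runs along
  image columns.
* The axial coordinate is signed micrometers with 0 at the well center.
  "East" (the cytoplasmic side by default) is the positive axis; the mapping
  can be flipped via ``east_positive``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from sc2wb.errors import ConfigError, DataError

#: fraction of axial pixels at each lane end assumed band-free, used for
#: background estimation
FLANK_FRACTION = 0.10

#: robust scale factor converting a median absolute deviation to a normal s.d.
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class ArrayLayout:
    """Physical geometry of a microwell array and its pixel mapping.

    All lengths are micrometers.  Defaults follow the standard device:
    32 um wells, 40 um deep, 1 mm pitch along the separation axis and
    0.25 mm transverse, 0.5 mm separation length per side (1 mm total lane).

    Parameters
    ----------
    origin_px
        ``(row, col)`` pixel coordinates of the center of the first well
        (row 0, column 0 of the well grid).
    east_positive
        If True (default), "east" -- the cytoplasmic side -- maps to
        increasing axial coordinate.
    """

    well_diameter: float = 32.0
    well_depth: float = 40.0
    pitch_axis: float = 1000.0
    pitch_transverse: float = 250.0
    separation_length_per_side: float = 500.0
    pixel_size: float = 5.0
    origin_px: tuple[float, float] = (25.0, 100.0)
    east_positive: bool = True
    n_rows: int = 1
    n_cols: int = 1

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.well_diameter >= self.pitch_transverse:
            raise ConfigError(
                f"well_diameter ({self.well_diameter}) must be smaller than "
                f"pitch_transverse ({self.pitch_transverse})"
            )
        if self.separation_length_per_side > self.pitch_axis / 2:
            raise ConfigError(
                f"separation_length_per_side ({self.separation_length_per_side}) "
                f"exceeds pitch_axis/2 ({self.pitch_axis / 2}): adjacent lanes "
                "would overlap"
            )
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("n_rows and n_cols must be at least 1")

    @property
    def separation_length(self) -> float:
        """Total separation length L of one lane (both sides), in um."""
        return 2.0 * self.separation_length_per_side

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_center_px(self, row: int, col: int) -> tuple[float, float]:
        """Pixel ``(row, col)`` coordinates of the well at grid position."""
        r0, c0 = self.origin_px
        return (
            r0 + row * self.pitch_transverse / self.pixel_size,
            c0 + col * self.pitch_axis / self.pixel_size,
        )

    def image_shape(self) -> tuple[int, int]:
        """Smallest image shape containing every lane of the grid."""
        half_t = int(round(self.pitch_transverse / 2 / self.pixel_size))
        sep_px = int(round(self.separation_length_per_side / self.pixel_size))
        r_last, c_last = self.well_center_px(self.n_rows - 1, self.n_cols - 1)
        return (int(round(r_last)) + half_t, int(round(c_last)) + sep_px)

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayLayout":
        d = dict(d)
        if "origin_px" in d:
            d["origin_px"] = tuple(float(v) for v in d["origin_px"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid layout field: {exc}") from exc


@dataclass(frozen=True)
class LaneROI:
    """Rectangular pixel region of one bi-directional lane."""

    cell_id: int
    rows: tuple[int, int]  # half-open [start, stop)
    cols: tuple[int, int]  # half-open [start, stop)
    well_center_px: tuple[float, float]

    def slices(self) -> tuple[slice, slice]:
        return slice(*self.rows), slice(*self.cols)


@dataclass
class LaneProfile:
    """Axial fluorescence profile of one lane, background subtracted.

    ``positions`` are signed micrometers (0 at the well center, uniformly
    spaced at the pixel size); ``intensities`` are the transverse aggregate of
    the lane minus the estimated background.  ``well_mask`` is the axial
    interval covered by the microwell, excluded from peak fitting.
    """

    cell_id: int
    channel: str
    positions: np.ndarray
    intensities: np.ndarray
    background_sd: float
    well_mask: tuple[float, float]
    raw_intensities: np.ndarray = field(repr=False, default=None)
    background: float = 0.0

    def side_mask(self, side: str) -> np.ndarray:
        """Boolean mask selecting one signed half of the lane, well excluded."""
        if side == "east":
            return self.positions > self.well_mask[1]
        if side == "west":
            return self.positions < self.well_mask[0]
        raise ValueError(f"side must be 'east' or 'west', got {side!r}")


def read_scan(path: str | Path, channel_names: Sequence[str]) -> dict[str, np.ndarray]:
    """Read a (multi-page) TIFF scan into per-channel 2-D arrays.

    One page per channel, in the order of ``channel_names``.  Raises
    :class:`DataError` if the file is missing or the page count does not
    match the requested channels.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"scan file not found: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise DataError(f"expected a 2-D or stacked 2-D TIFF, got ndim={data.ndim}")
    if data.shape[0] != len(channel_names):
        raise DataError(
            f"channel-count mismatch: expected {len(channel_names)} channels "
            f"({list(channel_names)}), found {data.shape[0]} pages in {path}"
        )
    return {name: np.asarray(data[i], dtype=np.float64) for i, name in enumerate(channel_names)}


def write_scan(images: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-channel images as a multi-page float32 TIFF (one page per channel)."""
    stack = np.stack([np.asarray(img, dtype=np.float32) for img in images.values()])
    tifffile.imwrite(path, stack)


def lane_rois(layout: ArrayLayout) -> list[LaneROI]:
    """Segment the array into one rectangular lane region per well.

    Regions are pairwise disjoint by construction: each spans
    ``[-separation_length_per_side, +separation_length_per_side)`` along the
    axis (half-open at the east edge) and one transverse pitch across,
    centered on the well.  Cell ids enumerate the grid row-major.
    """
    sep_px = int(round(layout.separation_length_per_side / layout.pixel_size))
    half_t = int(round(layout.pitch_transverse / 2 / layout.pixel_size))
    rois = []
    for i in range(layout.n_rows):
        for j in range(layout.n_cols):
            r, c = layout.well_center_px(i, j)
            ri, ci = int(round(r)), int(round(c))
            rois.append(
                LaneROI(
                    cell_id=i * layout.n_cols + j,
                    rows=(ri - half_t, ri + half_t),
                    cols=(ci - sep_px, ci + sep_px),
                    well_center_px=(r, c),
                )
            )
    return rois


def extract_profile(
    image: np.ndarray,
    roi: LaneROI,
    layout: ArrayLayout,
    channel: str = "",
    aggregate: str = "sum",
) -> LaneProfile:
    """Collapse a lane region to a background-subtracted axial profile.

    The lane is aggregated across its transverse width (sum by default, which
    preserves total signal for AUC comparisons; mean optional).  Background is
    the median of the outermost ``FLANK_FRACTION`` of axial pixels on each
    lane end, assumed band-free; ``background_sd`` is the robust s.d.
    (1.4826 * MAD) of those flanks.
    """
    rs, cs = roi.slices()
    if rs.start < 0 or cs.start < 0 or rs.stop > image.shape[0] or cs.stop > image.shape[1]:
        raise DataError(
            f"lane ROI rows={roi.rows} cols={roi.cols} outside image of shape {image.shape}"
        )
    lane = np.asarray(image[rs, cs], dtype=np.float64)
    if aggregate == "sum":
        raw = lane.sum(axis=0)
    elif aggregate == "mean":
        raw = lane.mean(axis=0)
    else:
        raise ConfigError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")

    n = raw.size
    k = max(int(round(FLANK_FRACTION * n)), 2)
    flanks = np.concatenate([raw[:k], raw[-k:]])
    background = float(np.median(flanks))
    background_sd = float(MAD_TO_SD * np.median(np.abs(flanks - background)))

    col_center = roi.well_center_px[1]
    cols = np.arange(cs.start, cs.stop, dtype=np.float64)
    positions = (cols - col_center) * layout.pixel_size
    if not layout.east_positive:
        # report the axial coordinate in the east-positive convention
        positions = -positions[::-1]
        raw = raw[::-1]
    half_well = layout.well_diameter / 2.0
    return LaneProfile(
        cell_id=roi.cell_id,
        channel=channel,
        positions=positions,
        intensities=raw - background,
        background_sd=background_sd,
        well_mask=(-half_well, half_well),
        raw_intensities=raw,
        background=background,
    )
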