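"""Depth-intensity profiles of the inner plexiform layer.

The IPL is analysed along its *depth* axis, which runs from the retinal
ganglion layer (RGL) to the inner nuclear layer (INL).  All downstream
stages work in one canonical frame: depth index 0 is always the
RGL-adjacent edge of the region of interest, the last index the
INL-adjacent edge.  Orientation of the section in the image is resolved
here, at ingestion, and nowhere else.

Coordinates are 0-based; depth intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError

ORIENTATIONS = ("rgl-left", "rgl-right", "rgl-top", "rgl-bottom")


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular image region containing the IPL.

    ``x0, y0, width, height`` is a standard image rectangle (columns /
    rows).  ``orientation`` names the ROI edge that borders the retinal
    ganglion layer and thereby fixes the depth axis: horizontal for
    ``rgl-left`` / ``rgl-right``, vertical for ``rgl-top`` / ``rgl-bottom``.
    """

    x0: int
    y0: int
    width: int
    height: int
    orientation: str = "rgl-left"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must have positive width and height")
        if self.depth_extent < 8:
            # the SAC binning formula subdivides the sub-ON span 7 ways
            raise ValueError(
                f"ROI depth extent must be >= 8 px, got {self.depth_extent}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def depth_extent(self) -> int:
        """Pixels along the depth (RGL -> INL) axis."""
        if self.orientation in ("rgl-left", "rgl-right"):
            return self.width
        return self.height

    @property
    def across_extent(self) -> int:
        """Pixels across the depth axis (averaged over)."""
        if self.orientation in ("rgl-left", "rgl-right"):
            return self.height
        return self.width

    def check_in_bounds(self, image: np.ndarray) -> None:
        rows, cols = image.shape[:2]
        if self.x0 + self.width > cols or self.y0 + self.height > rows:
            raise BoundsError(
                f"ROI {self.x0},{self.y0},{self.width},{self.height} exceeds "
                f"image bounds {cols}x{rows}"
            )

    def extended(self, extra_px: int) -> "RegionOfInterest":
        """ROI grown by ``extra_px`` past the INL edge along the depth axis."""
        if extra_px < 0:
            raise ValueError("extra_px must be non-negative")
        if extra_px == 0:
            return self
        if self.orientation == "rgl-left":
            return RegionOfInterest(self.x0, self.y0, self.width + extra_px,
                                    self.height, self.orientation)
        if self.orientation == "rgl-right":
            if self.x0 - extra_px < 0:
                raise BoundsError("additional region extends past image edge")
            return RegionOfInterest(self.x0 - extra_px, self.y0,
                                    self.width + extra_px, self.height,
                                    self.orientation)
        if self.orientation == "rgl-top":
            return RegionOfInterest(self.x0, self.y0, self.width,
                                    self.height + extra_px, self.orientation)
        if self.y0 - extra_px < 0:
            raise BoundsError("additional region extends past image edge")
        return RegionOfInterest(self.x0, self.y0 - extra_px, self.width,
                                self.height + extra_px, self.orientation)


@dataclass(frozen=True)
class IntensityProfile:
    """Mean gray value at each depth position, RGL side first."""

    values: np.ndarray
    channel_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile values must be a non-empty 1-D array")

    def __len__(self) -> int:
        return int(self.values.size)


def extract_profile(image: np.ndarray, roi: RegionOfInterest,
                    channel_id: str = "") -> IntensityProfile:
    """Average a grayscale channel across the ROI into a depth profile.

    ``values[d]`` is the mean of all ROI pixels at depth offset ``d`` from
    the RGL-side edge; the image is reoriented per ``roi.orientation`` so
    index 0 is always the RGL side.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("extract_profile expects a single 2-D gray channel")
    roi.check_in_bounds(image)
    block = image[roi.y0:roi.y0 + roi.height,
                  roi.x0:roi.x0 + roi.width].astype(float)
    if roi.orientation in ("rgl-left", "rgl-right"):
        values = block.mean(axis=0)
        if roi.orientation == "rgl-right":
            values = values[::-1]
    else:
        values = block.mean(axis=1)
        if roi.orientation == "rgl-bottom":
            values = values[::-1]
    return IntensityProfile(values=np.ascontiguousarray(values),
                            channel_id=channel_id)


def sample_background(image: np.ndarray, point: tuple[int, int]) -> float:
    """Mean gray value of the 3x3 neighborhood around ``point`` = (x, y).

    At image borders the window truncates to the in-bounds pixels rather
    than erroring; users legitimately click near edges.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("sample_background expects a single 2-D gray channel")
    x, y = int(point[0]), int(point[1])
    rows, cols = image.shape
    if not (0 <= x < cols and 0 <= y < rows):
        raise BoundsError(f"background point ({x}, {y}) outside image "
                          f"{cols}x{rows}")
    window = image[max(y - 1, 0):min(y + 2, rows),
                   max(x - 1, 0):min(x + 2, cols)]
    return float(np.mean(window.astype(float)))


def smooth_profile(profile: IntensityProfile, window: int) -> IntensityProfile:
    """Centered moving average; edge windows truncate to in-bounds samples.

    ``window`` must be odd; ``window=1`` returns the input unchanged.
    Smoothing is a landmark-detection aid only -- quantification always
    runs on raw profiles.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"smoothing window must be a positive odd integer, got {window}")
    n = len(profile)
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds profile length {n}")
    if window == 1:
        return profile
    kernel = np.ones(window)
    sums = np.convolve(profile.values, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return IntensityProfile(values=sums / counts, channel_id=profile.channel_id)


def default_smooth_window(length: int) -> int:
    """Scale-aware default smoothing window for landmark detection.

    Roughly 1/50 of the profile length (never below 5, always odd, never
    above the profile length): wide enough to suppress pixel noise left
    after ROI-height averaging, narrow relative to a neurite band
    (~1/10 of the IPL) so symmetric peaks are not displaced.
    """
    w = max(5, int(round(length / 50)))
    if w % 2 == 0:
        w += 1
    return min(w, length if length % 2 == 1 else length - 1)
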