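"""Layer-boundary geometry of the IPL.

Boundaries are real-valued fractions of the IPL depth (0 = RGL edge,
1 = INL edge); pixel assignment is deferred to quantification so the
geometry stays exact and testable in closed form.  An optional additional
analysis region for misprojected neurites extends past 1, measured in the
same IPL-length units.

The SAC (cholinergic-landmark) mode implements the ten-sublayer scheme:
the RGL-to-ON-peak span is split 7 ways, with successive pairs of the
first six sublayers merged into layers 1-3 (each 2/7 of the span); the
7th sublayer plus the first quarter of the ON-to-divider span is layer 4
and covers most of the ON band; the next half of that span is layer 5;
its last quarter plus the first quarter of the divider-to-OFF span is
layer 6; the next half of that span is layer 7; its last quarter plus the
first fifth of the OFF-to-INL span is layer 8, covering most of the OFF
band; the remaining four fifths split evenly into layers 9 and 10.  At
the wild-type landmark positions each layer is close to 10% of the IPL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LandmarkValidationError
from .landmarks import LandmarkSet, validate_landmarks


@dataclass(frozen=True)
class BoundarySet:
    """Strictly increasing layer boundaries spanning the IPL.

    ``boundaries[0] == 0`` and ``boundaries[n_ipl_layers] == 1`` exactly;
    if ``has_additional`` there is one further boundary > 1 ending the
    additional analysis region.
    """

    boundaries: np.ndarray
    n_ipl_layers: int
    has_additional: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        expected = self.n_ipl_layers + 1 + (1 if self.has_additional else 0)
        if b.size != expected:
            raise ValueError(f"expected {expected} boundaries, got {b.size}")
        if b[0] != 0.0 or b[self.n_ipl_layers] != 1.0:
            raise ValueError("IPL boundaries must start at 0 and end at 1 exactly")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_layers(self) -> int:
        return self.n_ipl_layers + (1 if self.has_additional else 0)

    @property
    def end(self) -> float:
        """Outermost boundary (1 unless an additional region is present)."""
        return float(self.boundaries[-1])


def compute_sac_boundaries(lm: LandmarkSet) -> BoundarySet:
    """Ten-layer binning anchored on the cholinergic band landmarks."""
    validate_landmarks(lm)
    p1, m, p2 = lm.on_peak, lm.divider, lm.off_peak
    u = p1 / 7.0  # unit sublayer of the RGL-to-ON-peak span
    b = np.array([
        0.0,
        2 * u,
        4 * u,
        6 * u,
        p1 + 0.25 * (m - p1),
        p1 + 0.75 * (m - p1),
        m + 0.25 * (p2 - m),
        m + 0.75 * (p2 - m),
        p2 + 0.2 * (1 - p2),
        p2 + 0.6 * (1 - p2),
        1.0,
    ])
    return BoundarySet(boundaries=b, n_ipl_layers=10)


def compute_uniform_boundaries(n: int) -> BoundarySet:
    """``n`` even layers by IPL thickness (n=5 is Cajal's S1-S5 convention)."""
    if n < 1:
        raise ValueError(f"number of layers must be >= 1, got {n}")
    b = np.linspace(0.0, 1.0, n + 1)
    b[0], b[-1] = 0.0, 1.0
    return BoundarySet(boundaries=b, n_ipl_layers=n)


def compute_manual_boundaries(positions) -> BoundarySet:
    """User-supplied interior boundaries (cortex, zebrafish 3-band retina...)."""
    pos = np.asarray(list(positions), dtype=float)
    if pos.size and (np.any(pos <= 0) or np.any(pos >= 1)):
        raise LandmarkValidationError("manual boundaries must lie strictly in (0, 1)")
    if pos.size > 1 and np.any(np.diff(pos) <= 0):
        raise LandmarkValidationError("manual boundaries must be strictly increasing")
    b = np.concatenate([[0.0], pos, [1.0]])
    return BoundarySet(boundaries=b, n_ipl_layers=pos.size + 1)


def append_additional_region(bs: BoundarySet, end: float) -> BoundarySet:
    """Append the misprojection analysis region [1, end) past the INL edge."""
    if bs.has_additional:
        raise ValueError("BoundarySet already has an additional region")
    if not end > 1.0:
        raise ValueError(f"additional-region end must exceed 1 (IPL edge), got {end}")
    return BoundarySet(boundaries=np.append(bs.boundaries, end),
                       n_ipl_layers=bs.n_ipl_layers, has_additional=True)


def layer_geometry(bs: BoundarySet, ipl_length_px: float) -> pd.DataFrame:
    """Per-layer depth and width in pixels.

    Layer numbers ascend from the RGL-adjacent layer to the INL-adjacent
    layer, then the additional region if present.  ``depth_px`` is the
    distance of the layer's RGL-side boundary from the RGL edge of the
    ROI; widths of the IPL layers sum to ``ipl_length_px`` exactly up to
    floating point.
    """
    if ipl_length_px < 1:
        raise ValueError("ipl_length_px must be >= 1")
    b = bs.boundaries
    return pd.DataFrame({
        "layer_number": np.arange(1, bs.n_layers + 1),
        "depth_px": b[:-1] * ipl_length_px,
        "width_px": np.diff(b) * ipl_length_px,
    })
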