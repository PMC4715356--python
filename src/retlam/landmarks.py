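"""Biological landmark detection in IPL depth profiles.

The mouse IPL carries two cholinergic (ChAT) starburst amacrine cell
neurite bands -- the ON band near 40% depth from the RGL and the OFF band
near 77% -- separated by an intensity minimum close to 60% that marks the
ON/OFF functional divide.  Calbindin/calretinin staining shows the same
two outer bands plus an intermediate third stripe, so in that mode the
divider is the *peak* of the middle stripe rather than a minimum.

Peak search "starts from the middle of the IPL": each half of the profile
is searched independently by global argmax, so a dispersed band with
several local maxima (as in Dscam mutants) still yields exactly one
landmark per half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LandmarkDetectionError, LandmarkValidationError
from .profiles import IntensityProfile, default_smooth_window, smooth_profile

# Hard-coded percentile landmarks: average wild-type mouse SAC band
# positions (depth fractions from the RGL side). Fixed constants, never
# recomputed from images.
ON_PEAK_PCT = 40.0
DIVIDER_PCT = 60.0
OFF_PEAK_PCT = 77.0


@dataclass(frozen=True)
class LandmarkSet:
    """ON peak, divider and OFF peak as depth fractions in (0, 1)."""

    on_peak: float
    divider: float
    off_peak: float
    source: str = "manual"


def validate_landmarks(lm: LandmarkSet) -> LandmarkSet:
    """Check 0 < on_peak < divider < off_peak < 1; pass through if valid."""
    pairs = [
        ("0", 0.0, "on_peak", lm.on_peak),
        ("on_peak", lm.on_peak, "divider", lm.divider),
        ("divider", lm.divider, "off_peak", lm.off_peak),
        ("off_peak", lm.off_peak, "1", 1.0),
    ]
    for lo_name, lo, hi_name, hi in pairs:
        if not lo < hi:
            raise LandmarkValidationError(
                f"landmark ordering violated: {lo_name} ({lo}) must be < "
                f"{hi_name} ({hi})"
            )
    return lm


def percentile_landmarks() -> LandmarkSet:
    """The hard-coded wild-type landmark positions (40/60/77 percentile)."""
    return LandmarkSet(ON_PEAK_PCT / 100, DIVIDER_PCT / 100,
                       OFF_PEAK_PCT / 100, source="percentile")


def _pixel_fraction(index: int, length: int) -> float:
    # landmark = pixel-center fraction; no sub-pixel refinement
    return (index + 0.5) / length


def _prepare(profile: IntensityProfile, smooth_window: int | None) -> np.ndarray:
    n = len(profile)
    if n < 8:
        raise LandmarkDetectionError(f"profile too short ({n} px) for band detection")
    if np.ptp(profile.values) == 0:
        raise LandmarkDetectionError("no bands: profile is constant")
    if smooth_window is None:
        smooth_window = default_smooth_window(n)
    return smooth_profile(profile, smooth_window).values


def _outer_peaks(sm: np.ndarray) -> tuple[int, int]:
    """Global argmax per half-profile; ties broken toward the lowest index."""
    mid = sm.size // 2
    on_idx = int(np.argmax(sm[:mid]))
    off_idx = mid + int(np.argmax(sm[mid:]))
    if on_idx == 0 or off_idx == sm.size - 1:
        raise LandmarkDetectionError(
            "band peak found at profile end; landmarks must be interior "
            "(check the ROI covers the whole IPL)"
        )
    return on_idx, off_idx


def detect_chat_landmarks(profile: IntensityProfile,
                          smooth_window: int | None = None) -> LandmarkSet:
    """Locate the two SAC band peaks and the inter-band minimum.

    ON peak = argmax over the RGL half, OFF peak = argmax over the INL
    half, divider = argmin strictly between them.  Positions are returned
    as pixel-center fractions of the profile length.
    """
    sm = _prepare(profile, smooth_window)
    on_idx, off_idx = _outer_peaks(sm)
    between = sm[on_idx + 1:off_idx]
    if between.size == 0:
        raise LandmarkDetectionError("no interior samples between the two band peaks")
    div_idx = on_idx + 1 + int(np.argmin(between))
    n = sm.size
    return validate_landmarks(LandmarkSet(
        _pixel_fraction(on_idx, n),
        _pixel_fraction(div_idx, n),
        _pixel_fraction(off_idx, n),
        source="chat",
    ))


def detect_calbindin_landmarks(profile: IntensityProfile,
                               smooth_window: int | None = None) -> LandmarkSet:
    """Locate three calbindin/calretinin stripes.

    The landmarks are the three brightest *separable* stripes: interior
    local maxima of the smoothed profile (plateau-aware, so a flat-topped
    band counts once), ranked by height with ties broken toward the
    lowest index, then ordered by depth.  A bare argmax between the outer
    bands would land on a band flank rather than the intermediate
    stripe, and a half-split search would mistake an equally bright
    middle stripe for the OFF band; ranking separable stripes avoids
    both.  Fewer than three separable maxima is a detection error.
    """
    from scipy.signal import find_peaks

    sm = _prepare(profile, smooth_window)
    candidates, _ = find_peaks(sm)
    if candidates.size < 3:
        raise LandmarkDetectionError(
            f"fewer than three separable stripes (found {candidates.size}); "
            "calbindin mode needs the two SAC bands plus the intermediate band"
        )
    order = np.lexsort((candidates, -sm[candidates]))
    picked = np.sort(candidates[order[:3]])
    n = sm.size
    return validate_landmarks(LandmarkSet(
        _pixel_fraction(int(picked[0]), n),
        _pixel_fraction(int(picked[1]), n),
        _pixel_fraction(int(picked[2]), n),
        source="calbindin",
    ))
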