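"""Synthetic retinal sections with known ground truth.

Every other module is testable without any download: this module renders
multichannel section images whose depth profiles are Gaussian neurite
bands on a constant baseline, with optional additive Gaussian pixel
noise (clipped at zero) and an optional misprojection component placed
beyond the INL edge of the IPL.

Band widths default to SD = 0.04 of the IPL length, which puts the full
width at half maximum near 10% of the IPL -- the measured span of a
mouse SAC band.  Presets emulate the canonical validation scenes: a
wild-type ChAT pair at 40%/77% depth, a calbindin triplet with the
intermediate stripe, a dispersed ON band split into two sub-peaks, and a
channel misprojecting ~10% of its signal into the INL side.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .landmarks import LandmarkSet
from .profiles import IntensityProfile

BAND_SD = 0.04  # default band SD as a fraction of IPL length

Band = tuple[float, float, float]  # (center fraction, SD fraction, amplitude)


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of a synthetic section.

    ``bands`` maps channel id to its list of (center, SD, amplitude)
    Gaussian bands, all in IPL-length fractions; ``misprojection``
    maps channel id to the share of that channel's total signal placed
    beyond the INL edge (requires ``extra_px`` > 0).
    """

    length_px: int = 700
    height_px: int = 80
    bands: dict[str, tuple[Band, ...]] = field(default_factory=dict)
    baseline: float = 0.1
    noise_sd: float = 0.0
    misprojection: dict[str, float] = field(default_factory=dict)
    extra_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_px < 8 or self.height_px < 1:
            raise ValueError("section must be at least 8 px deep and 1 px high")
        if self.baseline < 0 or self.noise_sd < 0:
            raise ValueError("baseline and noise_sd must be non-negative")
        for ch, bands in self.bands.items():
            for c, sd, a in bands:
                if not 0 < c < 1:
                    raise ValueError(f"band center {c} of channel {ch!r} not in (0,1)")
                if sd <= 0 or a <= 0:
                    raise ValueError(f"band SD and amplitude must be positive ({ch!r})")
        for ch, f in self.misprojection.items():
            if not 0 <= f < 1:
                raise ValueError(f"misprojection fraction {f} of {ch!r} not in [0,1)")
            if f > 0 and self.extra_px <= 0:
                raise ValueError("misprojection requires extra_px > 0")

    @property
    def total_px(self) -> int:
        return self.length_px + self.extra_px

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.bands)


def _noiseless_profile(spec: SectionSpec, channel: str) -> np.ndarray:
    """Baseline + Gaussian bands (+ scaled misprojection band), no noise."""
    if channel not in spec.bands:
        raise ValueError(f"unknown channel {channel!r}; have {spec.channels}")
    n_total = spec.total_px
    x = (np.arange(n_total) + 0.5) / spec.length_px  # IPL-length fractions
    in_ipl = x < 1.0
    # baseline models IPL neuropil autofluorescence; the region past the
    # INL edge is dark apart from misprojected signal (and noise)
    values = np.where(in_ipl, float(spec.baseline), 0.0)
    signal = np.zeros(n_total)
    for c, sd, a in spec.bands[channel]:
        signal += a * np.exp(-((x - c) ** 2) / (2 * sd ** 2))
    signal[~in_ipl] = 0.0  # band tails never leak into the extra region
    f = spec.misprojection.get(channel, 0.0)
    if f > 0:
        extra_frac = spec.extra_px / spec.length_px
        center = 1.0 + extra_frac / 2
        sd = min(BAND_SD, extra_frac / 5)
        mis = np.exp(-((x - center) ** 2) / (2 * sd ** 2))
        mis[in_ipl] = 0.0
        # scale so the extra region holds exactly fraction f of total
        # channel signal (IPL baseline included, noiseless)
        ipl_sum = signal[in_ipl].sum() + spec.baseline * in_ipl.sum()
        mis *= (f * ipl_sum / (1 - f)) / mis.sum()
        signal += mis
    return values + signal


def make_profile(spec: SectionSpec, channel: str) -> IntensityProfile:
    """1-D depth profile of one channel; deterministic given ``spec.seed``."""
    values = _noiseless_profile(spec, channel)
    if spec.noise_sd > 0:
        rng = np.random.default_rng((spec.seed, zlib.crc32(channel.encode())))
        values = values + rng.normal(0, spec.noise_sd, values.size)
    return IntensityProfile(values=np.clip(values, 0, None), channel_id=channel)


def make_section_image(spec: SectionSpec):
    """Render the section; returns (channel -> 2-D image, ground truth).

    Each channel is its noiseless profile broadcast across ``height_px``
    rows with independent per-pixel noise; the depth axis is horizontal
    with the RGL side at the left.  Ground truth is the LandmarkSet of
    true band centers (divider = middle band center if a channel has
    three bands, else the midpoint of the outermost pair).
    """
    rng = np.random.default_rng(spec.seed)
    channels: dict[str, np.ndarray] = {}
    for ch in spec.channels:
        base = _noiseless_profile(spec, ch)
        img = np.tile(base, (spec.height_px, 1))
        if spec.noise_sd > 0:
            img = img + rng.normal(0, spec.noise_sd, img.shape)
        channels[ch] = np.clip(img, 0, None)
    try:
        truth = ground_truth_landmarks(spec)
    except ValueError:
        truth = None  # band layout has no landmark structure (e.g. one band)
    return channels, truth


def ground_truth_landmarks(spec: SectionSpec, grid: int = 20001) -> LandmarkSet:
    """True landmark positions of the noiseless generated scene.

    Evaluated analytically on a fine grid over the IPL: the ON/OFF peaks
    are the maxima of the landmark channel's noiseless band sum in each
    half, the divider is the inter-peak minimum (ChAT) or the inter-peak
    maximum (calbindin middle stripe).  This is the generative truth a
    detector should recover, including small peak shifts caused by
    overlapping band tails.
    """
    if "calbindin" in spec.bands:
        channel, divider_is_max = "calbindin", True
    elif "chat" in spec.bands:
        channel, divider_is_max = "chat", False
    else:
        channel, divider_is_max = spec.channels[0], False
    x = np.linspace(0.0, 1.0, grid)
    y = np.zeros_like(x)
    for c, sd, a in spec.bands[channel]:
        y += a * np.exp(-((x - c) ** 2) / (2 * sd ** 2))
    half = grid // 2
    on = x[int(np.argmax(y[:half]))]
    off = x[half + int(np.argmax(y[half:]))]
    lo, hi = np.searchsorted(x, on) + 1, np.searchsorted(x, off)
    if divider_is_max:
        # middle stripe = largest interior local maximum (outer band
        # flanks rise toward the peaks and must not win)
        inner = np.arange(lo, hi)
        is_peak = (y[inner] >= y[inner - 1]) & (y[inner] >= y[inner + 1])
        cand = inner[is_peak]
        div_idx = int(cand[np.argmax(y[cand])])
    else:
        div_idx = lo + int(np.argmin(y[lo:hi]))
    return LandmarkSet(float(on), float(x[div_idx]), float(off), source="manual")


# Diffuse cholinergic neuropil in the ON half.  Two equal symmetric bands
# alone put the inter-band minimum at their midpoint (58.5% depth); real
# wild-type staining has the ON/OFF divide at 60%, so the wild-type scenes
# carry this weak broad component.  Its amplitude solves d/dx[sum of
# bands] = 0 at x = 0.60 exactly, placing the continuous minimum on the
# divide while shifting the ON peak by < 0.15% of the IPL.
_ON_SHOULDER: Band = (0.25, 0.10, 0.1598)

_PRESETS = {
    # wild-type: ChAT pair at the canonical 40/77 percentile positions,
    # plus a TH-like channel with a small physiological OPL projection
    "wildtype_chat": SectionSpec(
        bands={
            "chat": ((0.40, BAND_SD, 1.0), (0.77, BAND_SD, 1.0), _ON_SHOULDER),
            "th": ((0.35, BAND_SD, 0.8),),
        },
        misprojection={"th": 0.015},
        extra_px=70,
    ),
    # calbindin triplet: outer stripes coincide with the ChAT bands, the
    # intermediate stripe sits at the 60% ON/OFF divide it demarcates
    "calbindin_triplet": SectionSpec(
        bands={
            "chat": ((0.40, BAND_SD, 1.0), (0.77, BAND_SD, 1.0), _ON_SHOULDER),
            "calbindin": ((0.40, BAND_SD, 1.0), (0.60, BAND_SD, 0.7),
                          (0.77, BAND_SD, 1.0)),
        },
    ),
    # dispersed ON band: two sub-peaks of unequal height within one half
    "dscam_split": SectionSpec(
        bands={
            "chat": ((0.34, 0.025, 0.9), (0.44, 0.025, 1.0),
                     (0.77, BAND_SD, 1.0)),
        },
    ),
    # mutant misprojection: TH channel places 10% of its signal past the
    # INL edge of the IPL
    "bax_misprojection": SectionSpec(
        bands={
            "chat": ((0.40, BAND_SD, 1.0), (0.77, BAND_SD, 1.0)),
            "th": ((0.35, BAND_SD, 0.8),),
        },
        misprojection={"th": 0.10},
        extra_px=70,
    ),
}


def preset(name: str, **overrides) -> SectionSpec:
    """A named validation scene; ``overrides`` replace spec fields."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    spec = _PRESETS[name]
    return replace(spec, **overrides) if overrides else spec


def write_fixture(spec: SectionSpec, out_dir, name: str = "section",
                  bit_depth: int = 16):
    """Write the section as a multi-page 16-bit TIFF plus a ground-truth sidecar.

    Page order follows ``spec.channels``; intensities are scaled so the
    global maximum maps to 90% of the dtype range.  The sidecar is a
    plain-text key/value file recording channels, geometry and true
    landmarks.  Returns (tiff_path, sidecar_path).
    """
    import tifffile
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channels, truth = make_section_image(spec)
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    peak = max(img.max() for img in channels.values())
    scale = 0.9 * np.iinfo(dtype).max / peak if peak > 0 else 1.0
    stack = np.stack([np.round(channels[ch] * scale).astype(dtype)
                      for ch in spec.channels])
    tiff_path = out_dir / f"{name}.tif"
    tifffile.imwrite(tiff_path, stack)
    sidecar_path = out_dir / f"{name}.groundtruth.txt"
    lines = [
        f"channels = {','.join(spec.channels)}",
        f"ipl_length_px = {spec.length_px}",
        f"extra_px = {spec.extra_px}",
        f"height_px = {spec.height_px}",
        f"intensity_scale = {scale:.8g}",
        f"on_peak = {truth.on_peak:.8g}",
        f"divider = {truth.divider:.8g}",
        f"off_peak = {truth.off_peak:.8g}",
        f"seed = {spec.seed}",
    ]
    sidecar_path.write_text("\n".join(lines) + "\n")
    return tiff_path, sidecar_path
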