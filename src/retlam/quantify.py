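"""Per-layer, per-channel intensity statistics and the results table.

Three parallel intensity readouts are kept, mirroring the tool's output
fields: the raw layer mean, a normalized value (mean minus 99% of the
lowest non-zero layer mean on that image), and optionally the mean minus
a sampled background.  None of them is clamped at zero -- a pixel cannot
be told apart from pure background noise, so negative values are reported
as computed and users should consistently use one of the three readouts.
Intensity % is each layer's share of the summed signal, including the
additional analysis region when one is selected, so a misprojection
readout is a share of *total* measured signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .binning import BoundarySet, layer_geometry
from .errors import NormalizationError
from .profiles import IntensityProfile

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "image", "channel", "layer_number", "layer_depth_px", "layer_width_px",
    "intensity", "normalized_intensity", "intensity_minus_background",
    "intensity_pct",
]


def assign_layers(n_pixels: int, bs: BoundarySet, ipl_length_px: float) -> np.ndarray:
    """Layer index (0-based) for each profile pixel; -1 if past the last boundary.

    A pixel with center ``(i + 0.5) / ipl_length_px`` (in IPL-length
    fractions) belongs to layer ``k`` iff ``boundaries[k] <= c <
    boundaries[k+1]``; the last layer's upper bound is inclusive.
    """
    centers = (np.arange(n_pixels) + 0.5) / ipl_length_px
    b = bs.boundaries
    idx = np.searchsorted(b, centers, side="right") - 1
    # last layer's upper bound is inclusive
    idx[centers == b[-1]] = bs.n_layers - 1
    idx[(idx < 0) | (idx >= bs.n_layers)] = -1
    return idx


def layer_mean_intensity(profile: IntensityProfile, bs: BoundarySet,
                         ipl_length_px: float | None = None) -> np.ndarray:
    """Mean raw intensity of the profile pixels falling in each layer.

    ``ipl_length_px`` defaults to the profile length when no additional
    region is present.  A layer capturing no pixel centers gets 0 and a
    logged warning.
    """
    n = len(profile)
    if ipl_length_px is None:
        if bs.has_additional:
            raise ValueError("ipl_length_px is required when an additional "
                             "region is present")
        ipl_length_px = float(n)
    needed = bs.end * ipl_length_px
    if n < needed - 0.5:  # outermost pixel center must be reachable
        raise ValueError(
            f"profile of {n} px does not cover the outermost boundary "
            f"({needed:.1f} px)"
        )
    idx = assign_layers(n, bs, ipl_length_px)
    means = np.zeros(bs.n_layers)
    for k in range(bs.n_layers):
        members = profile.values[idx == k]
        if members.size == 0:
            logger.warning("layer %d captured no pixel centers; mean set to 0", k + 1)
        else:
            means[k] = members.mean()
    return means


def normalized_intensity(layer_means) -> np.ndarray:
    """Layer means minus 99% of the lowest non-zero layer mean.

    Not clamped: a zero layer yields a negative value, reported as
    computed.
    """
    means = np.asarray(layer_means, dtype=float)
    nonzero = means[means > 0]
    if nonzero.size == 0:
        raise NormalizationError("all layer means are zero; normalization undefined")
    return means - 0.99 * nonzero.min()


def subtract_background(layer_means, bg: float) -> np.ndarray:
    """Layer means minus the sampled 3x3 background value (not clamped)."""
    if bg < 0:
        raise ValueError("background intensity must be non-negative")
    return np.asarray(layer_means, dtype=float) - bg


def intensity_percent(layer_means) -> np.ndarray:
    """Each layer's intensity as a percent of the summed intensity.

    The input must include the additional region when one is selected, so
    its percent is a share of total measured signal.
    """
    means = np.asarray(layer_means, dtype=float)
    total = means.sum()
    if total <= 0:
        raise ValueError("cannot compute intensity percent: total intensity is 0")
    return 100.0 * means / total


def quantify_channel(profile: IntensityProfile, bs: BoundarySet,
                     ipl_length_px: float | None = None,
                     background: float | None = None) -> pd.DataFrame:
    """All intensity statistics for one channel of one image."""
    if ipl_length_px is None and not bs.has_additional:
        ipl_length_px = float(len(profile))
    means = layer_mean_intensity(profile, bs, ipl_length_px)
    geom = layer_geometry(bs, ipl_length_px)
    out = geom.rename(columns={"depth_px": "layer_depth_px",
                               "width_px": "layer_width_px"})
    out["intensity"] = means
    out["normalized_intensity"] = normalized_intensity(means)
    out["intensity_minus_background"] = (
        subtract_background(means, background) if background is not None
        else np.nan)
    out["intensity_pct"] = intensity_percent(means)
    return out


def assemble_results(per_channel: dict[tuple[str, str], pd.DataFrame],
                     with_background: bool = False) -> pd.DataFrame:
    """Stack per-(image, channel) tables; append combined means across images.

    ``per_channel`` maps (image_id, channel_id) to the quantify_channel
    output.  With more than one image a summary row set (image id
    ``combined``) carries the per-layer means of every statistic across
    images, per channel.
    """
    if not per_channel:
        raise ValueError("no quantification tables to assemble")
    layer_counts = {df.shape[0] for df in per_channel.values()}
    if len(layer_counts) != 1:
        raise ValueError(f"inconsistent layer counts across channels: {layer_counts}")
    frames = []
    for (image_id, channel_id), df in per_channel.items():
        df = df.copy()
        df.insert(0, "channel", channel_id)
        df.insert(0, "image", image_id)
        frames.append(df)
    result = pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]
    images = result["image"].unique()
    if len(images) > 1:
        value_cols = [c for c in RESULT_COLUMNS if c not in
                      ("image", "channel", "layer_number")]
        combined = (result.groupby(["channel", "layer_number"], sort=False)
                    [value_cols].mean().reset_index())
        combined.insert(0, "image", "combined")
        result = pd.concat([result, combined[RESULT_COLUMNS]], ignore_index=True)
    if not with_background:
        result["intensity_minus_background"] = np.nan
    return result


def write_results(results: pd.DataFrame, path) -> None:
    """Tab-delimited results file, one header row, 6 significant digits.

    ``intensity_minus_background`` is left blank when background
    reduction was not selected.
    """
    out = results.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if np.isnan(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def plot_histograms(results: pd.DataFrame, out_dir, value: str = "intensity_pct"):
    """Bar plot of per-layer values for each image plus the combined set.

    Returns the list of written file paths.  Rendering is illustrative,
    not bit-specified.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for image_id, sub in results.groupby("image", sort=False):
        fig, ax = plt.subplots(figsize=(6, 4))
        for channel_id, ch in sub.groupby("channel", sort=False):
            ax.bar(ch["layer_number"], ch[value], alpha=0.6, label=channel_id)
        ax.set_xlabel("layer (RGL side first)")
        ax.set_ylabel(value)
        ax.set_title(str(image_id))
        ax.legend()
        path = out_dir / f"histogram_{image_id}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
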