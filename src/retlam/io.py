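"""Image readers: single/multi-page TIFF and PNG, 8/16-bit grayscale channels.

Channels are addressed by page (TIFF) or leading-axis index; pixels are
promoted to float internally.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def read_channels(path) -> list[np.ndarray]:
    """Read an image file into a list of 2-D float channel arrays.

    TIFF pages / stacked axes become separate channels; an RGB(A) PNG is
    split into its color planes; a plain grayscale image is one channel.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        data = np.asarray(tifffile.imread(path))
    else:
        import imageio.v3 as iio
        data = np.asarray(iio.imread(path))
    return split_channels(data)


def split_channels(data: np.ndarray) -> list[np.ndarray]:
    data = np.asarray(data)
    if data.ndim == 2:
        return [data.astype(float)]
    if data.ndim == 3:
        # channel axis: leading for stacks (C, H, W), trailing for RGB(A)
        axis = 0 if data.shape[0] <= data.shape[2] else 2
        if data.shape[2] in (3, 4) and data.shape[0] not in (1, 2):
            axis = 2
        return [np.take(data, i, axis=axis).astype(float)
                for i in range(data.shape[axis])]
    raise ValueError(f"unsupported image dimensionality: {data.shape}")
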