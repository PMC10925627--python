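"""Model-free null heat maps and attribution post-processing.

Edge detectors (Sobel gradient magnitude, absolute Laplacian) depend only
on the image, never on a model, and serve as null baselines: any attribution
method worth using should localize lesions better than a generic edge map.

Attribution maps from any source are normalized by absolute value and peak
(the benchmark metric is rank-based, so positive rescaling is immaterial,
but a fixed convention keeps serialized maps comparable).  The intensity
transform used for rendering heat maps, ``-log(1 - s(1 - 1/b)) / log(b)``,
is monotone and applied for visualization only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage as ndi


@dataclass(frozen=True)
class HeatMap:
    """Non-negative per-pixel importance scores with provenance."""

    scores: NDArray[np.float64]
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("heat map contains non-finite values")
        if (self.scores < 0).any():
            raise ValueError("heat map contains negative values")


def sobel_map(image: NDArray) -> HeatMap:
    """Gradient-magnitude map from the standard 3x3 Sobel kernels."""
    img = np.asarray(image, dtype=float)
    gx = ndi.sobel(img, axis=1, mode="reflect")
    gy = ndi.sobel(img, axis=0, mode="reflect")
    return HeatMap(scores=np.hypot(gx, gy), method="sobel")


def laplace_map(image: NDArray) -> HeatMap:
    """Absolute response of the 4-neighbour Laplacian kernel."""
    img = np.asarray(image, dtype=float)
    return HeatMap(scores=np.abs(ndi.laplace(img, mode="reflect")), method="laplace")


def normalize_attribution(
    raw: NDArray, method: str = "attribution", provenance: dict | None = None
) -> HeatMap:
    """Absolute value, then division by the peak (all-zero maps stay zero)."""
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("attribution map contains non-finite values")
    arr = np.abs(arr)
    peak = arr.max()
    if peak > 0:
        arr = arr / peak
    return HeatMap(scores=arr, method=method, provenance=provenance or {})


def viz_transform(scores: NDArray, b: float = 0.5) -> NDArray[np.float64]:
    """Monotone intensity transform for rendering: -log(1 - s(1 - 1/b))/log(b).

    Maps [0, 1] onto [0, 1] bijectively for any base ``b`` in (0, 1); for
    b = 0.5 it reduces to log2(1 + s).  Rendering only — never applied
    before metric computation.
    """
    if not 0 < b < 1:
        raise ValueError(f"base must be in (0, 1), got {b}")
    s = np.asarray(scores, dtype=float)
    if (s < 0).any() or (s > 1).any():
        raise ValueError("scores must lie in [0, 1]")
    return -np.log(1.0 - s * (1.0 - 1.0 / b)) / np.log(b)


def viz_transform_inverse(values: NDArray, b: float = 0.5) -> NDArray[np.float64]:
    """Inverse of :func:`viz_transform` on [0, 1]."""
    if not 0 < b < 1:
        raise ValueError(f"base must be in (0, 1), got {b}")
    v = np.asarray(values, dtype=float)
    return (1.0 - np.power(b, -v)) / (1.0 - 1.0 / b)
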