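"""Background slices: loading, filtering, geometry and the brain phantom.

Real axial T1 slices can be loaded from PNG or NIfTI files, filtered by the
black-pixel rule (slices with >= 55% black pixels are mostly outside the
head and are dropped), standardized to 270x270, and intensity-rescaled to
[0, 0.7] so that inserted lesions (which brighten pixels by up to a factor
1 + w) stay within [0, 1].

For users without access to a suitable MRI corpus, :func:`synth_phantom`
generates a deterministic brain-like phantom: an elliptical head with a
brighter cortical rim, smooth low-frequency tissue texture, and one or two
darker ventricle-like blobs on a black exterior.  The phantom emulates only
the properties the benchmark pipeline consumes — value range, black
exterior, a contiguous brain region, a sub-55% black fraction and a
subject-like identifier for split bookkeeping — not MRI anatomy or physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage as ndi
from skimage import measure
from PIL import Image

from .errors import DegenerateInputError, GeometryError

#: upper end of the background intensity range
BACKGROUND_MAX = 0.7
#: slices with at least this fraction of black pixels are rejected
BLACK_FRACTION_LIMIT = 0.55
#: a pixel at or below this intensity counts as black
BLACK_TOLERANCE = 1e-6
#: the standardized slice geometry
TARGET_SIZE = 270


@dataclass(frozen=True)
class BackgroundSlice:
    """A standardized background with its brain mask and subject identity."""

    pixels: NDArray[np.float64]      # values in [0, BACKGROUND_MAX]
    brain_mask: NDArray[np.bool_]
    subject_id: str

    def __post_init__(self) -> None:
        if self.pixels.shape != self.brain_mask.shape:
            raise ValueError("pixels and brain mask must share a shape")
        if not self.brain_mask.any():
            raise DegenerateInputError("brain mask is empty")


def load_slice(path: str | Path, slice_index: int | None = None) -> NDArray[np.float64]:
    """Load a 2-D grayscale slice from PNG (8/16-bit) or NIfTI, mapped to [0, 1].

    PNG intensities are divided by the format's maximum representable value.
    NIfTI volumes are normalized by a robust maximum (the 99.5th percentile,
    then clipped) since MRI intensities have no fixed scale; 3-D volumes
    require ``slice_index`` selecting an axial slice (last axis).
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(path).dataobj).astype(float)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValueError("a slice index is required for 3-D NIfTI volumes")
            vol = vol[..., slice_index]
        elif vol.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim}")
        robust_max = np.percentile(vol, 99.5)
        if robust_max <= 0:
            raise DegenerateInputError("volume has no positive intensities")
        return np.clip(vol / robust_max, 0.0, 1.0)
    img = Image.open(path)
    if img.mode == "I;16":
        return np.asarray(img, dtype=np.float64) / 65535.0
    if img.mode in ("L", "I"):
        arr = np.asarray(img, dtype=np.float64)
        return arr / 255.0 if img.mode == "L" else arr / 65535.0
    raise ValueError(f"unsupported PNG mode {img.mode!r}; expected 8/16-bit grayscale")


def black_fraction(img: NDArray, tolerance: float = BLACK_TOLERANCE) -> float:
    """Fraction of pixels at or below the black tolerance."""
    arr = np.asarray(img)
    return float(np.count_nonzero(arr <= tolerance) / arr.size)


def filter_slices(slices: list[NDArray], limit: float = BLACK_FRACTION_LIMIT) -> list[NDArray]:
    """Keep slices whose black fraction is strictly below ``limit``, in order."""
    return [s for s in slices if black_fraction(s) < limit]


def standardize_geometry(img: NDArray, target: int = TARGET_SIZE) -> NDArray[np.float64]:
    """Pad rows with zeros and center-crop columns to ``target`` x ``target``.

    Vertical padding is split symmetrically with the extra row going to the
    top on odd remainders; the horizontal crop is symmetric with the extra
    column dropped from the right.
    """
    arr = np.asarray(img, dtype=float)
    h, w = arr.shape
    if h > target:
        raise GeometryError(f"input height {h} exceeds target {target}")
    if w < target:
        raise GeometryError(f"input width {w} is below target {target}")
    pad = target - h
    top, bottom = (pad + 1) // 2, pad // 2
    arr = np.pad(arr, ((top, bottom), (0, 0)))
    crop = w - target
    left = crop // 2
    return arr[:, left : left + target]


def rescale_intensity(img: NDArray, peak: float = BACKGROUND_MAX) -> NDArray[np.float64]:
    """Linearly scale so the maximum maps to ``peak`` and zero stays zero."""
    arr = np.asarray(img, dtype=float)
    m = arr.max()
    if m <= 0:
        raise DegenerateInputError("cannot rescale an all-zero image")
    return arr * (peak / m)


def brain_mask(
    img: NDArray, tolerance: float = BLACK_TOLERANCE, closing_size: int = 3
) -> NDArray[np.bool_]:
    """Mask of in-brain pixels: above-black, closed, hole-filled, largest
    connected component."""
    arr = np.asarray(img)
    mask = arr > tolerance
    if not mask.any():
        raise DegenerateInputError("image has no above-black pixels")
    mask = ndi.binary_closing(mask, structure=np.ones((closing_size, closing_size), bool))
    mask = ndi.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def synth_phantom(seed: int, size: int = TARGET_SIZE) -> BackgroundSlice:
    """Deterministic brain-like phantom slice.

    Construction: an ellipse (semi-axes 0.80-0.88 and 0.74-0.82 of the
    half-size, guaranteeing a black fraction below 55%) filled with
    mid-grey tissue, modulated by smooth low-frequency texture, with a
    brighter cortical rim just inside the boundary and 1-2 darker
    ventricle-like blobs near the centre.  Intensities are rescaled so the
    maximum is exactly 0.7; the exterior is exactly 0.  The phantom ships
    with its brain mask, which by construction is the ellipse itself.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A7]))
    half = size / 2.0
    a = rng.uniform(0.80, 0.88) * half
    b = rng.uniform(0.74, 0.82) * half
    cy = half + rng.uniform(-0.01, 0.01) * size
    cx = half + rng.uniform(-0.01, 0.01) * size
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2
    ellipse = r2 <= 1.0

    # smooth low-frequency tissue texture; the correlation length is a
    # sizeable fraction of the head so texture blobs cannot mimic lesions
    texture = ndi.gaussian_filter(rng.uniform(0, 1, (size, size)), size / 10.0, mode="reflect")
    texture = (texture - texture.min()) / max(np.ptp(texture), 1e-12)

    img = np.zeros((size, size))
    img[ellipse] = 0.42 + 0.12 * texture[ellipse]
    # brighter cortical rim: a band just inside the ellipse boundary
    rim = ellipse & (r2 > 0.78)
    img[rim] += 0.18
    # 1-2 dark ventricle-like blobs near the centre
    for _ in range(rng.integers(1, 3)):
        vy = cy + rng.uniform(-0.08, 0.08) * size
        vx = cx + rng.uniform(-0.08, 0.08) * size
        va = rng.uniform(0.04, 0.09) * size
        vb = rng.uniform(0.02, 0.05) * size
        angle = rng.uniform(0, np.pi)
        dy, dx = yy - vy, xx - vx
        u = dy * np.cos(angle) + dx * np.sin(angle)
        v = -dy * np.sin(angle) + dx * np.cos(angle)
        blob = (u / va) ** 2 + (v / vb) ** 2 <= 1.0
        img[blob & ellipse] *= 0.55
    # keep the interior strictly above black so the mask is recoverable
    img[ellipse] = np.maximum(img[ellipse], 0.05)
    img = rescale_intensity(img, BACKGROUND_MAX)
    return BackgroundSlice(pixels=img, brain_mask=ellipse, subject_id=f"phantom-{seed:06d}")


def phantom_cohort(n: int, seed: int, size: int = TARGET_SIZE) -> list[BackgroundSlice]:
    """A cohort of ``n`` phantom subjects with distinct per-subject seeds."""
    seq = np.random.SeedSequence([seed, 0xBAC])
    subject_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(n)]
    return [synth_phantom(s, size) for s in subject_seeds]


def write_slices(slices: list[BackgroundSlice], directory: str | Path) -> None:
    """Serialize slices and masks as 16-bit PNG plus a JSON manifest."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, sl in enumerate(slices):
        img_name, mask_name = f"slice_{i:04d}.png", f"mask_{i:04d}.png"
        arr = np.round(sl.pixels / BACKGROUND_MAX * 65535).astype(np.uint16)
        Image.fromarray(arr).save(directory / img_name)
        Image.fromarray(
            (sl.brain_mask * 65535).astype(np.uint16)
        ).save(directory / mask_name)
        manifest.append({"image": img_name, "mask": mask_name, "subject_id": sl.subject_id})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
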