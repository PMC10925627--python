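"""Generation of synthetic lesion shapes.

Candidate shapes are carved out of seeded noise: a uniform noise image is
Gaussian-smoothed, binarized with Otsu's threshold, and passed through
mathematical morphology.  One branch (erosion followed by opening) yields
smooth, blob-like foregrounds; a second erosion on top of that yields
smaller, more fragmented and elongated ones.  Connected components of the
morphology output are scored by isoperimetric compactness 4*pi*A/p**2 and
kept as "regular" lesions (compactness > 0.8, round) or "irregular" lesions
(compactness < 0.4, elongated/ragged); everything in between is rejected,
so the two classes are well separated by construction.

Accepted components are cropped, padded with a 2-pixel zero margin,
lightly smoothed (Gaussian, sigma 0.75) to taper the boundary, and scaled
to a peak intensity ``w`` — the lesion-contrast parameter of the benchmark.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage as ndi
from skimage import filters, measure
from PIL import Image

from .errors import DegenerateInputError, GenerationExhaustedError

logger = logging.getLogger(__name__)

REGULAR = "regular"
IRREGULAR = "irregular"
REJECTED = "rejected"

#: compactness bounds defining the two lesion classes
REGULAR_MIN_COMPACTNESS = 0.8
IRREGULAR_MAX_COMPACTNESS = 0.4


@dataclass(frozen=True)
class ForgeConfig:
    """Parameters of the shape-generation pipeline.

    All values are recorded in bank manifests so a bank is reproducible
    from its config and seed alone.

    Parameters
    ----------
    noise_size : side length of the square noise image, pixels.
    smooth_sigma : std. dev. of the Gaussian applied to the noise, pixels.
    stamp_sigma : std. dev. of the boundary-tapering Gaussian, pixels.
    selem_size : side of the square structuring element for erosion/opening.
    min_area : smallest component area (pixels) considered a candidate;
        compactness is numerically unstable below this.
    max_extent : optional cap on a candidate's bounding-box side, pixels.
        Used to build banks of stamps that fit small backgrounds.
    connectivity : 1 (4-neighbour) or 2 (8-neighbour) component labelling.
    """

    noise_size: int = 256
    smooth_sigma: float = 2.0
    stamp_sigma: float = 0.75
    selem_size: int = 3
    min_area: int = 16
    max_extent: int | None = None
    connectivity: int = 2
    regular_min: float = REGULAR_MIN_COMPACTNESS
    irregular_max: float = IRREGULAR_MAX_COMPACTNESS

    def structuring_element(self) -> NDArray[np.bool_]:
        return np.ones((self.selem_size, self.selem_size), dtype=bool)


@dataclass(frozen=True)
class ShapeComponent:
    """One connected component of a binary image, as a tight binary crop."""

    mask: NDArray[np.bool_]          # tight bounding-box crop
    area: int                        # pixel count
    perimeter: float                 # Crofton perimeter estimate, pixel units

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("component must be non-empty")


@dataclass(frozen=True)
class LesionStamp:
    """A finalized lesion patch ready for compositing.

    ``patch`` holds intensities in [0, w] with a 2-pixel zero margin around
    the (smoothed) support; ``support`` is the strictly-positive pixel mask.
    """

    patch: NDArray[np.float64]
    component_mask: NDArray[np.bool_]  # the pre-smoothing binary component
    shape_class: str                 # REGULAR or IRREGULAR
    compactness: float
    source_seed: int
    w: float

    @property
    def support(self) -> NDArray[np.bool_]:
        return self.patch > 0


@dataclass
class LesionBank:
    regular: list[LesionStamp] = field(default_factory=list)
    irregular: list[LesionStamp] = field(default_factory=list)
    generation_seed: int = 0
    noise_images_used: int = 0
    config: ForgeConfig = field(default_factory=ForgeConfig)

    def stamps(self, shape_class: str) -> list[LesionStamp]:
        if shape_class == REGULAR:
            return self.regular
        if shape_class == IRREGULAR:
            return self.irregular
        raise ValueError(f"unknown shape class {shape_class!r}")


def generate_noise(seed: int, size: int = 256) -> NDArray[np.float64]:
    """Seeded i.i.d. uniform noise image on [0, 1)."""
    if size < 32:
        raise ValueError(f"noise image must be at least 32 pixels, got {size}")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(size, size))


def smooth_gaussian(img: NDArray, sigma: float) -> NDArray[np.float64]:
    """Gaussian smoothing with reflective boundary handling."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndi.gaussian_filter(np.asarray(img, dtype=float), sigma, mode="reflect")


def binarize_otsu(img: NDArray) -> NDArray[np.uint8]:
    """Binarize at the threshold maximizing between-class variance.

    Images with at most 256 distinct values are thresholded by exact
    maximization over every possible cut of the value histogram (binned
    Otsu can misassign values falling in the threshold bin); continuous
    images use the standard 256-bin histogram approximation.
    """
    img = np.asarray(img, dtype=float)
    levels, counts = np.unique(img, return_counts=True)
    if levels.size < 2:
        raise DegenerateInputError("Otsu binarization needs >= 2 distinct values")
    if levels.size <= 256:
        w0 = np.cumsum(counts)[:-1]
        w1 = img.size - w0
        csum = np.cumsum(levels * counts)
        mu0 = csum[:-1] / w0
        mu1 = (csum[-1] - csum[:-1]) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
        k = int(np.argmax(bcv))  # lower class = levels[: k + 1]
        t = (levels[k] + levels[k + 1]) / 2.0
    else:
        t = filters.threshold_otsu(img)
    return (img > t).astype(np.uint8)


def apply_regular_morphology(
    binary: NDArray, config: ForgeConfig | None = None
) -> NDArray[np.uint8]:
    """Erosion followed by opening; the branch producing round candidates."""
    config = config or ForgeConfig()
    se = config.structuring_element()
    eroded = ndi.binary_erosion(np.asarray(binary, dtype=bool), structure=se)
    opened = ndi.binary_opening(eroded, structure=se)
    return opened.astype(np.uint8)


def apply_irregular_morphology(
    binary: NDArray, config: ForgeConfig | None = None
) -> NDArray[np.uint8]:
    """One further erosion on the regular-branch output; candidates fragment
    and elongate, which is what produces the irregular class."""
    config = config or ForgeConfig()
    se = config.structuring_element()
    eroded = ndi.binary_erosion(np.asarray(binary, dtype=bool), structure=se)
    return eroded.astype(np.uint8)


def extract_candidates(
    binary: NDArray, config: ForgeConfig | None = None
) -> list[ShapeComponent]:
    """Connected components fully surrounded by background.

    Components touching the image border are not "fully surrounded by zero
    intensity pixels" and are discarded, as are components below the
    minimum-area threshold (and above ``max_extent``, if configured).
    """
    config = config or ForgeConfig()
    arr = np.asarray(binary, dtype=bool)
    labels = measure.label(arr, connectivity=config.connectivity)
    out: list[ShapeComponent] = []
    for prop in measure.regionprops(labels):
        minr, minc, maxr, maxc = prop.bbox
        if minr == 0 or minc == 0 or maxr == arr.shape[0] or maxc == arr.shape[1]:
            continue
        if prop.area < config.min_area:
            continue
        if config.max_extent is not None and (
            maxr - minr > config.max_extent or maxc - minc > config.max_extent
        ):
            continue
        out.append(
            ShapeComponent(
                mask=prop.image.astype(bool),
                area=int(prop.area),
                perimeter=float(prop.perimeter_crofton),
            )
        )
    return out


def component_from_mask(mask: NDArray) -> ShapeComponent:
    """Rebuild a :class:`ShapeComponent` from a stored binary mask."""
    mask = np.asarray(mask, dtype=bool)
    props = measure.regionprops(mask.astype(np.uint8))
    if len(props) != 1:
        raise ValueError("mask must contain exactly one component")
    prop = props[0]
    return ShapeComponent(
        mask=prop.image.astype(bool),
        area=int(prop.area),
        perimeter=float(prop.perimeter_crofton),
    )


def compactness(component: ShapeComponent) -> float:
    """Isoperimetric ratio 4*pi*A/p**2: 1 for a circle, smaller the more
    elongated or ragged the shape.

    The perimeter is a Crofton estimate (4 projection directions), which is
    calibrated for this score: discretized disks of radius 5-30 score above
    0.8 while 1-pixel lines of length >= 20 score below 0.4.  Naive
    pixel-edge counting would systematically under-score round shapes.
    """
    if component.perimeter <= 0:
        raise ValueError("component has zero perimeter estimate")
    return 4.0 * np.pi * component.area / component.perimeter**2


def classify_shape(score: float, config: ForgeConfig | None = None) -> str:
    """Map a compactness score to REGULAR, IRREGULAR or REJECTED."""
    config = config or ForgeConfig()
    if score < 0:
        raise ValueError("compactness is non-negative")
    if score > config.regular_min:
        return REGULAR
    if score < config.irregular_max:
        return IRREGULAR
    return REJECTED


def finalize_lesion(
    component: ShapeComponent,
    w: float,
    source_seed: int = -1,
    config: ForgeConfig | None = None,
) -> LesionStamp:
    """Pad a component with a 2-pixel zero margin, taper its boundary with a
    Gaussian (sigma ``stamp_sigma``), and rescale to peak intensity ``w``."""
    config = config or ForgeConfig()
    if not 0 < w <= 1:
        raise ValueError(f"intensity scale w must be in (0, 1], got {w}")
    score = compactness(component)
    shape_class = classify_shape(score, config)
    if shape_class == REJECTED:
        raise ValueError(
            f"component compactness {score:.3f} falls in the rejected band"
        )
    padded = np.pad(component.mask.astype(float), 2)
    smoothed = ndi.gaussian_filter(padded, config.stamp_sigma, mode="constant")
    peak = smoothed.max()
    if peak <= 0:
        raise DegenerateInputError("smoothed stamp has no positive support")
    patch = smoothed * (w / peak)
    return LesionStamp(
        patch=patch,
        component_mask=component.mask.copy(),
        shape_class=shape_class,
        compactness=score,
        source_seed=source_seed,
        w=w,
    )


def candidates_from_noise(
    seed: int, config: ForgeConfig
) -> tuple[list[ShapeComponent], list[ShapeComponent]]:
    """Run one noise image through both morphology branches.

    Returns (regular-branch candidates, irregular-branch candidates); the
    candidates still need compactness classification.
    """
    noise = generate_noise(seed, config.noise_size)
    smoothed = smooth_gaussian(noise, config.smooth_sigma)
    binary = binarize_otsu(smoothed)
    reg_branch = apply_regular_morphology(binary, config)
    irr_branch = apply_irregular_morphology(reg_branch, config)
    return extract_candidates(reg_branch, config), extract_candidates(irr_branch, config)


def build_lesion_bank(
    n_regular: int,
    n_irregular: int,
    seed: int,
    w: float = 0.5,
    config: ForgeConfig | None = None,
    max_noise_images: int = 200,
) -> LesionBank:
    """Iterate seeded noise images through the pipeline until both class
    quotas are met.

    Regular stamps come from the erosion+opening branch, irregular stamps
    from the extra-erosion branch.  Irregular shapes are the scarcer class,
    so ``n_irregular`` typically determines how many noise images are
    consumed.  Deterministic given ``seed`` and ``config``.
    """
    if n_regular < 1 or n_irregular < 1:
        raise ValueError("both class quotas must be >= 1")
    config = config or ForgeConfig()
    bank = LesionBank(generation_seed=seed, config=config)
    # independent noise seeds derived from the bank seed
    seed_seq = np.random.SeedSequence(seed)
    noise_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(max_noise_images)]
    for i, noise_seed in enumerate(noise_seeds):
        if len(bank.regular) >= n_regular and len(bank.irregular) >= n_irregular:
            break
        reg_cands, irr_cands = candidates_from_noise(noise_seed, config)
        for cand in reg_cands:
            if len(bank.regular) >= n_regular:
                break
            if classify_shape(compactness(cand), config) == REGULAR:
                bank.regular.append(finalize_lesion(cand, w, noise_seed, config))
        for cand in irr_cands:
            if len(bank.irregular) >= n_irregular:
                break
            if classify_shape(compactness(cand), config) == IRREGULAR:
                bank.irregular.append(finalize_lesion(cand, w, noise_seed, config))
        bank.noise_images_used = i + 1
    if len(bank.regular) < n_regular or len(bank.irregular) < n_irregular:
        raise GenerationExhaustedError(
            f"quotas not met after {max_noise_images} noise images: "
            f"{len(bank.regular)}/{n_regular} regular, "
            f"{len(bank.irregular)}/{n_irregular} irregular"
        )
    logger.info(
        "lesion bank built: %d regular, %d irregular from %d noise images",
        len(bank.regular), len(bank.irregular), bank.noise_images_used,
    )
    return bank


def write_bank(bank: LesionBank, directory: str | Path) -> None:
    """Serialize a bank as 16-bit PNG stamps plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "generation_seed": bank.generation_seed,
        "noise_images_used": bank.noise_images_used,
        "config": asdict(bank.config),
        "stamps": [],
    }
    for cls, stamps in ((REGULAR, bank.regular), (IRREGULAR, bank.irregular)):
        for k, stamp in enumerate(stamps):
            name = f"{cls}_{k:04d}.png"
            # stamps are stored scaled to the full 16-bit range; w restores them
            arr = np.round(stamp.patch / stamp.w * 65535).astype(np.uint16)
            Image.fromarray(arr).save(directory / name)
            comp_name = f"{cls}_{k:04d}_component.png"
            Image.fromarray(
                stamp.component_mask.astype(np.uint8) * 255, mode="L"
            ).save(directory / comp_name)
            manifest["stamps"].append(
                {
                    "file": name,
                    "component_file": comp_name,
                    "shape_class": stamp.shape_class,
                    "compactness": stamp.compactness,
                    "source_seed": stamp.source_seed,
                    "w": stamp.w,
                }
            )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_bank(directory: str | Path) -> LesionBank:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = ForgeConfig(**manifest["config"])
    bank = LesionBank(
        generation_seed=manifest["generation_seed"],
        noise_images_used=manifest["noise_images_used"],
        config=config,
    )
    for entry in manifest["stamps"]:
        arr = np.asarray(Image.open(directory / entry["file"]), dtype=np.float64)
        patch = arr / 65535.0 * entry["w"]
        comp = np.asarray(Image.open(directory / entry["component_file"])) > 0
        stamp = LesionStamp(
            patch=patch,
            component_mask=comp,
            shape_class=entry["shape_class"],
            compactness=entry["compactness"],
            source_seed=entry["source_seed"],
            w=entry["w"],
        )
        bank.stamps(entry["shape_class"]).append(stamp)
    return bank
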