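"""Compositing lesions onto backgrounds and dataset assembly.

Each benchmark image carries 3-5 lesions of a single shape class placed at
random non-overlapping locations inside the brain mask.  The composite is
``X = clip(B * (1 + L), 0, 1)``: a multiplicative brightening, so a lesion
of intensity ``w`` raises the local background by up to a factor ``1 + w``.
Lesion visibility therefore depends on the background underneath — the
property that makes background pixels act as suppressor variables for the
classifier, the failure mode the benchmark is designed to expose.  An
additive variant ``X = clip(B + L, 0, 1)`` is available for sensitivity
checks.

The ground-truth explanation of an image is the support of its lesion map:
the set of pixels any ideal attribution method should highlight.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from PIL import Image

from .backgrounds import BackgroundSlice, BACKGROUND_MAX
from .errors import DegenerateInputError, IntegrityError, PlacementExhaustedError
from .lesion_forge import IRREGULAR, REGULAR, LesionBank

logger = logging.getLogger(__name__)

LESION_COUNT_RANGE = (3, 5)
SPLITS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.6, 0.2, 0.2)


@dataclass(frozen=True)
class LesionMap:
    """Per-image lesion intensities: 0 outside lesions, (0, w] inside."""

    pixels: NDArray[np.float64]
    placements: list[tuple[int, tuple[int, int]]]  # (stamp index, top-left)

    @property
    def support(self) -> NDArray[np.bool_]:
        return self.pixels > 0


@dataclass(frozen=True)
class CompositeSample:
    sample_id: str
    image: NDArray[np.float64]
    label: str                       # REGULAR or IRREGULAR
    lesion_map: LesionMap
    ground_truth: NDArray[np.bool_]
    subject_id: str

    @property
    def n_ground_truth(self) -> int:
        return int(self.ground_truth.sum())


@dataclass
class BenchmarkDataset:
    samples: list[CompositeSample]
    splits: dict[str, str] = field(default_factory=dict)  # sample_id -> split
    seed: int = 0
    overlay_mode: str = "multiplicative"

    def subset(self, split: str) -> list[CompositeSample]:
        return [s for s in self.samples if self.splits.get(s.sample_id) == split]

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.subject_id)
        return list(seen)


def sample_lesion_count(rng: np.random.Generator) -> int:
    """Number of lesions per image, uniform over {3, 4, 5}."""
    lo, hi = LESION_COUNT_RANGE
    return int(rng.integers(lo, hi + 1))


def place_lesions(
    bank: LesionBank,
    label: str,
    count: int,
    background: BackgroundSlice,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> LesionMap:
    """Place ``count`` same-class stamps at random in-brain, non-overlapping
    positions by rejection sampling.

    A position is accepted only if the stamp's entire positive support lies
    inside the brain mask and intersects no previously placed support.
    Raises :class:`PlacementExhaustedError` if any lesion cannot be placed
    within ``max_attempts`` proposals.
    """
    lo, hi = LESION_COUNT_RANGE
    if not lo <= count <= hi:
        raise ValueError(f"lesion count must be in [{lo}, {hi}], got {count}")
    stamps = bank.stamps(label)
    if not stamps:
        raise ValueError(f"bank holds no {label} stamps")
    H, W = background.pixels.shape
    mask = background.brain_mask
    pixels = np.zeros((H, W))
    occupied = np.zeros((H, W), dtype=bool)
    placements: list[tuple[int, tuple[int, int]]] = []
    for _ in range(count):
        for attempt in range(max_attempts):
            stamp_idx = int(rng.integers(len(stamps)))
            stamp = stamps[stamp_idx]
            sh, sw = stamp.patch.shape
            if sh > H or sw > W:
                continue
            top = int(rng.integers(0, H - sh + 1))
            left = int(rng.integers(0, W - sw + 1))
            support = stamp.support
            region = np.s_[top : top + sh, left : left + sw]
            if not mask[region][support].all():
                continue
            if occupied[region][support].any():
                continue
            pixels[region][support] = stamp.patch[support]
            occupied[region] |= support
            placements.append((stamp_idx, (top, left)))
            break
        else:
            raise PlacementExhaustedError(
                f"could not place lesion {len(placements) + 1}/{count} "
                f"within {max_attempts} attempts"
            )
    return LesionMap(pixels=pixels, placements=placements)


def overlay(
    background: BackgroundSlice, lesion_map: LesionMap, mode: str = "multiplicative"
) -> NDArray[np.float64]:
    """Composite a lesion map onto a background.

    ``multiplicative`` (default): X = clip(B * (1 + L), 0, 1) — brightening
    proportional to the local background, so lesions vanish on black.
    ``additive``: X = clip(B + L, 0, 1), for sensitivity analyses.
    """
    B, L = background.pixels, lesion_map.pixels
    if B.shape != L.shape:
        raise ValueError(f"shape mismatch: {B.shape} vs {L.shape}")
    if mode == "multiplicative":
        X = B * (1.0 + L)
    elif mode == "additive":
        X = B + L
    else:
        raise ValueError(f"unknown overlay mode {mode!r}")
    return np.clip(X, 0.0, 1.0)


def ground_truth(lesion_map: LesionMap) -> NDArray[np.bool_]:
    """The ground-truth explanation mask: pixels with positive lesion intensity."""
    mask = lesion_map.support
    if not mask.any():
        raise DegenerateInputError("lesion map has empty support")
    return mask


def ground_truth_set(lesion_map: LesionMap) -> set[tuple[int, int]]:
    """Set-of-coordinates form of :func:`ground_truth`."""
    mask = ground_truth(lesion_map)
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(mask))}


def build_dataset(
    backgrounds: list[BackgroundSlice],
    bank: LesionBank,
    n_samples: int,
    seed: int,
    overlay_mode: str = "multiplicative",
    max_retries: int = 10,
) -> BenchmarkDataset:
    """Assemble a balanced two-class dataset.

    Classes alternate sample by sample (exact balance up to 1 for odd
    ``n_samples``); each sample draws its background uniformly at random,
    so every background serves both classes and background identity carries
    no label information.  If placement on a background fails, a fresh
    random background is retried up to ``max_retries`` times.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not backgrounds:
        raise ValueError("need at least one background")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD5]))
    samples: list[CompositeSample] = []
    for k in range(n_samples):
        label = REGULAR if k % 2 == 0 else IRREGULAR
        for retry in range(max_retries):
            bg = backgrounds[int(rng.integers(len(backgrounds)))]
            count = sample_lesion_count(rng)
            try:
                lmap = place_lesions(bank, label, count, bg, rng)
            except PlacementExhaustedError:
                logger.warning("placement failed on %s, retrying", bg.subject_id)
                continue
            samples.append(
                CompositeSample(
                    sample_id=f"s{k:05d}",
                    image=overlay(bg, lmap, overlay_mode),
                    label=label,
                    lesion_map=lmap,
                    ground_truth=ground_truth(lmap),
                    subject_id=bg.subject_id,
                )
            )
            break
        else:
            raise PlacementExhaustedError(
                f"sample {k}: placement failed on {max_retries} backgrounds"
            )
    return BenchmarkDataset(samples=samples, seed=seed, overlay_mode=overlay_mode)


def split_by_subject(
    dataset: BenchmarkDataset,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> BenchmarkDataset:
    """Assign train/val/test splits at the subject level (no leakage).

    Subjects (never individual samples) are partitioned by the given
    fractions, so all samples of a subject share a split.  The assignment
    is stratified by each subject's class imbalance (greedy assignment of
    the most imbalanced subjects first, with seeded reshuffles) so that
    per-split class balance holds within one sample.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    subjects = dataset.subject_ids
    if len(subjects) < 3:
        raise ValueError("subject-wise splitting needs at least 3 subjects")
    n = len(subjects)
    n_train = max(1, min(int(round(fractions[0] * n)), n - 2))
    n_val = max(1, min(int(round(fractions[1] * n)), n - n_train - 1))
    sizes = {"train": n_train, "val": n_val, "test": n - n_train - n_val}
    imbalance = {subj: 0 for subj in subjects}
    counts = {subj: 0 for subj in subjects}
    for s in dataset.samples:
        imbalance[s.subject_id] += 1 if s.label == REGULAR else -1
        counts[s.subject_id] += 1
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B]))
    best_assignment, best_score = None, None
    for _ in range(200):
        order = sorted(
            (subjects[i] for i in rng.permutation(n)),
            key=lambda subj: -abs(imbalance[subj]),
        )
        assignment: dict[str, str] = {}
        load = {k: 0 for k in SPLITS}   # running class imbalance per split
        room = dict(sizes)
        for subj in order:
            candidates = [k for k in SPLITS if room[k] > 0]
            split = min(candidates, key=lambda k: abs(load[k] + imbalance[subj]))
            assignment[subj] = split
            load[split] += imbalance[subj]
            room[split] -= 1
        score = max(abs(v) for v in load.values())
        if best_score is None or score < best_score:
            best_assignment, best_score = assignment, score
        if score <= 1:
            break
    if best_score > 1:
        logger.warning(
            "stratified split left a class imbalance of %d in one split", best_score
        )
    dataset.splits = {
        s.sample_id: best_assignment[s.subject_id] for s in dataset.samples
    }
    return dataset


def _png16(arr: NDArray, scale: float) -> Image.Image:
    return Image.fromarray(np.round(arr / scale * 65535).astype(np.uint16))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(dataset: BenchmarkDataset, directory: str | Path) -> None:
    """Write images and masks as 16-bit PNG with a CSV manifest, a JSON
    config snapshot and per-file checksums."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(exist_ok=True)
    rows = []
    files: list[Path] = []
    for s in dataset.samples:
        img_path = directory / "images" / f"{s.sample_id}.png"
        mask_path = directory / "masks" / f"{s.sample_id}.png"
        _png16(s.image, 1.0).save(img_path)
        Image.fromarray(
            (s.ground_truth.astype(np.uint16)) * 65535
        ).save(mask_path)
        files += [img_path, mask_path]
        rows.append(
            {
                "sample_id": s.sample_id,
                "label": s.label,
                "split": dataset.splits.get(s.sample_id, ""),
                "subject_id": s.subject_id,
                "n_lesions": len(s.lesion_map.placements),
                "n_ground_truth": s.n_ground_truth,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    config = {
        "seed": dataset.seed,
        "overlay_mode": dataset.overlay_mode,
        "n_samples": len(dataset.samples),
        "background_max": BACKGROUND_MAX,
    }
    (directory / "config.json").write_text(json.dumps(config, indent=1))
    files += [directory / "manifest.csv", directory / "config.json"]
    checksums = "\n".join(
        f"{_sha256(f)}  {f.relative_to(directory)}" for f in files
    )
    (directory / "checksums.txt").write_text(checksums + "\n")


def read_dataset(directory: str | Path, verify: bool = True) -> BenchmarkDataset:
    """Read a dataset directory back; raises :class:`IntegrityError` on
    checksum or manifest inconsistencies.

    Lesion maps are not serialized, so reconstructed samples carry the
    ground-truth mask as their lesion map support with unit placements.
    """
    directory = Path(directory)
    if not (directory / "manifest.csv").exists():
        raise IntegrityError(f"{directory} has no manifest.csv")
    if verify:
        for line in (directory / "checksums.txt").read_text().splitlines():
            digest, rel = line.split(None, 1)
            target = directory / rel.strip()
            if not target.exists():
                raise IntegrityError(f"missing file {rel}")
            if _sha256(target) != digest:
                raise IntegrityError(f"checksum mismatch for {rel}")
    manifest = pd.read_csv(directory / "manifest.csv", keep_default_na=False)
    config = json.loads((directory / "config.json").read_text())
    samples = []
    for row in manifest.itertuples():
        image = (
            np.asarray(Image.open(directory / "images" / f"{row.sample_id}.png"), float)
            / 65535.0
        )
        gt = (
            np.asarray(Image.open(directory / "masks" / f"{row.sample_id}.png")) > 0
        )
        if int(gt.sum()) != row.n_ground_truth:
            raise IntegrityError(
                f"{row.sample_id}: mask support {int(gt.sum())} != manifest "
                f"{row.n_ground_truth}"
            )
        lmap = LesionMap(pixels=gt.astype(float), placements=[])
        samples.append(
            CompositeSample(
                sample_id=row.sample_id,
                image=image,
                label=row.label,
                lesion_map=lmap,
                ground_truth=gt,
                subject_id=row.subject_id,
            )
        )
    splits = {
        row.sample_id: row.split for row in manifest.itertuples() if row.split
    }
    return BenchmarkDataset(
        samples=samples,
        splits=splits,
        seed=config["seed"],
        overlay_mode=config["overlay_mode"],
    )
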