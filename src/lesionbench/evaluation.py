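"""Explanation-performance scoring and aggregation.

The metric is top-n precision against the ground-truth lesion mask: with
n = |F| the number of ground-truth pixels, take the n highest-scoring
heat-map pixels and report the fraction that fall inside F,

    EP = |Top_n(s) ∩ F| / |F|.

Because exactly n pixels are selected, precision and recall coincide, and
the score is invariant under any strictly increasing transform of the heat
map.  A uniformly random heat map scores |F| / (total pixels) in
expectation (the mean of the hypergeometric overlap), which is the floor
any useful attribution method must clear.

Ties between equal scores are broken deterministically in row-major pixel
order by default; a seeded randomized tie-break is available to quantify
tie sensitivity for sparse maps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .baseline_explainers import HeatMap
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EPRecord:
    sample_id: str
    method: str
    model_id: str
    degree: str
    ep: float
    n_ground_truth: int
    correctly_classified: bool


def top_n_indices(
    heatmap: HeatMap | NDArray,
    n: int,
    tie_break: str = "row-major",
    rng: np.random.Generator | None = None,
) -> NDArray[np.intp]:
    """Flat indices of the ``n`` highest-scoring pixels.

    Equal scores are resolved in row-major order (``tie_break="row-major"``,
    the reproducible default) or by a seeded shuffle (``"random"``).
    """
    scores = heatmap.scores if isinstance(heatmap, HeatMap) else np.asarray(heatmap)
    flat = scores.ravel()
    if not 1 <= n <= flat.size:
        raise ValueError(f"n must be in [1, {flat.size}], got {n}")
    if tie_break == "row-major":
        order = np.argsort(-flat, kind="stable")
    elif tie_break == "random":
        if rng is None:
            raise ValueError("random tie-breaking needs an rng")
        perm = rng.permutation(flat.size)
        order = perm[np.argsort(-flat[perm], kind="stable")]
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return order[:n]


def explanation_precision(
    heatmap: HeatMap | NDArray,
    gt_mask: NDArray,
    tie_break: str = "row-major",
    rng: np.random.Generator | None = None,
) -> float:
    """Top-n precision of a heat map against a ground-truth mask, n = |F|."""
    scores = heatmap.scores if isinstance(heatmap, HeatMap) else np.asarray(heatmap)
    gt = np.asarray(gt_mask, dtype=bool)
    if scores.shape != gt.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {gt.shape}")
    n = int(gt.sum())
    if n == 0:
        raise DegenerateInputError("ground-truth mask is empty")
    top = top_n_indices(scores, n, tie_break=tie_break, rng=rng)
    hits = gt.ravel()[top].sum()
    return float(hits / n)


def evaluate_batch(
    heatmaps: dict[str, dict[str, HeatMap]],
    dataset,
    predictions: pd.DataFrame,
) -> tuple[list[EPRecord], list[EPRecord]]:
    """Score every (sample, method) heat map against the sample's ground truth.

    ``heatmaps`` maps sample_id -> method name -> heat map; ``predictions``
    is a frame with columns sample_id, model_id, degree, predicted, true.
    Returns ``(all_records, intersection_records)`` where the second list is
    restricted to samples correctly classified by *every* model in the
    predictions frame — the view used for headline reporting.  Samples with
    missing heat maps are logged and skipped, never imputed.
    """
    required = {"sample_id", "model_id", "predicted", "true"}
    if not required.issubset(predictions.columns):
        raise ValueError(f"predictions must have columns {sorted(required)}")
    preds = predictions.copy()
    if "degree" not in preds.columns:
        preds["degree"] = ""
    preds["correct"] = preds["predicted"] == preds["true"]
    correct_by_all = set(
        preds.groupby("sample_id")["correct"].all().pipe(lambda s: s[s].index)
    )
    by_id = {s.sample_id: s for s in dataset.samples}
    records: list[EPRecord] = []
    skipped = 0
    for row in preds.itertuples():
        sample = by_id.get(row.sample_id)
        methods = heatmaps.get(row.sample_id)
        if sample is None or not methods:
            skipped += 1
            logger.warning("no heat maps for sample %s; skipped", row.sample_id)
            continue
        for method, hm in methods.items():
            records.append(
                EPRecord(
                    sample_id=row.sample_id,
                    method=method,
                    model_id=str(row.model_id),
                    degree=str(row.degree),
                    ep=explanation_precision(hm, sample.ground_truth),
                    n_ground_truth=sample.n_ground_truth,
                    correctly_classified=bool(row.correct),
                )
            )
    if skipped:
        logger.warning("%d prediction rows skipped for missing heat maps", skipped)
    intersection = [r for r in records if r.sample_id in correct_by_all]
    return records, intersection


def summarize(records: list[EPRecord]) -> pd.DataFrame:
    """Descriptive statistics of EP per (method, model, degree) group.

    Quartiles use linear interpolation, matching the usual boxplot
    convention.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame([asdict(r) for r in records])
    grouped = df.groupby(["method", "model_id", "degree"], sort=True)["ep"]
    out = grouped.agg(
        count="count",
        mean="mean",
        min="min",
        q1=lambda s: s.quantile(0.25),
        median="median",
        q3=lambda s: s.quantile(0.75),
        max="max",
    ).reset_index()
    return out


def export_report(
    summary: pd.DataFrame,
    records: list[EPRecord],
    directory: str | Path,
    metadata: dict | None = None,
    boxplot: bool = False,
) -> None:
    """Write ep_records.csv, ep_summary.csv and run.json (plus an optional
    boxplot figure) into an existing directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    pd.DataFrame([asdict(r) for r in records]).to_csv(
        directory / "ep_records.csv", index=False
    )
    summary.to_csv(directory / "ep_summary.csv", index=False)
    (directory / "run.json").write_text(json.dumps(metadata or {}, indent=1))
    if boxplot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = pd.DataFrame([asdict(r) for r in records])
        fig, ax = plt.subplots(figsize=(8, 4))
        df.boxplot(column="ep", by="method", ax=ax)
        ax.set_ylabel("explanation performance")
        fig.suptitle("")
        fig.savefig(directory / "ep_boxplot.png", dpi=120)
        plt.close(fig)
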