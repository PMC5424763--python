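"""Confusion-matrix arithmetic and end-to-end pipeline orchestration.

The 2x2 confusion matrix is laid out rows = predicted, columns = actual,
classes (good, NG).  Per-class accuracy is the column-normalized diagonal;
the overall accuracy is pooled over all samples (total correct / total),
which for unequal class sizes differs from the unweighted mean of the two
per-class accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from seedvision.bpnn import BPNNModel, GOOD, NG, combine, predict_batch
from seedvision.features import extract_features
from seedvision.imaging import segment_frame

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix2:
    """counts[predicted][actual] for classes (good, ng)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a 2x2 nonnegative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(pred, truth) -> ConfusionMatrix2:
    """Tally predicted vs actual good/ng labels."""
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth) or not pred:
        raise ValueError("pred and truth must have equal positive length")
    idx = {GOOD: 0, NG: 1}
    counts = np.zeros((2, 2), dtype=np.int64)
    for p, t in zip(pred, truth):
        counts[idx[p], idx[t]] += 1
    return ConfusionMatrix2(counts)


def accuracies(cm: ConfusionMatrix2) -> tuple[float, float, float]:
    """(good, NG, overall) accuracies as percents rounded to 2 decimals."""
    c = cm.counts
    good_total = c[:, 0].sum()
    ng_total = c[:, 1].sum()
    if good_total == 0 or ng_total == 0:
        raise ValueError("both classes must be present in the truth labels")
    acc_good = 100.0 * c[0, 0] / good_total
    acc_ng = 100.0 * c[1, 1] / ng_total
    acc_overall = 100.0 * (c[0, 0] + c[1, 1]) / c.sum()
    return round(float(acc_good), 2), round(float(acc_ng), 2), round(float(acc_overall), 2)


def _subset_features(row: dict[str, float], model: BPNNModel) -> np.ndarray:
    return np.array([row[c] for c in model.feature_columns], dtype=np.float64)


def classify_regions(regions, shape_model: BPNNModel, colortex_model: BPNNModel,
                     **feature_kwargs) -> pd.DataFrame:
    """Per-region features, per-net verdicts and the combined AND label."""
    rows = []
    for reg in regions:
        feats = extract_features(reg, **feature_kwargs)
        s_rows = _subset_features(feats, shape_model)[None, :]
        c_rows = _subset_features(feats, colortex_model)[None, :]
        s_lab = predict_batch(shape_model, s_rows)[0]
        c_lab = predict_batch(colortex_model, c_rows)[0]
        rows.append({
            "region_id": reg.region_id,
            "centroid_row": reg.centroid[0], "centroid_col": reg.centroid[1],
            "shape_label": s_lab, "colortex_label": c_lab,
            "label": combine(s_lab, c_lab),
            **feats,
        })
    return pd.DataFrame(rows)


def run_pipeline(frames, shape_model: BPNNModel, colortex_model: BPNNModel,
                 truth=None, segment_kwargs: dict | None = None,
                 feature_kwargs: dict | None = None):
    """Segment, featurize and classify a list of frames.

    ``frames`` is a list of (H, W, 3) arrays.  Optional ``truth`` is a list
    (parallel to frames) of ``(centroid, label)`` pairs per frame; predicted
    regions are matched to truth seeds by nearest centroid.  Returns
    ``(per_seed_table, report)`` where the report carries the confusion
    matrix and accuracies when truth was given.
    """
    if not shape_model.feature_columns or not colortex_model.feature_columns:
        raise ValueError("models must record the feature columns they were trained on")
    segment_kwargs = segment_kwargs or {}
    feature_kwargs = feature_kwargs or {}
    tables = []
    matched_pred, matched_truth = [], []
    for fi, frame in enumerate(frames):
        regions = segment_frame(frame, **segment_kwargs)
        if not regions:
            logger.warning("frame %d: no regions found, skipped", fi)
            continue
        table = classify_regions(regions, shape_model, colortex_model, **feature_kwargs)
        table.insert(0, "frame", fi)
        if truth is not None:
            cents = np.array([[r["centroid_row"], r["centroid_col"]]
                              for _, r in table.iterrows()])
            truth_labels = []
            for _, row in table.iterrows():
                pt = np.array([row["centroid_row"], row["centroid_col"]])
                tc = np.array([c for c, _ in truth[fi]])
                j = int(np.argmin(((tc - pt) ** 2).sum(1)))
                truth_labels.append(truth[fi][j][1])
            table["truth"] = truth_labels
            matched_pred.extend(table["label"])
            matched_truth.extend(truth_labels)
        tables.append(table)
    per_seed = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    report: dict = {"n_frames": len(frames), "n_seeds": len(per_seed)}
    if truth is not None and matched_pred:
        cm = confusion(matched_pred, matched_truth)
        acc_good, acc_ng, acc_overall = accuracies(cm)
        report.update(
            confusion=cm,
            acc_good=acc_good,
            acc_ng=acc_ng,
            acc_overall=acc_overall,
        )
    return per_seed, report
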