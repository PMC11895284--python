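"""Classifier evaluation: AUC, F-score, AUCPR and a replication harness.

AUC is computed rank-based (Mann-Whitney, midranks for ties). AUCPR uses
step-wise summation over descending score thresholds — the average-
precision form — because trapezoidal interpolation on a precision-recall
curve is optimistic. ``benchmark`` repeats a pipeline over independently
seeded synthetic replicates and tabulates per-replicate and mean metrics,
mirroring a multi-iteration evaluation protocol.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._errors import DataError


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y.astype(float) > 0.5
    return y


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Ties in the scores receive midranks. Requires both classes present.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def f_score(pred: Sequence, truth: Sequence, positive_class) -> float:
    """F1 = 2PR/(P+R) for one class; 0 with a warning when P+R = 0."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    tp = int(((pred == positive_class) & (truth == positive_class)).sum())
    fp = int(((pred == positive_class) & (truth != positive_class)).sum())
    fn = int(((pred != positive_class) & (truth == positive_class)).sum())
    if 2 * tp + fp + fn == 0:
        warnings.warn(
            f"no predictions or truths for class {positive_class!r}; F1 = 0",
            stacklevel=2,
        )
        return 0.0
    if tp == 0 and (fp == 0 or fn == 0):
        if fp == 0 and fn > 0:
            warnings.warn(
                f"no predicted positives for class {positive_class!r}; F1 = 0",
                stacklevel=2,
            )
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def macro_f1(pred: Sequence, truth: Sequence, classes: Sequence | None = None) -> float:
    """Unweighted mean of per-class F1 over the classes present in truth."""
    truth = np.asarray(truth)
    if classes is None:
        classes = np.unique(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.mean([f_score(pred, truth, c) for c in classes]))


def aucpr(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the precision-recall curve by step summation.

    Thresholds descend through the unique scores; the area is
    sum_i (R_i - R_{i-1}) * P_i, i.e., average precision. All-identical
    scores give the positive prevalence. Requires at least one positive.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise DataError("AUCPR requires at least one positive label")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    n_pred = np.arange(1, len(y) + 1)
    # evaluate only at the last index of each tied-score block
    block_end = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    precision = tp[block_end] / n_pred[block_end]
    recall = tp[block_end] / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def benchmark(
    pipeline_fn: Callable[[int], dict],
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Run a pipeline over independently seeded replicates.

    ``pipeline_fn(seed)`` must return a flat mapping from metric name (or
    ``(metric, cell_type)`` tuple) to value. The result table has columns
    rep, seed, metric, cell_type, value, followed by mean rows (rep="mean",
    seed blank). Pipeline errors are re-raised annotated with the
    replicate index.
    """
    rows = []
    for rep, seed in enumerate(seeds):
        try:
            result = pipeline_fn(int(seed))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on replicate {rep} (seed {seed})") from exc
        for key, value in result.items():
            metric, cell_type = key if isinstance(key, tuple) else (key, "")
            rows.append(
                {"rep": rep, "seed": int(seed), "metric": metric,
                 "cell_type": cell_type, "value": float(value)}
            )
    table = pd.DataFrame(rows)
    means = (
        table.groupby(["metric", "cell_type"], as_index=False)["value"]
        .mean()
        .assign(rep="mean", seed="")
    )
    return pd.concat(
        [table, means[["rep", "seed", "metric", "cell_type", "value"]]],
        ignore_index=True,
    )
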