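"""Balanced-resampling cross-validation and the window-size scan.

Binding residues are vastly outnumbered by non-binding ones, so each
evaluation round draws a negative subset equal in size to the positive set
(uniformly, without replacement), runs a stratified 5-fold cross-validation
on the balanced set, and repeats the draw ten times; the reported metrics
are the average over the ten resamples.  Within every fold the scoring
matrices, diversity sources, background distribution and feature
standardization are fitted on the training folds only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError
from .features import SegmentFeaturizer
from .metrics import ConfusionCounts, Metrics, compute_metrics, mean_metrics
from .records import ProteinRecord, Segment, extract_all_windows
from .svm import PukParams, fit_svm


@dataclass
class CvConfig:
    window_length: int = 9
    feature_set: str = "refinement"
    folds: int = 5
    resamples: int = 10
    puk: PukParams = field(default_factory=PukParams)
    seed: int = 0
    background: str = "pooled"
    position_encoding: str = "pwm"
    averaging: str = "macro"  # macro: mean of per-resample metrics; micro: pool all counts

    def to_dict(self) -> dict:
        d = {
            "window_length": self.window_length,
            "feature_set": self.feature_set,
            "folds": self.folds,
            "resamples": self.resamples,
            "seed": self.seed,
            "background": self.background,
            "position_encoding": self.position_encoding,
            "averaging": self.averaging,
            "puk": {
                "omega": self.puk.omega,
                "sigma": self.puk.sigma,
                "C": self.puk.C,
                "tolerance": self.puk.tolerance,
            },
        }
        return d


@dataclass
class FoldResult:
    counts: ConfusionCounts
    metrics: Metrics


@dataclass
class ResampleResult:
    folds: list[FoldResult]
    counts: ConfusionCounts  # pooled over folds
    metrics: Metrics         # from the pooled counts


@dataclass
class CvReport:
    config: dict
    resamples: list[ResampleResult]
    average: Metrics

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "resamples": [
                {
                    "folds": [
                        {
                            "counts": vars(f.counts),
                            "metrics": f.metrics.to_dict(),
                        }
                        for f in r.folds
                    ],
                    "counts": vars(r.counts),
                    "metrics": r.metrics.to_dict(),
                }
                for r in self.resamples
            ],
            "average": self.average.to_dict(),
        }

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        """One row per resample x fold, plus per-resample and overall rows."""
        rows = []
        for ri, r in enumerate(self.resamples):
            for fi, f in enumerate(r.folds):
                rows.append({"resample": ri, "fold": fi, **f.metrics.to_dict()})
            rows.append({"resample": ri, "fold": "pooled", **r.metrics.to_dict()})
        rows.append({"resample": "average", "fold": "", **self.average.to_dict()})
        return pd.DataFrame(rows)


def _derive_seed(seed: int, *parts: int) -> int:
    h = np.uint32(seed & 0x7FFFFFFF)
    for p in parts:
        h = np.uint32((int(h) * 1000003 + p + 1) % 2147483647)
    return int(h)


def _evaluate_fold(
    segments: list[Segment],
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: CvConfig,
    fold_seed: int,
) -> ConfusionCounts:
    train_segs = [segments[i] for i in train_idx]
    test_segs = [segments[i] for i in test_idx]
    featurizer = SegmentFeaturizer(
        feature_set=config.feature_set,
        background=config.background,
        position_encoding=config.position_encoding,
    )
    x_train = featurizer.fit_transform(train_segs, labels[train_idx] > 0)
    x_test = featurizer.transform(test_segs)
    model = fit_svm(
        x_train, labels[train_idx], params=config.puk, seed=fold_seed,
        layout=featurizer.layout(),
    )
    y_pred = model.predict(x_test)
    return ConfusionCounts.from_predictions(labels[test_idx], y_pred)


def balanced_cv(segments: list[Segment], config: CvConfig | None = None) -> CvReport:
    """Run the balanced-resampling stratified k-fold protocol on labeled segments."""
    config = config or CvConfig()
    labels = np.array([1 if s.label else -1 for s in segments])
    pos_idx = np.flatnonzero(labels > 0)
    neg_idx = np.flatnonzero(labels < 0)
    n_pos = pos_idx.size
    if n_pos < config.folds or neg_idx.size < config.folds:
        raise ParameterError(
            f"need at least {config.folds} segments per class "
            f"(have {n_pos} positive, {neg_idx.size} negative)"
        )
    if neg_idx.size < n_pos:
        raise ParameterError("fewer negative than positive segments; cannot balance")

    resample_results = []
    for r in range(config.resamples):
        rng = np.random.default_rng(_derive_seed(config.seed, r))
        sampled_neg = rng.choice(neg_idx, size=n_pos, replace=False)
        subset = np.concatenate([pos_idx, np.sort(sampled_neg)])
        sub_segments = [segments[i] for i in subset]
        sub_labels = labels[subset]
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=_derive_seed(config.seed, r, 7)
        )
        folds = []
        pooled = ConfusionCounts(0, 0, 0, 0)
        for fi, (tr, te) in enumerate(skf.split(np.zeros(len(sub_labels)), sub_labels)):
            counts = _evaluate_fold(
                sub_segments, sub_labels, tr, te, config, _derive_seed(config.seed, r, fi, 13)
            )
            folds.append(FoldResult(counts, compute_metrics(counts)))
            pooled = pooled + counts
        resample_results.append(ResampleResult(folds, pooled, compute_metrics(pooled)))

    if config.averaging == "micro":
        total = ConfusionCounts(0, 0, 0, 0)
        for r in resample_results:
            total = total + r.counts
        average = compute_metrics(total)
    else:
        average = mean_metrics([r.metrics for r in resample_results])
    return CvReport(config=config.to_dict(), resamples=resample_results, average=average)


def balanced_cv_records(records: list[ProteinRecord], config: CvConfig | None = None) -> CvReport:
    """Extract windows from full protein records, then run :func:`balanced_cv`."""
    config = config or CvConfig()
    return balanced_cv(extract_all_windows(records, config.window_length), config)


@dataclass
class WindowScanResult:
    reports: dict[int, CvReport]
    best_window: int

    def mcc_by_window(self) -> dict[int, float]:
        return {L: rep.average.mcc for L, rep in self.reports.items()}


def window_scan(
    records: list[ProteinRecord],
    sizes: tuple[int, ...] = (5, 7, 9, 11, 13, 15, 17),
    config: CvConfig | None = None,
) -> WindowScanResult:
    """Evaluate each odd window size and select the one maximizing average MCC.

    Ties break toward the smaller window.
    """
    config = config or CvConfig()
    for L in sizes:
        if L < 3 or L % 2 == 0:
            raise ParameterError(f"window sizes must be odd and >= 3, got {L}")
    reports: dict[int, CvReport] = {}
    for L in sizes:
        reports[L] = balanced_cv_records(records, dataclasses.replace(config, window_length=L))
    best = min(sorted(reports), key=lambda L: (-reports[L].average.mcc, L))
    return WindowScanResult(reports=reports, best_window=best)
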