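"""Evaluation protocol: stratified 10-fold CV, metrics, and the pipeline.

The full pipeline chains every stage of the method: synthetic EEG segments
(1/2/4 s windows) -> TKEO energy series -> quantized spectrogram image ->
chaotic baker + Arnold encryption -> compact CNN ensemble (one member per
seed) -> HSO-tuned soft fusion, scored by stratified k-fold cross-
validation. Metrics follow the seizure-detection convention with *ictal* as
the positive class (one-vs-rest for 3-class runs):

    accuracy    = (TP + TN) / total
    sensitivity = TP / (TP + FN)          (recall of seizures)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * prec * sens / (prec + sens)

all reported as percentages, per fold and as mean / median / sd across
folds. Group differences across methods are tested per metric with the
non-parametric Kruskal-Wallis H test (tie-corrected, chi-square p with
k - 1 degrees of freedom); the degenerate all-identical case is defined as
H = 0, p = 1. The fusion weights are tuned on an inner validation split
(20% of each training fold) so the test fold never leaks into tuning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import cnn as cnn_mod
from . import crypto as crypto_mod
from . import features as feat_mod
from . import hso as hso_mod
from .synthetic import LABELS, GeneratorConfig, generate_dataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "PipelineConfig",
    "stratified_kfold",
    "compute_metrics",
    "kruskal_wallis",
    "run_pipeline",
    "compare_methods",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with ictal/seizure as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """The five evaluation metrics (percent). Undefined entries are NaN.

    A denominator of zero (e.g. precision with no positive predictions)
    yields ``nan`` rather than 0, flagging the metric as undefined.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    acc = (tp + tn) / counts.total
    sens = tp / (tp + fn) if tp + fn > 0 else math.nan
    spec = tn / (tn + fp) if tn + fp > 0 else math.nan
    prec = tp / (tp + fp) if tp + fp > 0 else math.nan
    if not math.isnan(prec) and not math.isnan(sens) and prec + sens > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        f1 = math.nan
    return {
        "accuracy": 100.0 * acc,
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "precision": 100.0 * prec,
        "f1": 100.0 * f1,
    }


def stratified_kfold(labels: Sequence, k: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: array of fold ids in [0, k).

    Folds partition the samples; each class is split as evenly as possible
    (per-fold class counts differ by at most one sample). Seeded shuffle.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        assignment[test_idx] = fold
    return assignment


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and p-value across >= 2 groups.

    Tie-corrected rank statistic with a chi-square approximation on k - 1
    degrees of freedom. If every observation is identical the test is
    defined as (H, p) = (0, 1).
    """
    gs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(gs)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*gs)
    return float(h), float(p)


@dataclass
class MetricsReport:
    """Per-fold metric values (percent) with summary rows."""

    per_fold: pd.DataFrame  # rows = folds, columns = METRIC_NAMES

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_fold.std(ddof=1)

    @property
    def median(self) -> pd.Series:
        return self.per_fold.median()

    def summary(self) -> pd.DataFrame:
        """Mean / median / sd table in the conventional 'm ± sd' layout."""
        out = pd.DataFrame(
            {"mean": self.mean, "median": self.median, "sd": self.sd}
        )
        out["mean ± sd"] = [
            f"{m:.2f} ± {s:.2f}" for m, s in zip(out["mean"], out["sd"])
        ]
        return out


@dataclass
class CVResult:
    """One cross-validated pipeline run."""

    segment_length_s: float
    method: str
    fold_assignment: np.ndarray
    report: MetricsReport
    multiclass_accuracy: pd.Series | None = None
    fusion_weights: list[np.ndarray] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.report.summary()


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs; JSON-(de)serializable."""

    n_per_class: int = 200
    segment_lengths_s: tuple[float, ...] = (1.0, 2.0, 4.0)
    sampling_rate: float = 256.0
    n_channels: int = 4
    channel: int = 0
    image_side: int = 48
    apply_tkeo: bool = True
    encrypt: bool = True
    baker_partition: tuple[int, ...] = (12, 24, 12)
    baker_iterations: int = 2
    arnold_iterations: int = 3
    n_classes: int = 3
    n_members: int = 2
    epochs: int = 20
    batch_size: int = 32
    lr: float = 0.005
    k_folds: int = 10
    inner_val_fraction: float = 0.2
    hso_m: int = 12
    hso_iterations: int = 40
    seed: int = 0

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        obj = json.loads(p.read_text() if p.exists() else str(source))
        obj = {
            k: tuple(v) if isinstance(v, list) else v for k, v in obj.items()
        }
        return cls(**obj)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _label_indices(labels: Sequence[str], n_classes: int) -> np.ndarray:
    if n_classes == 3:
        order = {lab: i for i, lab in enumerate(LABELS)}
    else:  # binary: seizure (ictal) vs non-seizure
        order = {"normal": 0, "preictal": 0, "ictal": 1}
    return np.array([order[lab] for lab in labels], dtype=np.intp)


def _ictal_counts(y_true: np.ndarray, y_pred: np.ndarray, ictal_idx: int) -> ConfusionCounts:
    pos_t = y_true == ictal_idx
    pos_p = y_pred == ictal_idx
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _prepare_images(config: PipelineConfig, length_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Generate segments and turn them into (encrypted) pixel arrays."""
    gen = GeneratorConfig(
        sampling_rate=config.sampling_rate,
        n_channels=config.n_channels,
        segment_length_s=length_s,
        seed=config.seed,
    )
    segments = generate_dataset(config.n_per_class, gen)
    perms = []
    if config.encrypt:
        baker = crypto_mod.BakerKey(
            config.image_side, config.baker_partition, config.baker_iterations
        )
        arnold = crypto_mod.ArnoldKey(config.image_side, config.arnold_iterations)
        # fixed composition order: baker first, then Arnold
        perms = [crypto_mod.build_permutation(baker), crypto_mod.build_permutation(arnold)]
    images = np.empty((len(segments), config.image_side, config.image_side), dtype=np.uint8)
    labels = []
    for i, seg in enumerate(segments):
        img = feat_mod.to_spectrogram(seg, config.channel, apply_tkeo=config.apply_tkeo)
        img = feat_mod.resize_image(img, config.image_side)
        for perm in perms:
            img = crypto_mod.encrypt_image(img, perm)
        images[i] = img.pixels
        labels.append(seg.label)
    return images, _label_indices(labels, config.n_classes)


def _run_cv(
    images: np.ndarray, y: np.ndarray, config: PipelineConfig, length_s: float
) -> CVResult:
    folds = stratified_kfold(y, config.k_folds, seed=config.seed)
    per_fold_rows = []
    multiclass_acc = []
    fusion_weights = []
    ictal_idx = 2 if config.n_classes == 3 else 1
    for fold in range(config.k_folds):
        test = folds == fold
        train_idx = np.flatnonzero(~test)
        test_idx = np.flatnonzero(test)
        tr_idx, val_idx = train_test_split(
            train_idx,
            test_size=config.inner_val_fraction,
            stratify=y[train_idx],
            random_state=config.seed + fold,
        )
        members = []
        for m in range(config.n_members):
            model = cnn_mod.CNNModel(
                input_side=config.image_side,
                n_classes=config.n_classes,
                conv_channels=(8, 16) if m % 2 == 0 else (6, 12),
                seed=config.seed * 1000 + fold * 10 + m,
            )
            cnn_mod.train(
                model,
                images[tr_idx],
                y[tr_idx],
                epochs=config.epochs,
                batch_size=config.batch_size,
                lr=config.lr,
                seed=config.seed * 1000 + fold * 10 + m,
            )
            members.append(model)
        val_probs = [m.predict_proba(images[val_idx]) for m in members]
        params = hso_mod.tune_fusion(
            val_probs,
            y[val_idx],
            hso_mod.HSOConfig(
                m=config.hso_m,
                max_iterations=config.hso_iterations,
                seed=config.seed + fold,
            ),
        )
        fusion_weights.append(params.weights)
        test_probs = [m.predict_proba(images[test_idx]) for m in members]
        fused = cnn_mod.ensemble_fuse(test_probs, params)
        y_pred = fused.argmax(axis=1)
        counts = _ictal_counts(y[test_idx], y_pred, ictal_idx)
        per_fold_rows.append(compute_metrics(counts))
        multiclass_acc.append(float(np.mean(y_pred == y[test_idx])))
    report = MetricsReport(pd.DataFrame(per_fold_rows, columns=list(METRIC_NAMES)))
    return CVResult(
        segment_length_s=length_s,
        method="tkeo+chaotic-cnn+hso" if config.encrypt else "tkeo+cnn+hso",
        fold_assignment=folds,
        report=report,
        multiclass_accuracy=pd.Series(multiclass_acc, name="multiclass_accuracy") * 100,
        fusion_weights=fusion_weights,
    )


def run_pipeline(
    config: PipelineConfig | str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict[float, CVResult]:
    """Run the full pipeline for every configured segment length.

    Returns {segment_length_s: CVResult}. If ``out_dir`` is given, writes a
    metrics CSV per length, a combined summary table, and a PNG of one
    sample (encrypted) spectrogram per class.
    """
    if config is None:
        config = PipelineConfig()
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_json(config)
    results: dict[float, CVResult] = {}
    for length_s in config.segment_lengths_s:
        images, y = _prepare_images(config, length_s)
        if out_dir is not None:
            _write_samples(images, y, config, length_s, Path(out_dir))
        results[length_s] = _run_cv(images, y, config, length_s)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for length_s, res in results.items():
            res.report.per_fold.to_csv(out / f"metrics_folds_{length_s:g}s.csv", index_label="fold")
            for metric in METRIC_NAMES:
                rows.append(
                    {
                        "segment_length_s": length_s,
                        "metric": metric,
                        "mean": res.report.mean[metric],
                        "median": res.report.median[metric],
                        "sd": res.report.sd[metric],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "metrics_summary.csv", index=False)
    return results


def _write_samples(
    images: np.ndarray, y: np.ndarray, config: PipelineConfig, length_s: float, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for cls in np.unique(y):
        idx = int(np.flatnonzero(y == cls)[0])
        img = feat_mod.SpectrogramImage(images[idx], config.channel)
        feat_mod.save_png(img, out / f"sample_{length_s:g}s_class{cls}.png", sidecar=False)


def compare_methods(results: Sequence[CVResult], alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis test per metric across >= 2 CV results.

    Returns a table with H, p, and a significance flag at ``alpha``.
    """
    if len(results) < 2:
        raise ValueError("need at least two CV results to compare")
    n_folds = {len(r.report.per_fold) for r in results}
    if len(n_folds) != 1:
        raise ValueError("all results must have the same fold count")
    rows = []
    for metric in METRIC_NAMES:
        groups = [r.report.per_fold[metric].to_numpy() for r in results]
        h, p = kruskal_wallis(groups)
        rows.append({"metric": metric, "H": h, "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows).set_index("metric")
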