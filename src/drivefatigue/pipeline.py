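"""End-to-end fatigue-detection pipeline.

Stages: resolve expert labels (unanimity / negotiation / discard), filter
flagged samples, extract per-window (ApEn_SWA, ApEn_YA) feature pairs,
train the 2-6-6-3 network on window features, classify each sample by
majority vote over its windows, and evaluate against the expert labels
with a three-class confusion matrix.

The network's input layer is two-dimensional, so classification is
necessarily per analysis window; a one-minute sample gets one decision by
majority vote over its 30 window labels, with ties broken toward the
higher (safer) fatigue level. A mean-feature mode — classify the mean
ApEn pair of the sample — is available as an alternative aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bpnn
from .apen import ApEnParams, sliding_window_apen
from .bpnn import MLPConfig, MLPModel
from .signal_io import DriveSample, FatigueLabel, filter_samples
from .simulate import generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ExpertScores",
    "ConfusionMatrix",
    "PipelineReport",
    "consensus_label",
    "extract_features",
    "train_classifier",
    "classify_sample",
    "evaluate",
    "stratified_split",
    "run_end_to_end",
]

N_LEVELS = 3


@dataclass(frozen=True)
class ExpertScores:
    """Three expert fatigue scores for one sample, plus an optional
    negotiated level reached after disagreement."""

    sample_index: int
    levels: tuple[int, int, int]
    negotiated: int | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError("exactly three expert scores required")


def consensus_label(scores: ExpertScores) -> FatigueLabel | None:
    """Resolve expert scores into a label, or ``None`` meaning discard.

    Unanimous scores decide directly; a disagreement is settled by the
    negotiated level when one was recorded; otherwise the sample is
    discarded (no consensus).
    """
    levels = []
    for v in scores.levels:
        try:
            levels.append(FatigueLabel(int(v)))
        except ValueError as exc:
            raise ValueError(f"invalid fatigue level code {v!r}") from exc
    if levels[0] == levels[1] == levels[2]:
        return levels[0]
    if scores.negotiated is not None:
        return FatigueLabel(int(scores.negotiated))
    return None


def extract_features(sample: DriveSample, params: ApEnParams) -> np.ndarray:
    """Per-window (ApEn_SWA, ApEn_YA) pairs for one sample.

    Returns an (n_windows, 2) array; with 2-s non-overlapping windows a
    60-s sample at 100 Hz yields 30 rows.
    """
    swa = sliding_window_apen(sample.swa, params)
    ya = sliding_window_apen(sample.ya, params)
    return np.column_stack([swa.values, ya.values])


def train_classifier(
    samples: list[DriveSample],
    apen_params: ApEnParams,
    config: MLPConfig,
) -> tuple[MLPModel, list[float]]:
    """Train the window-level classifier on labelled samples.

    Every analysis window inherits its sample's expert label; the network
    is trained full-batch on the pooled window features.
    """
    feats, labels = [], []
    for s in samples:
        if s.label is None:
            raise ValueError("all training samples must be labelled")
        F = extract_features(s, apen_params)
        feats.append(F)
        labels.extend([int(s.label)] * F.shape[0])
    X = np.vstack(feats)
    Y = bpnn.one_hot_targets(labels, N_LEVELS)
    model = bpnn.init_model(config)
    return bpnn.train(model, X, Y)


def classify_sample(
    model: MLPModel,
    sample: DriveSample,
    params: ApEnParams,
    aggregation: str = "majority",
) -> tuple[FatigueLabel, np.ndarray]:
    """Classify one sample; returns (sample label, per-window labels).

    ``aggregation="majority"`` votes over the window labels with ties
    broken toward the higher fatigue level (safety-conservative);
    ``"mean"`` classifies the sample's mean feature vector instead.
    """
    F = extract_features(sample, params)
    window_labels = bpnn.predict_batch(model, F)
    return _aggregate(window_labels, F, model, aggregation), window_labels


@dataclass
class ConfusionMatrix:
    """3x3 confusion matrix indexed (expert level, predicted level)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (N_LEVELS, N_LEVELS) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Overall accuracy: trace / total."""
        return float(np.trace(self.counts)) / self.total

    @property
    def class_totals(self) -> np.ndarray:
        """Number of evaluated samples per expert class."""
        return self.counts.sum(axis=1)

    def rates_percent(self) -> np.ndarray:
        """Row-normalised rates: of the samples an expert scored level e,
        the percentage detected as each level p. Rows sum to 100 where the
        expert class is non-empty."""
        totals = self.class_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = 100.0 * self.counts / totals[:, None]
        return np.where(totals[:, None] > 0, rates, np.nan)

    def to_frame(self) -> pd.DataFrame:
        names = [FatigueLabel(i).display_name for i in range(N_LEVELS)]
        return pd.DataFrame(self.counts,
                            index=pd.Index(names, name="expert"),
                            columns=pd.Index(names, name="predicted"))


def evaluate(predictions, truths) -> ConfusionMatrix:
    """Confusion matrix of predicted vs expert labels."""
    predictions = [int(p) for p in predictions]
    truths = [int(t) for t in truths]
    if len(predictions) != len(truths) or not truths:
        raise ValueError("predictions and truths must be non-empty and aligned")
    counts = np.zeros((N_LEVELS, N_LEVELS), dtype=int)
    for e, p in zip(truths, predictions):
        counts[e, p] += 1
    return ConfusionMatrix(counts)


def stratified_split(
    samples: list[DriveSample], train_fraction: float, seed: int
) -> tuple[list[int], list[int]]:
    """Stratified sample-level train/test index split.

    Splitting happens at the sample level, never at the window level, so
    windows from one sample can never straddle the split.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    by_level: dict[int, list[int]] = {}
    for i, s in enumerate(samples):
        if s.label is None:
            raise ValueError("all samples must be labelled before splitting")
        by_level.setdefault(int(s.label), []).append(i)
    for level in sorted(by_level):
        idx = np.array(by_level[level])
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1) if idx.size > 1 else idx.size
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return sorted(train_idx), sorted(test_idx)


@dataclass
class PipelineReport:
    """Everything an end-to-end run produces."""

    confusion: ConfusionMatrix
    predictions: list[FatigueLabel]
    truths: list[FatigueLabel]
    n_train: int
    n_test: int
    model: MLPModel
    mse_trace: list[float]

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.confusion.accuracy

    def summary(self) -> str:
        lines = [
            f"train samples: {self.n_train}   test samples: {self.n_test}",
            f"test accuracy: {self.accuracy_percent:.2f}%",
            "confusion matrix (rows = expert, cols = predicted):",
            self.confusion.to_frame().to_string(),
            "per-class rates (% within expert class):",
        ]
        rates = self.confusion.rates_percent()
        for i in range(N_LEVELS):
            name = FatigueLabel(i).display_name
            row = "  ".join(f"{rates[i, j]:6.2f}" for j in range(N_LEVELS))
            lines.append(f"  {name:>12}: {row}")
        return "\n".join(lines)


DEFAULT_CONFIG: dict = {
    "n_per_level": 20,
    "duration_s": 60.0,
    "fs": 100.0,
    "seed": 42,
    "train_fraction": 0.7,
    "aggregation": "majority",
    "apen": {},      # ApEnParams overrides
    "network": {},   # MLPConfig overrides
    "outdir": None,  # if set, intermediate CSVs and the report are written here
}


def _aggregate(window_labels: np.ndarray, features: np.ndarray,
               model: MLPModel, aggregation: str) -> FatigueLabel:
    if aggregation == "majority":
        counts = np.bincount(window_labels, minlength=N_LEVELS)
        return FatigueLabel(int(np.flatnonzero(counts == counts.max()).max()))
    if aggregation == "mean":
        label, _ = bpnn.predict(model, features.mean(axis=0))
        return label
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _write_outputs(outdir, samples, feature_list, apen_params, train_idx,
                   test_idx, predictions, report) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    step = apen_params.effective_step_s
    for i, F in enumerate(feature_list):
        for w in range(F.shape[0]):
            rows.append((i, w * step, F[w, 0], F[w, 1]))
    pd.DataFrame(rows, columns=["sample_index", "window_start_s",
                                "apen_swa", "apen_ya"]).to_csv(
        out / "features.csv", index=False)
    split = {i: "train" for i in train_idx} | {i: "test" for i in test_idx}
    pd.DataFrame(
        {"sample_index": range(len(samples)),
         "level": [int(s.label) for s in samples],
         "split": [split[i] for i in range(len(samples))]}
    ).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(
        {"sample_index": test_idx,
         "predicted_level": [int(p) for p in predictions],
         "true_level": [int(samples[i].label) for i in test_idx]}
    ).to_csv(out / "predictions.csv", index=False)
    report.confusion.to_frame().to_csv(out / "confusion.csv")
    (out / "report.txt").write_text(report.summary() + "\n")


def run_end_to_end(config: dict | None = None,
                   samples: list[DriveSample] | None = None) -> PipelineReport:
    """Run the full pipeline and return its report.

    With no ``samples``, a balanced synthetic dataset is generated from
    ``config["seed"]``. Stages: filter flagged samples, extract windowed
    ApEn features, stratified 70/30 sample-level split, train the window
    classifier on the training samples, majority-vote classify the test
    samples, evaluate. Fully deterministic given (config, samples). If
    ``config["outdir"]`` is set, the intermediate feature/label/prediction
    CSVs and the report are written there.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])

    if samples is None:
        samples = generate_dataset(
            n_per_level=int(cfg["n_per_level"]),
            duration_s=float(cfg["duration_s"]),
            fs=float(cfg["fs"]),
            seed=seed,
        )
    samples = filter_samples(samples)
    if not samples:
        raise RuntimeError("pipeline: no samples left after filtering")

    apen_params = ApEnParams(**cfg["apen"])
    net_overrides = dict(cfg["network"])
    net_overrides.setdefault("seed", seed + 1)
    net_config = MLPConfig(**net_overrides)

    # features are computed once per sample and reused for both phases
    feature_list = [extract_features(s, apen_params) for s in samples]

    train_idx, test_idx = stratified_split(samples, float(cfg["train_fraction"]),
                                           seed + 2)
    logger.info("pipeline: %d train / %d test samples",
                len(train_idx), len(test_idx))

    X = np.vstack([feature_list[i] for i in train_idx])
    y = np.concatenate([[int(samples[i].label)] * feature_list[i].shape[0]
                        for i in train_idx])
    model = bpnn.init_model(net_config)
    model, trace = bpnn.train(model, X, bpnn.one_hot_targets(y, N_LEVELS))

    predictions, truths = [], []
    for i in test_idx:
        window_labels = bpnn.predict_batch(model, feature_list[i])
        predictions.append(_aggregate(window_labels, feature_list[i], model,
                                      str(cfg["aggregation"])))
        truths.append(samples[i].label)
    confusion = evaluate(predictions, truths)
    report = PipelineReport(
        confusion=confusion,
        predictions=predictions,
        truths=truths,
        n_train=len(train_idx),
        n_test=len(test_idx),
        model=model,
        mse_trace=trace,
    )
    if cfg["outdir"]:
        _write_outputs(cfg["outdir"], samples, feature_list, apen_params,
                       train_idx, test_idx, predictions, report)
    return report
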