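"""Training, cross-validation, evaluation metrics and the threshold sweep.

Metrics follow the confusion-matrix definitions: TPR (= recall) = TP/(TP+FN),
specificity = TN/(TN+FP), FPR = 1 − specificity, precision = TP/(TP+FP), and
F1 the harmonic mean of precision and recall, plus threshold-free ROC AUC.
Ratios with a zero denominator are reported as ``None`` and named in
``EvalReport.undefined`` rather than raising or returning NaN.

Cross-validation is stratified (the active/inactive classes are imbalanced),
trains on k−1 folds and evaluates the held-out fold, and reports per-fold
metrics, their mean, and the best fold by F1. The sweep experiment
re-featurizes the dataset at each hydrogen-bond distance threshold (conformers
are embedded once and contacts re-filtered per threshold) and cross-validates
each setting with a shared seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .errors import SingleClassError
from .featurizer import DescriptorSet, FeaturizerConfig, featurize, hbond_matrix
from .model import MathModel, ModelConfig
from .pipeline import LabeledCompound

logger = logging.getLogger(__name__)

SWEEP_GRID = (2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0)


@dataclass
class EvalReport:
    """Confusion counts and derived classification metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: Optional[float]
    fpr: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    roc_auc: Optional[float]
    undefined: list[str] = field(default_factory=list)
    folds: list["EvalReport"] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("folds")
        return d

    def confusion_table(self) -> str:
        """Confusion matrix in the conventional actual-by-predicted layout."""
        return (
            "                 Predicted\n"
            "                 active  inactive\n"
            f"Actual active    {self.tp:6d}  {self.fn:8d}\n"
            f"Actual inactive  {self.fp:6d}  {self.tn:8d}"
        )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_and_metrics(
    y_true: Sequence[int],
    y_prob: Sequence[float],
    threshold: float = 0.5,
) -> EvalReport:
    """Threshold the scores (≥ threshold → active) and derive the metric suite.

    ROC AUC is computed over all thresholds (rank-based); it is undefined when
    only one class is present.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_prob.shape}")
    if y_prob.size and (y_prob.min() < 0 or y_prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    y_pred = (y_prob >= threshold).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    return metrics_from_counts(tp=tp, fp=fp, tn=tn, fn=fn, y_true=y_true, y_prob=y_prob)


def metrics_from_counts(
    tp: int, fp: int, tn: int, fn: int,
    y_true: Optional[np.ndarray] = None,
    y_prob: Optional[np.ndarray] = None,
) -> EvalReport:
    """Derive the metric suite from confusion counts (scores optional, for AUC)."""
    tpr = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    fpr = None if specificity is None else 1.0 - specificity
    f1 = None
    if precision is not None and tpr is not None and (precision + tpr) > 0:
        f1 = 2 * precision * tpr / (precision + tpr)
    roc_auc = None
    if y_true is not None and y_prob is not None and len(set(y_true.tolist())) == 2:
        roc_auc = float(roc_auc_score(y_true, y_prob))
    report = EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=tpr, fpr=fpr, specificity=specificity,
        precision=precision, recall=tpr, f1=f1, roc_auc=roc_auc,
    )
    report.undefined = [
        name for name in ("tpr", "fpr", "specificity", "precision", "recall", "f1", "roc_auc")
        if getattr(report, name) is None
    ]
    return report


# ---- featurization with caching -------------------------------------------


def featurize_records(
    records: Sequence[LabeledCompound],
    config: FeaturizerConfig,
    cache: Optional[dict] = None,
) -> tuple[list[DescriptorSet], np.ndarray, list[LabeledCompound]]:
    """Featurize every record; molecules that fail are logged and skipped.

    Returns (descriptors, binary labels, surviving records). ``cache`` maps
    (smiles, seed, threshold, mode-relevant options) → DescriptorSet across
    calls.
    """
    cache = cache if cache is not None else {}
    descs, labels, kept = [], [], []
    for rec in records:
        key = (
            rec.canonical_smiles, config.seed, config.effective_threshold(),
            config.strict_donors, config.exclude_13, config.distance_on,
        )
        try:
            if key not in cache:
                cache[key] = featurize(rec.canonical_smiles, config)
            descs.append(cache[key])
        except Exception as exc:
            logger.warning("featurization failed for %s: %s", rec.canonical_smiles, exc)
            continue
        labels.append(1 if rec.label == "active" else 0)
        kept.append(rec)
    return descs, np.asarray(labels, dtype=int), kept


def rethreshold(desc: DescriptorSet, dthreshold: float) -> DescriptorSet:
    """Derive the descriptor set at a tighter H-bond threshold from an existing
    one (contacts are filtered; geometry is reused)."""
    triples = [t for t in desc.hbond_triples if t.distance <= dthreshold]
    return DescriptorSet(
        node_features=desc.node_features,
        adjacency=desc.adjacency,
        distance=desc.distance,
        hbond_bool=hbond_matrix(triples, desc.n_atoms),
        hbond_triples=triples,
        smiles=desc.smiles,
    )


# ---- training --------------------------------------------------------------


@dataclass
class TrainingLog:
    losses: list[float]
    model_config: ModelConfig
    featurizer_config: FeaturizerConfig


def train_model(
    descriptors: Sequence[DescriptorSet],
    labels: Sequence[int],
    model_config: ModelConfig,
    featurizer_config: Optional[FeaturizerConfig] = None,
    seed: int = 0,
) -> tuple[MathModel, TrainingLog]:
    """Train with Adam and mini-batch binary cross-entropy; deterministic per seed."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise SingleClassError("training set must contain both classes")
    cfg = dataclasses.replace(model_config, seed=seed)
    model = MathModel(cfg, featurizer_config=featurizer_config)
    opt = ad.Adam(model.params, lr=cfg.learning_rate, betas=cfg.betas)
    rng = np.random.default_rng(seed + 1)
    drop_rng = np.random.default_rng(seed + 2) if cfg.dropout > 0 else None
    losses = []
    idx = np.arange(len(descriptors))
    for _ in range(cfg.epochs):
        rng.shuffle(idx)
        epoch_loss = 0.0
        for start in range(0, len(idx), cfg.batch_size):
            batch = idx[start:start + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward_batch([descriptors[i] for i in batch], drop_rng)
            loss = ad.bce_with_logits(logits, labels[batch])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        losses.append(epoch_loss / len(idx))
    return model, TrainingLog(losses, cfg, model.featurizer_config)


@dataclass
class CVResult:
    folds: list[EvalReport]
    mean: dict[str, Optional[float]]
    best_fold_index: int  # highest F1

    @property
    def best_fold(self) -> EvalReport:
        return self.folds[self.best_fold_index]


def _mean_metrics(folds: Sequence[EvalReport]) -> dict[str, Optional[float]]:
    out: dict[str, Optional[float]] = {}
    for name in ("tpr", "fpr", "specificity", "precision", "recall", "f1", "roc_auc"):
        vals = [getattr(f, name) for f in folds if getattr(f, name) is not None]
        out[name] = float(np.mean(vals)) if vals else None
    return out


def cross_validate(
    records: Sequence[LabeledCompound],
    k: int = 5,
    featurizer_config: Optional[FeaturizerConfig] = None,
    model_config: Optional[ModelConfig] = None,
    seed: int = 0,
    cache: Optional[dict] = None,
    descriptors: Optional[Sequence[DescriptorSet]] = None,
    labels: Optional[np.ndarray] = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the classifier.

    Pre-featurized ``descriptors``/``labels`` may be passed to skip conformer
    generation (the sweep uses this).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    featurizer_config = featurizer_config or FeaturizerConfig()
    model_config = model_config or ModelConfig.scaled_down()
    if descriptors is None:
        descriptors, labels, _ = featurize_records(records, featurizer_config, cache)
    labels = np.asarray(labels, dtype=int)
    if min((labels == 1).sum(), (labels == 0).sum()) < k:
        raise ValueError("stratification impossible: fewer members of a class than folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        model, _ = train_model(
            [descriptors[i] for i in tr], labels[tr],
            model_config, featurizer_config, seed=seed + fold_i,
        )
        probs = model.predict_proba([descriptors[i] for i in te])
        folds.append(
            confusion_and_metrics(labels[te], probs, model_config.classification_threshold)
        )
    f1s = [f.f1 if f.f1 is not None else -1.0 for f in folds]
    return CVResult(folds=folds, mean=_mean_metrics(folds), best_fold_index=int(np.argmax(f1s)))


def run_sweep(
    records: Sequence[LabeledCompound],
    thresholds: Sequence[float] = SWEEP_GRID,
    include_boolean: bool = True,
    featurizer_config: Optional[FeaturizerConfig] = None,
    model_config: Optional[ModelConfig] = None,
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """Cross-validate at each H-bond distance threshold (plus the Boolean mode).

    Conformers are embedded once at the loosest threshold and contacts
    re-filtered per setting. Returns one row per setting with the mean CV
    metrics, the evaluated molecule count, and a flag on the argmax row per
    metric. A setting that fails entirely is reported with NaN metrics rather
    than aborting the sweep.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be positive and ascending")
    featurizer_config = featurizer_config or FeaturizerConfig()
    model_config = model_config or ModelConfig.scaled_down()
    base_cfg = dataclasses.replace(
        featurizer_config,
        dthreshold=max(thresholds + [featurizer_config.effective_threshold()]),
        mode="distance",
    )
    base_descs, labels, kept = featurize_records(records, base_cfg)

    settings: list[tuple[str, float]] = []
    if include_boolean:
        settings.append(("boolean", FeaturizerConfig(mode="boolean").effective_threshold()))
    settings.extend((f"dist<{t:g}", t) for t in thresholds)

    rows = []
    for name, thr in settings:
        descs = [rethreshold(d, thr) for d in base_descs]
        row: dict = {"setting": name, "dthreshold": thr, "n": len(descs)}
        try:
            cv = cross_validate(
                kept, k=k, featurizer_config=featurizer_config,
                model_config=model_config, seed=seed,
                descriptors=descs, labels=labels,
            )
            row.update({m: cv.mean[m] for m in ("roc_auc", "precision", "recall", "f1", "specificity")})
        except Exception as exc:
            logger.warning("sweep setting %s failed: %s", name, exc)
            row.update({m: np.nan for m in ("roc_auc", "precision", "recall", "f1", "specificity")})
        rows.append(row)
    table = pd.DataFrame(rows)
    for m in ("roc_auc", "precision", "recall", "f1", "specificity"):
        col = table[m].astype(float)
        table[f"best_{m}"] = col.eq(col.max()) & col.notna()
    return table
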