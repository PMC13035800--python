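"""Cross-validated training and evaluation of the seizure classifier.

Protocol: stratified k-fold cross-validation (default k=10); within each
training split a stratified validation subset (default 10%) drives early
stopping (Adam, lr 1e-3, batch 256 capped at the training-set size,
patience 10 epochs); minority-class oversampling is applied to the training
portion only, *after* splitting, so duplicated ictal windows can never leak
across the train/test boundary. Metrics per fold: accuracy, sensitivity
(seizure recall), specificity (non-seizure recall) from the confusion
counts, and AUC in its rank (Mann-Whitney) formulation — the probability
that a random ictal score exceeds a random interictal score, ties counted
one half. Reported values are arithmetic means over folds.

The module-level functions implement the protocol; :class:`SeizureDetector`
is the model-object front end: build it from labeled segments (plus their
connectivity stacks), call :meth:`~SeizureDetector.fit`, and read the
per-fold and averaged metrics off the returned :class:`CVResults`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold

from .autograd import cross_entropy_with_logits
from .model import ModelConfig, SeizureTransNet
from .nn import Adam

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts", "FoldResult", "EvalReport", "CVResults",
    "SeizureDetector", "kfold_split", "train_fold", "train_model",
    "compute_metrics", "auc_rank", "cross_validate",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; ictal is the positive class."""
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class FoldResult:
    confusion: ConfusionCounts
    acc: float
    sen: float | None
    spe: float | None
    auc: float | None


@dataclass
class EvalReport:
    """Per-fold confusion counts and metrics, plus their averages."""
    folds: list = field(default_factory=list)

    def _mean(self, attr):
        vals = [getattr(f, attr) for f in self.folds]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    @property
    def acc(self): return self._mean("acc")

    @property
    def sen(self): return self._mean("sen")

    @property
    def spe(self): return self._mean("spe")

    @property
    def auc(self): return self._mean("auc")

    def averages(self) -> dict:
        return {"Acc": self.acc, "Sen": self.sen, "Spe": self.spe, "AUC": self.auc}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_rank(scores, labels) -> float:
    """ROC area by the rank (Mann-Whitney U) formulation, ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one sample of each class")
    ranks = rankdata(scores)  # average ranks on ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(scores, labels, threshold: float = 0.5) -> FoldResult:
    """Confusion counts and Acc/Sen/Spe/AUC from ictal-probability scores.

    Acc = (TP+TN)/total, Sen = TP/(TP+FN), Spe = TN/(TN+FP). Metrics whose
    denominator class is absent are returned as None (undefined), not 0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    preds = (scores >= threshold).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    cm = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    acc = (tp + tn) / cm.total
    sen = tp / (tp + fn) if (tp + fn) > 0 else None
    spe = tn / (tn + fp) if (tn + fp) > 0 else None
    auc = auc_rank(scores, labels) if (labels == 1).any() and (labels == 0).any() else None
    return FoldResult(confusion=cm, acc=acc, sen=sen, spe=spe, auc=auc)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def kfold_split(labels, k: int = 10, seed: int = 0, groups=None) -> list:
    """Stratified k disjoint test folds (lists of indices).

    With ``groups`` (e.g. one id per seizure event or per recording), a
    stratified *group* k-fold keeps each group in a single fold — the
    conservative alternative to segment-level splitting, under which
    overlapping ictal windows of one event can span train and test.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present to stratify folds")
    short = classes[counts < k]
    if short.size:
        raise ValueError(
            f"class(es) {short.tolist()} have fewer than k={k} samples")
    if groups is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test.tolist() for _, test in splitter.split(np.zeros(len(labels)), labels)]
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test.tolist() for _, test in
            splitter.split(np.zeros(len(labels)), labels, groups=np.asarray(groups))]


def _stratified_holdout(y, frac: float, rng: np.random.Generator):
    """Indices (train, held-out) with the same class mix, >=1 per class held out."""
    y = np.asarray(y)
    hold = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_hold = max(1, int(round(frac * len(idx))))
        hold.extend(idx[:n_hold])
    hold = np.sort(np.array(hold))
    train = np.setdiff1d(np.arange(len(y)), hold)
    return train, hold


def _oversample_indices(y, rng: np.random.Generator) -> np.ndarray:
    """Index array duplicating the minority class to parity (originals kept)."""
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("oversampling needs both classes present")
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    extra = rng.choice(minority, size=len(majority) - len(minority), replace=True) \
        if len(majority) > len(minority) else np.array([], dtype=int)
    idx = np.concatenate([np.arange(len(y)), extra])
    return idx[rng.permutation(len(idx))]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(model: SeizureTransNet, X, y, A=None, Xval=None, yval=None, Aval=None,
                lr: float = 1e-3, batch_size: int = 256, max_epochs: int = 50,
                patience: int = 10, seed: int = 0,
                stop_train_acc: float | None = None) -> dict:
    """Train with Adam and early stopping on validation loss.

    Training stops once the validation loss has failed to improve for
    ``patience`` consecutive epochs; the best-validation-loss parameters are
    restored. Without a validation set the model trains for ``max_epochs``,
    or until the eval-mode training accuracy reaches ``stop_train_acc``
    when that is given (capacity / overfitting checks). Returns a history
    dict (per-epoch train/val losses, epochs run, best epoch).
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    model.dropout_rng = np.random.default_rng(seed + 1)
    opt = Adam(model.parameters(), lr=lr)
    bs = min(batch_size, len(X))
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y).astype(int)
    A = None if A is None else np.asarray(A, dtype=np.float32)

    def eval_loss(Xe, ye, Ae):
        total, n = 0.0, 0
        for i in range(0, len(Xe), bs):
            logits = model.forward(Xe[i:i + bs], None if Ae is None else Ae[i:i + bs],
                                   training=False)
            loss = cross_entropy_with_logits(logits, ye[i:i + bs])
            total += loss.item() * len(ye[i:i + bs])
            n += len(ye[i:i + bs])
        return total / n

    history = {"train_loss": [], "val_loss": [], "best_epoch": None, "epochs_run": 0}
    best_val = np.inf
    best_state = model.state_dict()
    bad_epochs = 0
    have_val = Xval is not None and len(Xval) > 0
    if have_val:
        Xval = np.asarray(Xval, dtype=np.float32)
        yval = np.asarray(yval).astype(int)
        Aval = None if Aval is None else np.asarray(Aval, dtype=np.float32)

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(X))
        epoch_loss, n_seen = 0.0, 0
        for i in range(0, len(order), bs):
            batch = order[i:i + bs]
            model.zero_grad()
            logits = model.forward(X[batch], None if A is None else A[batch],
                                   training=True)
            loss = cross_entropy_with_logits(logits, y[batch])
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
            n_seen += len(batch)
        history["train_loss"].append(epoch_loss / n_seen)
        history["epochs_run"] = epoch
        if stop_train_acc is not None:
            preds = model.predict_proba(X, A, batch_size=bs)[:, 1] >= 0.5
            if (preds.astype(int) == y).mean() >= stop_train_acc:
                break
        if have_val:
            vl = eval_loss(Xval, yval, Aval)
            history["val_loss"].append(vl)
            if vl < best_val - 1e-12:
                best_val = vl
                best_state = model.state_dict()
                history["best_epoch"] = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    logger.info("early stop at epoch %d (best epoch %d, val loss %.4f)",
                                epoch, history["best_epoch"], best_val)
                    break
    if have_val:
        model.load_state_dict(best_state)
    return history


def train_fold(X, y, A=None, model_config: ModelConfig | None = None,
               val_fraction: float = 0.1, lr: float = 1e-3, batch_size: int = 256,
               max_epochs: int = 50, patience: int = 10, seed: int = 0):
    """Train one fold: stratified validation split, oversampling of the
    *training portion only*, Adam with early stopping.

    Returns (model, history, audit) where audit records the oversampled
    index bookkeeping for leakage checks.
    """
    if model_config is None:
        raise ValueError("model_config is required")
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y).astype(int)
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    tr_idx, val_idx = _stratified_holdout(y, val_fraction, rng)
    over_idx = _oversample_indices(y[tr_idx], rng)
    final_idx = tr_idx[over_idx]
    model = SeizureTransNet(model_config)
    history = train_model(
        model, X[final_idx], y[final_idx],
        A=None if A is None else np.asarray(A, dtype=np.float32)[final_idx],
        Xval=X[val_idx], yval=y[val_idx],
        Aval=None if A is None else np.asarray(A, dtype=np.float32)[val_idx],
        lr=lr, batch_size=batch_size, max_epochs=max_epochs, patience=patience,
        seed=seed)
    audit = {"train_indices": final_idx.tolist(), "val_indices": val_idx.tolist()}
    return model, history, audit


def cross_validate(X, y, A=None, model_config: ModelConfig | None = None,
                   k: int = 10, seed: int = 0, groups=None, **train_kwargs):
    """Full stratified k-fold protocol. Returns (EvalReport, details).

    details carries per-fold histories, test indices, scores and the
    oversampling audit trail (all in global segment indices).
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y).astype(int)
    A = None if A is None else np.asarray(A, dtype=np.float32)
    folds = kfold_split(y, k=k, seed=seed, groups=groups)
    report = EvalReport()
    details = []
    for fold_no, test_idx in enumerate(folds):
        t0 = time.time()
        test_idx = np.asarray(test_idx)
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        cfg = model_config
        model, history, audit = train_fold(
            X[train_idx], y[train_idx],
            A=None if A is None else A[train_idx],
            model_config=cfg, seed=seed + 1000 * fold_no, **train_kwargs)
        scores = model.predict_proba(
            X[test_idx], None if A is None else A[test_idx])[:, 1]
        result = compute_metrics(scores, y[test_idx])
        report.folds.append(result)
        details.append({
            "fold": fold_no,
            "test_indices": test_idx.tolist(),
            # map local training/val indices back to global segment indices
            "train_indices": [int(train_idx[i]) for i in audit["train_indices"]],
            "val_indices": [int(train_idx[i]) for i in audit["val_indices"]],
            "scores": scores.tolist(),
            "history": history,
            "seconds": time.time() - t0,
        })
        logger.info("fold %d/%d: acc=%.3f auc=%s (%.1fs, %d epochs)",
                    fold_no + 1, k, result.acc,
                    "n/a" if result.auc is None else f"{result.auc:.3f}",
                    details[-1]["seconds"], history["epochs_run"])
    return report, details


# ---------------------------------------------------------------------------
# model-object front end
# ---------------------------------------------------------------------------

class SeizureDetector:
    """Seizure/background classifier built from labeled EEG segments.

    Parameters
    ----------
    segments : list of EEGSegment (each (C, T), labeled ictal/interictal).
    tfpp : optional list of TFPPTensor aligned with segments; required for
        the connectivity-augmented input modes.
    model_config : ModelConfig; defaults are derived from the data shapes
        when omitted.
    """

    def __init__(self, segments, tfpp=None, model_config: ModelConfig | None = None):
        if not segments:
            raise ValueError("no segments provided")
        self.X = np.stack([s.data for s in segments]).astype(np.float32)
        self.y = np.array([s.y for s in segments], dtype=int)
        self.segments = list(segments)
        if tfpp is not None:
            if len(tfpp) != len(segments):
                raise ValueError("tfpp list must align with segments")
            self.A = np.stack([t.values for t in tfpp]).astype(np.float32)
        else:
            self.A = None
        if model_config is None:
            n, c, t = self.X.shape
            model_config = ModelConfig(
                input_mode="eeg+tfpp" if self.A is not None else "eeg",
                n_channels=c, samples_per_segment=t,
                n_tfpp_slices=0 if self.A is None else self.A.shape[1])
        self.config = model_config
        if self.config.uses_connectivity and self.A is None:
            raise ValueError(
                f"input_mode {self.config.input_mode!r} needs connectivity tensors")

    def fit(self, k: int = 10, seed: int = 0, groups=None, **train_kwargs) -> "CVResults":
        """Run the cross-validated protocol; returns :class:`CVResults`."""
        A = self.A if self.config.uses_connectivity else None
        report, details = cross_validate(
            self.X, self.y, A=A, model_config=self.config, k=k, seed=seed,
            groups=groups, **train_kwargs)
        return CVResults(model=self, report=report, details=details, k=k, seed=seed)


class CVResults:
    """Cross-validation results: per-fold metrics, averages, diagnostics."""

    def __init__(self, model: SeizureDetector, report: EvalReport, details, k, seed):
        self.model = model
        self.report = report
        self.details = details
        self.k = k
        self.seed = seed

    # convenience accessors
    @property
    def acc(self): return self.report.acc

    @property
    def sen(self): return self.report.sen

    @property
    def spe(self): return self.report.spe

    @property
    def auc(self): return self.report.auc

    def frame(self) -> pd.DataFrame:
        """Per-fold metrics with an AVG row (percent units)."""
        rows = []
        for i, f in enumerate(self.report.folds):
            rows.append({"ID": f"fold{i}", "Acc": 100 * f.acc,
                         "Sen": None if f.sen is None else 100 * f.sen,
                         "Spe": None if f.spe is None else 100 * f.spe,
                         "AUC": None if f.auc is None else 100 * f.auc})
        avg = self.report.averages()
        rows.append({"ID": "AVG",
                     **{m: None if avg[m] is None else 100 * avg[m]
                        for m in ("Acc", "Sen", "Spe", "AUC")}})
        return pd.DataFrame(rows, columns=["ID", "Acc", "Sen", "Spe", "AUC"])

    def summary(self) -> str:
        """Human-readable report: protocol, per-fold table, mean +/- sd."""
        df = self.frame()
        fold_vals = {m: [getattr(f, m.lower()) for f in self.report.folds]
                     for m in ("Acc", "Sen", "Spe", "AUC")}
        lines = [
            "SeizureDetector cross-validation results",
            "=" * 44,
            f"input mode: {self.model.config.input_mode}   "
            f"segments: {len(self.model.y)} "
            f"(ictal {int(self.model.y.sum())} / interictal {int((1 - self.model.y).sum())})",
            f"folds: {self.k}   seed: {self.seed}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
            "",
        ]
        for m, vals in fold_vals.items():
            if any(v is None for v in vals):
                lines.append(f"{m}: undefined in at least one fold")
            else:
                lines.append(f"{m}: {100 * np.mean(vals):.2f} +/- {100 * np.std(vals):.2f} %")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False, float_format="%.2f")
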