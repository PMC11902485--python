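"""Training loop, best-model checkpointing and leave-one-out cross-validation.

Training follows the reference protocol: whole volumes are fed one at a
time (batch of one), the hybrid cross-entropy + Dice cost is minimized
with ADAM, and the model state with the lowest cost over the run is the
one kept.  Cross-validation is leave-one-out over the cohort: each record
serves as the test set exactly once while the rest train the model, and
the per-modality intensity standard scale is rebuilt from the training
records of each fold only, so no test information leaks into
preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError
from .metrics import (
    ConfusionMatrix,
    MetricsReport,
    SummaryTable,
    aggregate_reports,
    confusion_matrix,
    hybrid_loss,
    hybrid_loss_logit_grad,
    metrics_from_confusion,
)
from .net21d import ArchitectureConfig, SegModel, build_model, predict, softmax
from .standardize import (
    build_standard_scale,
    compute_landmarks,
    fill_missing,
    standardize_intensity,
)
from .volume_io import LabelVolume, MultiModalVolume, stack_modalities

logger = logging.getLogger("neoseg")


@dataclass
class TrainConfig:
    """Optimization settings; the defaults mirror the reference protocol
    (ADAM, 1000 epochs, lowest-training-cost checkpointing)."""

    epochs: int = 1000
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7
    seed: int = 0
    checkpoint_rule: str = "lowest_cost"
    deterministic_mode: bool = True
    w_ce: float = 0.5
    w_dice: float = 0.5
    holdout_fraction: float = 0.0   # off by default: cost is measured on the training data
    log_every: int = 0              # 0 = silent

    def __post_init__(self):
        if self.epochs < 1:
            raise UsageError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise UsageError("learning rate must be non-negative")
        if self.optimizer != "adam":
            raise UsageError("only the ADAM optimizer is supported")
        if self.checkpoint_rule != "lowest_cost":
            raise UsageError("only 'lowest_cost' checkpointing is supported")


class Adam:
    """Standard ADAM with bias correction, updating parameters in place."""

    def __init__(self, triples, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.triples = triples
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(lyr, p)) for lyr, p, _ in triples]
        self.v = [np.zeros_like(getattr(lyr, p)) for lyr, p, _ in triples]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for slot, (lyr, p, g) in enumerate(self.triples):
            grad = getattr(lyr, g).astype(self.m[slot].dtype, copy=False)
            m = self.m[slot]
            v = self.v[slot]
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            param = getattr(lyr, p)
            param -= (self.lr / c1) * m / (np.sqrt(v / c2) + self.eps)


def best_epoch(history) -> int:
    """1-based index of the lowest cost in a training history (first min)."""
    history = list(history)
    if not history:
        raise UsageError("empty history")
    return int(np.argmin(history)) + 1


def _record_arrays(record):
    x, y = record
    x = x.channels if isinstance(x, MultiModalVolume) else np.asarray(x)
    y = y.labels if isinstance(y, LabelVolume) else np.asarray(y)
    return x, y


def training_cost(model: SegModel, records, w_ce=0.5, w_dice=0.5) -> float:
    """Mean hybrid cost over records in deterministic evaluation mode
    (dropout off); this is the quantity the checkpoint rule minimizes."""
    costs = []
    for record in records:
        x, y = _record_arrays(record)
        probs = softmax(model.forward(x, training=False).astype(np.float64))
        costs.append(hybrid_loss(probs, y, w_ce=w_ce, w_dice=w_dice))
    return float(np.mean(costs))


def train(model: SegModel, records, cfg: TrainConfig):
    """Optimize the model on a list of (MultiModalVolume, LabelVolume) pairs.

    One volume per optimization step, records visited in the given fixed
    order.  After each epoch the mean evaluation-mode cost over the
    training records is appended to the history; the returned model carries
    the weights of the lowest-cost epoch.  With ``deterministic_mode`` the
    run is fully reproducible from ``cfg.seed``.
    """
    records = list(records)
    if not records:
        raise UsageError("no training records")
    first_x, _ = _record_arrays(records[0])
    if first_x.shape[3] != model.config.in_channels:
        raise UsageError(
            f"records carry {first_x.shape[3]} channels, model expects {model.config.in_channels}"
        )
    drop_rng = np.random.default_rng(cfg.seed if cfg.deterministic_mode else None)
    opt = Adam(model.trainables(), cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.adam_eps)
    history = []
    best_cost = np.inf
    best_weights = model.get_weights()
    for epoch in range(1, cfg.epochs + 1):
        for record in records:
            x, y = _record_arrays(record)
            logits = model.forward(x, training=True, rng=drop_rng)
            probs = softmax(logits.astype(np.float64))
            _, grad = hybrid_loss_logit_grad(probs, y, w_ce=cfg.w_ce, w_dice=cfg.w_dice)
            model.backward(grad.astype(logits.dtype))
            opt.step()
        cost = training_cost(model, records, cfg.w_ce, cfg.w_dice)
        history.append(cost)
        if cost < best_cost:
            best_cost = cost
            best_weights = model.get_weights()
        if cfg.log_every and epoch % cfg.log_every == 0:
            logger.info("epoch %d/%d cost %.6f (best %.6f)", epoch, cfg.epochs, cost, best_cost)
    model.set_weights(best_weights)
    return model, history


@dataclass
class FoldResult:
    """Outcome of one leave-one-out fold."""

    test_record_id: str
    report: MetricsReport
    confusion: ConfusionMatrix
    history: list = field(default_factory=list)
    best_epoch: int = 0

    def __post_init__(self):
        if self.history and self.best_epoch:
            if self.history[self.best_epoch - 1] != min(self.history):
                raise UsageError("best_epoch does not point at the minimal cost")


def prepare_fold(train_records, test_record, replication=1):
    """Void-fill and standardize one fold's records.

    Landmarks are computed per record; the reference scale per modality is
    the mean over the *training* records only.  Returns the stacked
    training inputs and the stacked test input.
    """
    filled = {}
    all_records = list(train_records) + [test_record]
    for rec in all_records:
        pair = {}
        for mod, vol in (("T1", rec.t1), ("T2", rec.t2)):
            if vol.validity_mask is not None and not vol.validity_mask.all():
                vol = fill_missing(vol)
            pair[mod] = vol
        filled[id(rec)] = pair
    landmarks = {
        id(rec): {mod: compute_landmarks(filled[id(rec)][mod], modality=mod) for mod in ("T1", "T2")}
        for rec in all_records
    }
    scales = {
        mod: build_standard_scale([landmarks[id(rec)][mod] for rec in train_records])
        for mod in ("T1", "T2")
    }
    def stack(rec):
        std = {
            mod: standardize_intensity(filled[id(rec)][mod], landmarks[id(rec)][mod], scales[mod])
            for mod in ("T1", "T2")
        }
        return stack_modalities(std["T1"], std["T2"], replication=replication)

    return [stack(r) for r in train_records], stack(test_record), scales


def run_loocv(records, arch: ArchitectureConfig, cfg: TrainConfig):
    """Leave-one-out cross-validation over a labeled cohort.

    ``records`` are objects with ``t1``/``t2`` intensity volumes, a
    ``labels`` volume and a ``record_id`` (the phantom module's records
    qualify).  The fold holding out record r trains a freshly initialized
    model on the remaining records and evaluates on r; its init seed is
    cfg.seed plus the record's stable index (position among sorted
    record ids), so per-record results do not depend on input order.
    Returns the per-fold results and the aggregated summary table.
    """
    records = list(records)
    if len(records) < 2:
        raise UsageError("leave-one-out needs at least 2 records")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise UsageError("record ids must be unique")
    if arch.in_channels % 2:
        raise UsageError("in_channels must be even (two modalities, equal replication)")
    replication = arch.in_channels // 2
    fold_index = {rid: i for i, rid in enumerate(sorted(ids))}
    fold_results = []
    for k, test_rec in enumerate(records):
        # canonical (id-sorted) training order: fold outcomes depend only on
        # which record is held out, not on the order records were passed in
        train_recs = sorted(
            (r for i, r in enumerate(records) if i != k), key=lambda r: r.record_id
        )
        train_x, test_x, _ = prepare_fold(train_recs, test_rec, replication)
        train_pairs = [(x, r.labels) for x, r in zip(train_x, train_recs)]
        model = build_model(arch, seed=cfg.seed + fold_index[test_rec.record_id])
        model, history = train(model, train_pairs, cfg)
        _, pred_labels = predict(model, test_x)
        cm = confusion_matrix(pred_labels, test_rec.labels,
                              n_classes=arch.n_classes, record_id=test_rec.record_id)
        report = metrics_from_confusion(cm)
        fold_results.append(
            FoldResult(
                test_record_id=test_rec.record_id,
                report=report,
                confusion=cm,
                history=history,
                best_epoch=best_epoch(history),
            )
        )
        logger.info("fold %d/%d: test %s ACC %.4f", k + 1, len(records),
                    test_rec.record_id, report.acc)
    summary = aggregate_reports([fr.report for fr in fold_results])
    return fold_results, summary
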