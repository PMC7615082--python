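"""Optimization schedule, metrics, and the evaluation protocols.

Supervised training uses Adam under a three-stage learning-rate schedule
(linear warm-up for the first 10% of steps, constant peak for the next 40%,
cosine decay to zero over the last 50%) with early stopping once the
running-minimum validation loss is more than `patience` epochs old.

Evaluation protocols:

* length-subgroup analysis — metrics for short (EHR length <= threshold)
  and long (> threshold) patients, plus a positive-rate-matched version of
  the long subgroup in which all negatives are kept and positives are
  subsampled (without replacement, averaged over bootstrap draws) until the
  prevalence matches the short subgroup;
* training-fraction curves — repeat training on subsamples of the training
  set (optionally warm-started from a pre-trained encoder) and evaluate on
  the fixed validation set, averaged over seeds;
* modality ablation — re-encode the cohort keeping diagnosis + medication
  plus one additional modality at a time.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import nn
from .model import batch_arrays
from .records import CohortExample, PatientHistory, Vocabulary, encode_history

__all__ = [
    "ScheduleConfig", "EvalReport", "lr_at", "early_stop",
    "auroc", "auprc", "evaluate", "train_supervised",
    "subgroup_eval", "fraction_curve", "filter_modalities",
    "modality_ablation",
]


@dataclasses.dataclass
class ScheduleConfig:
    total_epochs: int = 100
    warmup_frac: float = 0.10
    hold_frac: float = 0.40
    decay_frac: float = 0.50
    peak_lr: float = 1e-4     # swept over {5e-5, 1e-4, 5e-4} at full scale
    batch_size: int = 128
    patience: int = 6

    def __post_init__(self) -> None:
        if abs(self.warmup_frac + self.hold_frac + self.decay_frac - 1.0) > 1e-9:
            raise ValueError("stage fractions must sum to 1")
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")


def lr_at(step: int, total_steps: int, cfg: ScheduleConfig) -> float:
    """Three-stage learning rate: warm-up, hold, cosine decay to zero."""
    if not 0 <= step <= total_steps:
        raise ValueError("step outside [0, total_steps]")
    t = step / total_steps
    if t <= cfg.warmup_frac:
        return cfg.peak_lr * (t / cfg.warmup_frac)
    hold_end = cfg.warmup_frac + cfg.hold_frac
    if t <= hold_end:
        return cfg.peak_lr
    frac = (t - hold_end) / cfg.decay_frac
    return cfg.peak_lr * 0.5 * (1.0 + math.cos(math.pi * frac))


def early_stop(val_losses: Sequence[float], patience: int = 6) -> bool:
    """True iff the running-minimum loss is more than `patience` epochs old.

    "Improvement" is a strict decrease of the running minimum.
    """
    if not val_losses:
        return False
    best = int(np.argmin(val_losses))  # first index attaining the minimum
    return (len(val_losses) - 1 - best) > patience


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    return float(average_precision_score(np.asarray(labels),
                                         np.asarray(scores)))


@dataclasses.dataclass
class EvalReport:
    auroc: float
    auprc: float
    n: int
    n_pos: int
    subgroup: str = "all"

    def __post_init__(self) -> None:
        if self.n_pos > self.n:
            raise ValueError("n_pos cannot exceed n")


def _report(labels: np.ndarray, scores: np.ndarray, subgroup: str) -> EvalReport:
    return EvalReport(auroc=auroc(labels, scores), auprc=auprc(labels, scores),
                      n=len(labels), n_pos=int(labels.sum()), subgroup=subgroup)


def evaluate(model, examples: Sequence[CohortExample],
             subgroup: str = "all", batch_size: int = 64) -> EvalReport:
    scores = model.predict_proba(examples, batch_size=batch_size)
    labels = np.array([ex.label for ex in examples])
    return _report(labels, scores, subgroup)


# ---------------------------------------------------------------------------
# supervised training
# ---------------------------------------------------------------------------


def _val_loss(model, examples: Sequence[CohortExample], batch_size: int) -> float:
    model.eval()
    total, count = 0.0, 0
    with nn.no_grad():
        for i in range(0, len(examples), batch_size):
            batch = batch_arrays(examples[i:i + batch_size])
            logits = model.forward(batch)
            loss = nn.bce_with_logits(logits, batch["labels"])
            total += float(loss.data) * len(batch["labels"])
            count += len(batch["labels"])
    model.train()
    return total / max(count, 1)


def train_supervised(model, train_examples: Sequence[CohortExample],
                     val_examples: Sequence[CohortExample],
                     schedule: ScheduleConfig, seed: int = 0,
                     restore_best: bool = True,
                     betas: tuple[float, float] = (0.9, 0.999),
                     ) -> pd.DataFrame:
    """Adam + three-stage schedule + early stopping; returns epoch log."""
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=schedule.peak_lr, betas=betas)
    n = len(train_examples)
    bs = min(schedule.batch_size, n)
    steps_per_epoch = max(1, n // bs)
    total_steps = schedule.total_epochs * steps_per_epoch
    order = np.arange(n)
    history: list[dict] = []
    val_losses: list[float] = []
    best_state, best_loss = None, float("inf")
    step = 0
    for epoch in range(schedule.total_epochs):
        rng.shuffle(order)
        epoch_loss, nb = 0.0, 0
        for i in range(steps_per_epoch):
            idx = order[i * bs:(i + 1) * bs]
            batch = batch_arrays([train_examples[j] for j in idx])
            opt.lr = lr_at(step, total_steps, schedule)
            logits = model.forward(batch)
            loss = nn.bce_with_logits(logits, batch["labels"])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            nb += 1
            step += 1
        vl = _val_loss(model, val_examples, bs) if len(val_examples) else math.nan
        val_losses.append(vl)
        history.append({"epoch": epoch, "train_loss": epoch_loss / max(nb, 1),
                        "val_loss": vl, "lr": opt.lr})
        if not math.isnan(vl) and vl < best_loss:
            best_loss = vl
            if restore_best:
                best_state = model.state_dict()
        if len(val_examples) and early_stop(val_losses, schedule.patience):
            break
    if restore_best and best_state is not None:
        model.load_state_dict(best_state)
    return pd.DataFrame(history)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def subgroup_eval(examples: Sequence[CohortExample], model,
                  threshold: int = 256, n_boot: int = 5,
                  rng: np.random.Generator | None = None,
                  ) -> dict[str, EvalReport | None]:
    """Length-subgroup analysis with a positive-rate-matched long subgroup."""
    rng = rng or np.random.default_rng(0)
    scores = model.predict_proba(examples)
    labels = np.array([ex.label for ex in examples])
    lengths = np.array([ex.ehr_length for ex in examples])
    short = lengths <= threshold
    long_ = ~short
    if not short.any() or not long_.any():
        raise ValueError("both subgroups must be non-empty")
    reports: dict[str, EvalReport | None] = {
        "short": _report(labels[short], scores[short], f"len<={threshold}"),
        "long": _report(labels[long_], scores[long_], f"len>{threshold}"),
    }
    rate_short = labels[short].mean()
    long_pos = np.where(long_ & (labels == 1))[0]
    long_neg = np.where(long_ & (labels == 0))[0]
    n_pos_target = int(round(rate_short * len(long_neg) / (1.0 - rate_short)))
    if n_pos_target > len(long_pos) or n_pos_target < 1:
        reports["long_matched"] = None  # long prevalence below short's
        return reports
    aurocs, auprcs = [], []
    for _ in range(n_boot):
        take = rng.choice(long_pos, size=n_pos_target, replace=False)
        idx = np.concatenate([long_neg, take])
        aurocs.append(auroc(labels[idx], scores[idx]))
        auprcs.append(auprc(labels[idx], scores[idx]))
    reports["long_matched"] = EvalReport(
        auroc=float(np.mean(aurocs)), auprc=float(np.mean(auprcs)),
        n=len(long_neg) + n_pos_target, n_pos=n_pos_target,
        subgroup=f"len>{threshold} rate-matched x{n_boot}")
    return reports


def _subsample(examples: Sequence[CohortExample], fraction: float,
               rng: np.random.Generator) -> list[CohortExample]:
    if fraction >= 1.0:
        return list(examples)
    n = max(1, int(round(fraction * len(examples))))
    idx = rng.choice(len(examples), size=n, replace=False)
    return [examples[i] for i in idx]


def fraction_curve(train_set: Sequence[CohortExample],
                   val_set: Sequence[CohortExample],
                   model_factory: Callable[[int], object],
                   schedule: ScheduleConfig,
                   fractions: Sequence[float] = (0.01, 0.05, 0.1, 0.2, 0.5, 1.0),
                   n_seeds: int = 3,
                   pretrained_state: Mapping[str, np.ndarray] | None = None,
                   base_seed: int = 0) -> pd.DataFrame:
    """AUROC/AUPRC versus training-set fraction, averaged over seeds.

    Subsampling is without replacement (prevalence-preserving in
    expectation); with `pretrained_state`, a second arm warm-starts the
    encoder from those weights before fine-tuning.
    """
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rows = []
    modes = [("scratch", None)]
    if pretrained_state is not None:
        modes.append(("pretrained", pretrained_state))
    for frac in fractions:
        for mode, init in modes:
            aurocs, auprcs, ns = [], [], []
            for s in range(n_seeds):
                rng = np.random.default_rng(base_seed + 1000 * s + 1)
                subset = _subsample(train_set, frac, rng)
                n_pos = sum(ex.label for ex in subset)
                if n_pos < 1 or n_pos == len(subset):
                    warnings.warn(
                        f"fraction {frac} seed {s}: degenerate subset skipped")
                    continue
                model = model_factory(base_seed + 1000 * s)
                if init is not None:
                    _warm_start(model, init)
                train_supervised(model, subset, val_set, schedule,
                                 seed=base_seed + 1000 * s)
                rep = evaluate(model, val_set)
                aurocs.append(rep.auroc)
                auprcs.append(rep.auprc)
                ns.append(len(subset))
            if aurocs:
                rows.append({"fraction": frac, "mode": mode,
                             "auroc": float(np.mean(aurocs)),
                             "auprc": float(np.mean(auprcs)),
                             "n_train": int(np.mean(ns)),
                             "n_runs": len(aurocs)})
    return pd.DataFrame(rows)


def _warm_start(model, state: Mapping[str, np.ndarray]) -> None:
    """Load every pre-trained weight whose name/shape matches the model."""
    own = dict(model.named_parameters())
    for name, value in state.items():
        if name in own and own[name].data.shape == value.shape:
            own[name].data = value.astype(np.float32).copy()


def filter_modalities(histories: Sequence[PatientHistory],
                      keep: frozenset[str] | set[str],
                      ) -> list[PatientHistory]:
    out = []
    for h in histories:
        events = [ev for ev in h.events if ev.modality in keep]
        out.append(dataclasses.replace(h, events=events))
    return out


def modality_ablation(histories: Sequence[PatientHistory],
                      baselines: Mapping[str, tuple[dt.date, int]],
                      vocab: Vocabulary, max_len: int,
                      trainer: Callable[[Sequence[CohortExample]], object] | None = None,
                      model=None,
                      base: frozenset[str] = frozenset({"diagnosis", "medication"}),
                      add_one_of: Sequence[str] | None = None,
                      eval_ids: set[str] | None = None) -> pd.DataFrame:
    """Metrics with diagnosis+medication plus one extra modality at a time.

    `baselines` maps patient id -> (baseline date, label). Either a fitted
    `model` (evaluation-only mode) or a `trainer` callable building a model
    from the re-encoded training examples must be given. `eval_ids`
    restricts evaluation to a held-out subset (defaults to everyone).
    """
    if (trainer is None) == (model is None):
        raise ValueError("provide exactly one of trainer / model")
    from .records import MODALITIES
    add_one_of = list(add_one_of if add_one_of is not None
                      else sorted(MODALITIES - base))
    configs = [("base", frozenset(base))]
    configs += [(f"base+{m}", frozenset(base) | {m}) for m in add_one_of]
    rows = []
    for name, keep in configs:
        filtered = filter_modalities(histories, keep)
        examples = []
        for h in filtered:
            if h.patient_id not in baselines:
                continue
            baseline, label = baselines[h.patient_id]
            try:
                examples.append(encode_history(h, baseline, vocab, max_len,
                                               label=label))
            except ValueError:
                continue  # learning period empty under this modality set
        eval_ex = [ex for ex in examples
                   if eval_ids is None or ex.patient_id in eval_ids]
        fitted = model if model is not None else trainer(
            [ex for ex in examples if eval_ids is None
             or ex.patient_id not in eval_ids])
        rep = evaluate(fitted, eval_ex, subgroup=name)
        rows.append({"config": name, "modalities": "+".join(sorted(keep)),
                     "auroc": rep.auroc, "auprc": rep.auprc,
                     "n": rep.n, "n_pos": rep.n_pos})
    return pd.DataFrame(rows)
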