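"""Self-supervised pre-training of the hierarchical encoder (BYOL-style).

Two networks are trained against each other without negative pairs: an
*online* network (encoder, projector, predictor) updated by gradient
descent, and a *target* network (encoder, projector) whose weights are an
exponential moving average of the online weights. Augmentation is
single-sided and two-level:

* EHR augmentation, before windowing — a random crop of a contiguous visit
  sub-period (applied to both paths so the per-window loss stays
  positionally aligned) followed by random token masking (online only);
* segment augmentation, in latent space — a proportion of window
  representations in the online path are zeroed or perturbed with standard
  Gaussian noise before aggregation.

The loss is the squared distance between L2-normalized online predictions
and target projections, summed over augmented window timesteps and averaged
over the examples that have at least one augmented timestep. The target
side never receives gradients.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .model import HiModelConfig, HierarchicalRiskModel
from .records import CohortExample, EncodedSequence, Vocabulary

__all__ = [
    "AugmentationConfig", "HeadConfig", "BYOLState",
    "crop_visits", "mask_tokens", "augment_ehr", "augment_segments",
    "byol_loss", "ema_update", "build_byol", "pretrain_step", "pretrain",
]


@dataclasses.dataclass
class AugmentationConfig:
    crop_prob: float = 0.5          # P_c: probability of the random crop
    token_mask_prob: float = 0.2    # P_m: per-token MASK probability
    segment_aug_prob: float = 0.5   # per-window augmentation probability
    zero_prob: float = 0.85         # P(zero | augmented)
    noise_prob: float = 0.15        # P(Gaussian noise | augmented)
    per_timestep: bool = True       # False: 50% applies per sequence instead

    def __post_init__(self) -> None:
        for name in ("crop_prob", "token_mask_prob", "segment_aug_prob",
                     "zero_prob", "noise_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.zero_prob + self.noise_prob - 1.0) > 1e-9:
            raise ValueError("zero_prob + noise_prob must equal 1")


@dataclasses.dataclass
class HeadConfig:
    hidden: int = 150
    out_dim: int = 150


@dataclasses.dataclass
class BYOLState:
    """Online (encoder+projector+predictor) and EMA target (encoder+projector)."""

    online_encoder: HierarchicalRiskModel
    online_projector: nn.MLP
    online_predictor: nn.MLP
    target_encoder: HierarchicalRiskModel
    target_projector: nn.MLP
    tau: float = 0.996

    def online_parameters(self) -> list[Tensor]:
        return (self.online_encoder.parameters()
                + self.online_projector.parameters()
                + self.online_predictor.parameters())


# ---------------------------------------------------------------------------
# EHR-level augmentation
# ---------------------------------------------------------------------------


def crop_visits(encoded: EncodedSequence,
                rng: np.random.Generator) -> EncodedSequence:
    """Keep a uniformly chosen contiguous sub-interval of visits (>= 1)."""
    n = encoded.true_length
    pos = encoded.position_ids[:n]
    n_visits = int(pos[-1]) + 1
    a, b = sorted(int(v) for v in rng.integers(0, n_visits, size=2))
    keep = (pos >= a) & (pos <= b)
    idx = np.nonzero(keep)[0]
    m = len(idx)
    L = len(encoded.token_ids)

    def take(arr):
        out = np.zeros(L, dtype=arr.dtype)
        out[:m] = arr[:n][idx]
        return out

    new_pos = np.zeros(L, dtype=encoded.position_ids.dtype)
    rel = pos[idx] - a
    new_pos[:m] = rel
    new_seg = np.zeros(L, dtype=encoded.segment_ids.dtype)
    new_seg[:m] = rel % 2
    mask = np.zeros(L, dtype=encoded.attention_mask.dtype)
    mask[:m] = 1
    return EncodedSequence(token_ids=take(encoded.token_ids),
                           age_ids=take(encoded.age_ids),
                           segment_ids=new_seg, position_ids=new_pos,
                           attention_mask=mask, true_length=m)


def mask_tokens(encoded: EncodedSequence, p: float,
                rng: np.random.Generator) -> EncodedSequence:
    """Independently replace each real token id by MASK with probability p."""
    n = encoded.true_length
    toks = encoded.token_ids.copy()
    hit = rng.random(n) < p
    toks[:n][hit] = Vocabulary.MASK
    return dataclasses.replace(encoded, token_ids=toks)


def augment_ehr(encoded: EncodedSequence, cfg: AugmentationConfig,
                rng: np.random.Generator) -> EncodedSequence:
    """Random crop (with probability crop_prob) then random token masking."""
    if encoded.true_length < 1:
        raise ValueError("cannot augment an empty sequence")
    out = encoded
    if cfg.crop_prob > 0 and rng.random() < cfg.crop_prob:
        out = crop_visits(out, rng)
    if cfg.token_mask_prob > 0:
        out = mask_tokens(out, cfg.token_mask_prob, rng)
    return out


# ---------------------------------------------------------------------------
# segment-level augmentation
# ---------------------------------------------------------------------------


def augment_segments(seg_reps: Tensor, seg_mask: np.ndarray,
                     cfg: AugmentationConfig, rng: np.random.Generator,
                     ) -> tuple[Tensor, np.ndarray]:
    """Zero or noise a random subset of real window representations.

    Returns the augmented representations and the boolean augmented-index
    mask A with shape [B, n_seg]; padding windows are never augmented.
    """
    B, S, d = seg_reps.shape
    real = seg_mask.astype(bool)
    if cfg.per_timestep:
        aug = (rng.random((B, S)) < cfg.segment_aug_prob) & real
    else:
        seq_on = rng.random(B) < cfg.segment_aug_prob
        aug = real & seq_on[:, None]
    zero_branch = rng.random((B, S)) < cfg.zero_prob
    keep = np.ones((B, S, 1), dtype=np.float32)
    keep[aug & zero_branch] = 0.0
    noise = np.zeros((B, S, d), dtype=np.float32)
    noisy = aug & ~zero_branch
    if noisy.any():
        noise[noisy] = rng.standard_normal((int(noisy.sum()), d)).astype(np.float32)
    return seg_reps * keep + noise, aug


# ---------------------------------------------------------------------------
# loss and EMA
# ---------------------------------------------------------------------------


def _l2_normalize(x: Tensor) -> Tensor:
    sq = (x * x).sum(axis=-1, keepdims=True)
    if np.any(sq.data <= 0):
        raise ValueError("zero-norm vector cannot be normalized")
    return x / (sq ** 0.5)


def byol_loss(online_preds: Tensor, target_projs: np.ndarray,
              aug_mask: np.ndarray) -> Tensor:
    """Sum over augmented timesteps of 2 - 2*cos(pred, proj), per example;
    mean over examples that have at least one augmented timestep."""
    tp = np.asarray(target_projs, dtype=np.float32)
    norms = np.linalg.norm(tp, axis=-1, keepdims=True)
    if np.any(norms[aug_mask.astype(bool)] <= 0):
        raise ValueError("zero-norm target projection")
    tp_n = tp / np.maximum(norms, 1e-30)
    on_n = _l2_normalize(online_preds)
    diff = on_n - tp_n
    per_t = (diff * diff).sum(axis=-1)                  # [B, S]
    w = aug_mask.astype(np.float32)
    per_example = (per_t * w).sum(axis=-1)              # [B]
    contributing = w.sum(axis=-1) > 0
    n = int(contributing.sum())
    if n == 0:
        return Tensor(0.0)
    sel = np.where(contributing, 1.0, 0.0).astype(np.float32)
    return (per_example * sel).sum() * np.float32(1.0 / n)


def ema_update(state: BYOLState) -> None:
    """tau * target + (1 - tau) * online, elementwise, in place."""
    tau = np.float32(state.tau)
    pairs = [(state.target_encoder, state.online_encoder),
             (state.target_projector, state.online_projector)]
    for target, online in pairs:
        t_params = dict(target.named_parameters())
        o_params = dict(online.named_parameters())
        if set(t_params) != set(o_params):
            raise ValueError("target/online parameter sets do not match")
        for name, tp in t_params.items():
            op = o_params[name]
            if tp.data.shape != op.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            tp.data = tau * tp.data + (np.float32(1.0) - tau) * op.data


def build_byol(cfg: HiModelConfig, head: HeadConfig | None = None,
               tau: float = 0.996, seed: int = 0) -> BYOLState:
    """Construct online and target networks; target starts as an online copy."""
    head = head or HeadConfig(hidden=cfg.hidden, out_dim=cfg.hidden)
    rng = np.random.default_rng(seed + 1)
    online_enc = HierarchicalRiskModel(cfg, seed=seed)
    online_proj = nn.MLP(cfg.hidden, head.hidden, head.out_dim, rng)
    online_pred = nn.MLP(head.out_dim, head.hidden, head.out_dim, rng)
    target_enc = HierarchicalRiskModel(cfg, seed=seed)
    target_enc.load_state_dict(online_enc.state_dict())
    target_proj = nn.MLP(cfg.hidden, head.hidden, head.out_dim, rng)
    target_proj.load_state_dict(online_proj.state_dict())
    return BYOLState(online_enc, online_proj, online_pred,
                     target_enc, target_proj, tau=tau)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _batch_from_sequences(seqs: list[EncodedSequence]) -> dict[str, np.ndarray]:
    n = max(s.true_length for s in seqs)
    n = max(n, 1)
    stack = lambda attr: np.stack([getattr(s, attr)[:n] for s in seqs])
    return {"token_ids": stack("token_ids"), "age_ids": stack("age_ids"),
            "segment_ids": stack("segment_ids"),
            "position_ids": stack("position_ids"),
            "attention_mask": stack("attention_mask")}


def pretrain_step(examples: Sequence[CohortExample], state: BYOLState,
                  cfg: AugmentationConfig, optimizer,
                  rng: np.random.Generator) -> dict[str, float]:
    """One BYOL step on a batch; returns loss and cosine-alignment stats."""
    cropped = []
    for ex in examples:
        enc = ex.encoded
        if cfg.crop_prob > 0 and rng.random() < cfg.crop_prob:
            enc = crop_visits(enc, rng)
        cropped.append(enc)
    online_in = [mask_tokens(e, cfg.token_mask_prob, rng) if
                 cfg.token_mask_prob > 0 else e for e in cropped]

    online_batch = _batch_from_sequences(online_in)
    target_batch = _batch_from_sequences(cropped)

    # online path
    seg_reps, seg_mask = state.online_encoder.extract_segments(online_batch)
    seg_reps_aug, aug_mask = augment_segments(seg_reps, seg_mask, cfg, rng)
    _, seg_states = state.online_encoder.aggregate(seg_reps_aug, seg_mask)
    preds = state.online_predictor(state.online_projector(seg_states))

    # target path: unaugmented input, no gradients
    with nn.no_grad():
        t_reps, t_mask = state.target_encoder.extract_segments(target_batch)
        _, t_states = state.target_encoder.aggregate(t_reps, t_mask)
        t_projs = state.target_projector(t_states).data

    loss = byol_loss(preds, t_projs, aug_mask)
    stats = {"loss": float(loss.data),
             "n_augmented": float(aug_mask.sum()),
             "mean_cosine": _mean_cosine(preds.data, t_projs, aug_mask)}
    if loss.requires_grad:
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    ema_update(state)
    return stats


def _mean_cosine(preds: np.ndarray, projs: np.ndarray,
                 aug_mask: np.ndarray) -> float:
    m = aug_mask.astype(bool)
    if not m.any():
        return float("nan")
    a = preds[m]
    b = projs[m]
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    cos = (a * b).sum(-1) / np.maximum(na * nb, 1e-12)
    return float(cos.mean())


def pretrain(examples: Sequence[CohortExample], state: BYOLState,
             cfg: AugmentationConfig, steps: int, batch_size: int,
             lr: float, seed: int, warmup_frac: float = 0.1,
             predictor_lr_scale: float = 10.0,
             weight_decay: float = 1e-4) -> list[dict[str, float]]:
    """SGD-with-momentum BYOL pre-training with warmup + cosine decay.

    The predictor trains `predictor_lr_scale` times faster than the rest:
    keeping the predictor near-optimal (together with a little weight
    decay) is what stops the one-sided objective from collapsing to a
    constant representation.
    """
    rng = np.random.default_rng(seed)
    enc_proj = (state.online_encoder.parameters()
                + state.online_projector.parameters())
    pred = state.online_predictor.parameters()
    opt = nn.SGD(enc_proj + pred, lr=lr, momentum=0.9,
                 weight_decay=weight_decay,
                 lr_scales=[1.0] * len(enc_proj)
                 + [predictor_lr_scale] * len(pred))
    log: list[dict[str, float]] = []
    order = np.arange(len(examples))
    pos = len(order)
    warmup = max(1, int(warmup_frac * steps))
    for step in range(steps):
        if pos + batch_size > len(order):
            rng.shuffle(order)
            pos = 0
        batch = [examples[i] for i in order[pos:pos + batch_size]]
        pos += batch_size
        if step < warmup:
            opt.lr = lr * (step + 1) / warmup
        else:
            frac = (step - warmup) / max(1, steps - warmup)
            opt.lr = lr * 0.5 * (1.0 + np.cos(np.pi * frac))
        stats = pretrain_step(batch, state, cfg, opt, rng)
        stats["step"] = step
        stats["lr"] = float(opt.lr)
        log.append(stats)
    return log
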