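"""Hierarchical and flat Transformer risk models for encoded EHR sequences.

The hierarchical model widens the receptive field far beyond a vanilla
Transformer: the encoded sequence is cut into overlapping fixed-width
windows by a sliding window (full coverage guaranteed), a shared-weight
*local feature extractor* Transformer encodes each window independently and
is pooled to one vector per window, and a *feature aggregator* Transformer
with a learned CLS vector summarizes the window representations for the
risk head. Attention cost is quadratic only in the window size and in the
number of windows, never in the full sequence length.

The flat baseline is a BERT-style encoder restricted to the most recent
`max_len` records (the oldest records are invisible to it), pooled at the
first (CLS) position.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .records import CohortExample, Vocabulary

__all__ = [
    "HiModelConfig", "FlatModelConfig", "SegmentBatch",
    "segment_windows", "attention_footprint",
    "HierarchicalRiskModel", "FlatRiskModel",
    "small_hier_config", "small_flat_config",
    "batch_arrays", "save_checkpoint", "load_checkpoint",
]

MAX_AGE = 110


@dataclasses.dataclass
class HiModelConfig:
    """Hierarchical model hyperparameters (defaults: the published setting)."""

    vocab_size: int
    hidden: int = 150
    heads: int = 6
    intermediate: int = 108
    extractor_layers: int = 4
    aggregator_layers: int = 4
    window: int = 50
    stride: int = 30
    max_len: int = 1220
    dropout: float = 0.2
    attn_dropout: float = 0.3
    seg_pooling: str = "first"   # "first" | "mean"

    def __post_init__(self) -> None:
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")
        if not (0 < self.stride <= self.window <= self.max_len):
            raise ValueError("require 0 < stride <= window <= max_len")
        if self.seg_pooling not in ("first", "mean"):
            raise ValueError("seg_pooling must be 'first' or 'mean'")


@dataclasses.dataclass
class FlatModelConfig:
    """Flat (truncating) baseline hyperparameters."""

    vocab_size: int
    hidden: int = 150
    heads: int = 6
    intermediate: int = 108
    layers: int = 8
    max_len: int = 256
    dropout: float = 0.2
    attn_dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")


def small_hier_config(vocab_size: int, **overrides) -> HiModelConfig:
    """Single-CPU test profile: same architecture, desk-scale capacity."""
    # 440 = window + 13 * stride: the sliding grid tiles the padded length
    # exactly, so extra padding only ever adds masked-out windows
    kw = dict(hidden=32, heads=2, intermediate=64, extractor_layers=1,
              aggregator_layers=1, window=50, stride=30, max_len=440,
              dropout=0.0, attn_dropout=0.0, seg_pooling="mean")
    kw.update(overrides)
    return HiModelConfig(vocab_size=vocab_size, **kw)


def small_flat_config(vocab_size: int, **overrides) -> FlatModelConfig:
    kw = dict(hidden=32, heads=2, intermediate=64, layers=2, max_len=256,
              dropout=0.0, attn_dropout=0.0)
    kw.update(overrides)
    return FlatModelConfig(vocab_size=vocab_size, **kw)


# ---------------------------------------------------------------------------
# sliding-window segmentation
# ---------------------------------------------------------------------------


def segment_windows(n: int, window: int, stride: int) -> list[tuple[int, int]]:
    """Window (start, end) pairs covering positions 0..n-1.

    Starts advance by `stride`; if the final stride-aligned window stops
    short of `n`, one extra window anchored at `n - window` is appended so
    the newest records are never dropped. Sequences shorter than `window`
    yield a single right-padded window.
    """
    if n < 1:
        raise ValueError("need at least one position")
    if n <= window:
        return [(0, window)]
    count = (n - window) // stride + 1
    wins = [(i * stride, i * stride + window) for i in range(count)]
    if wins[-1][1] < n:
        wins.append((n - window, n))
    return wins


@dataclasses.dataclass
class SegmentBatch:
    """Windowed views of a batch: [B, n_seg, W] arrays plus masks."""

    windows: list[tuple[int, int]]
    token_ids: np.ndarray
    age_ids: np.ndarray
    segment_ids: np.ndarray
    position_ids: np.ndarray
    window_mask: np.ndarray    # [B, n_seg, W] 1 = real token
    segment_mask: np.ndarray   # [B, n_seg]    1 = window has >=1 real token


def batch_arrays(examples: Sequence[CohortExample],
                 trim: bool = False) -> dict[str, np.ndarray]:
    """Stack encoded sequences; `trim` drops the shared padding tail.

    Trimming is off by default so the sliding-window grid depends only on
    the configured maximum length, never on batch composition.
    """
    toks = np.stack([ex.encoded.token_ids for ex in examples])
    ages = np.stack([ex.encoded.age_ids for ex in examples])
    segs = np.stack([ex.encoded.segment_ids for ex in examples])
    poss = np.stack([ex.encoded.position_ids for ex in examples])
    mask = np.stack([ex.encoded.attention_mask for ex in examples])
    if trim:
        n = max(int(ex.encoded.true_length) for ex in examples)
        toks, ages, segs, poss, mask = (a[:, :n] for a in
                                        (toks, ages, segs, poss, mask))
    labels = np.array([-1 if ex.label is None else ex.label
                       for ex in examples], dtype=np.float32)
    return {"token_ids": toks, "age_ids": ages, "segment_ids": segs,
            "position_ids": poss, "attention_mask": mask, "labels": labels}


def make_segment_batch(batch: dict[str, np.ndarray], window: int,
                       stride: int) -> SegmentBatch:
    n = batch["token_ids"].shape[1]
    wins = segment_windows(n, window, stride)
    idx = np.zeros((len(wins), window), dtype=np.int64)
    valid = np.zeros((len(wins), window), dtype=np.int64)
    for s, (a, b) in enumerate(wins):
        width = min(b, n) - a
        idx[s, :width] = np.arange(a, a + width)
        valid[s, :width] = 1
    gather = lambda arr: arr[:, idx]
    wmask = gather(batch["attention_mask"]) * valid[None, :, :]
    return SegmentBatch(
        windows=wins,
        token_ids=gather(batch["token_ids"]),
        age_ids=gather(batch["age_ids"]),
        segment_ids=gather(batch["segment_ids"]),
        position_ids=gather(batch["position_ids"]),
        window_mask=wmask,
        segment_mask=(wmask.sum(axis=2) > 0).astype(np.int64),
    )


def attention_footprint(config: HiModelConfig | FlatModelConfig) -> dict[str, int]:
    """Largest attention-matrix side and per-layer score-element count."""
    if isinstance(config, FlatModelConfig):
        side = config.max_len
        return {"largest_side": side,
                "score_elements_per_layer": config.heads * side * side}
    n_seg = len(segment_windows(config.max_len, config.window, config.stride))
    side = max(config.window, n_seg + 1)  # +1: the aggregator's CLS slot
    elements = config.heads * (
        n_seg * config.window ** 2 + (n_seg + 1) ** 2)
    return {"largest_side": side, "score_elements_per_layer": elements}


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class _EmbeddingBlock(nn.Module):
    """Sum of token, age, visit-segment and visit-position embeddings."""

    def __init__(self, cfg, n_positions: int, rng: np.random.Generator):
        super().__init__()
        self.token = nn.Embedding(cfg.vocab_size, cfg.hidden, rng)
        self.age = nn.Embedding(MAX_AGE + 1, cfg.hidden, rng)
        self.segment = nn.Embedding(2, cfg.hidden, rng)
        self.position = nn.Embedding(n_positions, cfg.hidden, rng)
        self.n_positions = n_positions
        self.vocab_size = cfg.vocab_size

    def __call__(self, token_ids, age_ids, segment_ids, position_ids) -> Tensor:
        if token_ids.max(initial=0) >= self.vocab_size:
            raise ValueError("token id out of vocabulary range")
        pos = np.minimum(position_ids, self.n_positions - 1)
        age = np.minimum(age_ids, MAX_AGE)
        return (self.token(token_ids) + self.age(age)
                + self.segment(segment_ids) + self.position(pos))


class HierarchicalRiskModel(nn.Module):
    """Sliding-window extractor + aggregator + pooling + sigmoid risk head."""

    def __init__(self, cfg: HiModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.embeddings = _EmbeddingBlock(cfg, cfg.max_len + 1, rng)
        self.extractor = nn.TransformerEncoder(
            cfg.extractor_layers, cfg.hidden, cfg.heads, cfg.intermediate,
            cfg.dropout, cfg.attn_dropout, rng)
        self.max_segments = len(
            segment_windows(cfg.max_len, cfg.window, cfg.stride))
        self.cls = Tensor(nn.trunc_normal(rng, (cfg.hidden,)), requires_grad=True)
        self.agg_position = nn.Embedding(self.max_segments + 1, cfg.hidden, rng)
        self.aggregator = nn.TransformerEncoder(
            cfg.aggregator_layers, cfg.hidden, cfg.heads, cfg.intermediate,
            cfg.dropout, cfg.attn_dropout, rng)
        self.pool = nn.Linear(cfg.hidden, cfg.hidden, rng)
        self.head = nn.Linear(cfg.hidden, 1, rng)

    # -- local feature extraction --------------------------------------------

    def extract_segments(self, batch: dict[str, np.ndarray],
                         ) -> tuple[Tensor, np.ndarray]:
        """Window the batch and encode each window; -> ([B, n_seg, d], mask)."""
        seg = make_segment_batch(batch, self.cfg.window, self.cfg.stride)
        B, n_seg, W = seg.token_ids.shape
        d = self.cfg.hidden
        flat = lambda a: a.reshape(B * n_seg, W)
        x = self.embeddings(flat(seg.token_ids), flat(seg.age_ids),
                            flat(seg.segment_ids), flat(seg.position_ids))
        kmask = flat(seg.window_mask).astype(np.float32)
        # all-padding windows get a dummy mask to keep softmax finite; their
        # representations are zeroed below via the segment mask
        dead = kmask.sum(axis=1) == 0
        if dead.any():
            kmask = kmask.copy()
            kmask[dead] = 1.0
        states = self.extractor(x, kmask)
        if self.cfg.seg_pooling == "first":
            reps = states[:, 0]
        else:
            m = flat(seg.window_mask).astype(np.float32)[:, :, None]
            denom = np.maximum(m.sum(axis=1), 1.0)
            reps = (states * m).sum(axis=1) / denom
        reps = reps.reshape(B, n_seg, d)
        reps = reps * seg.segment_mask[:, :, None].astype(np.float32)
        return reps, seg.segment_mask

    # -- aggregation ----------------------------------------------------------

    def aggregate(self, seg_reps: Tensor, seg_mask: np.ndarray,
                  ) -> tuple[Tensor, Tensor]:
        """CLS-prefixed aggregator; -> (pooled [B, d], seg states [B, n_seg, d])."""
        B, n_seg, d = seg_reps.shape
        cls_tile = self.cls.reshape(1, 1, d) * np.ones((B, 1, 1), dtype=np.float32)
        x = nn.concat([cls_tile, seg_reps], axis=1)
        pos_ids = np.minimum(np.arange(n_seg + 1), self.max_segments)
        x = x + self.agg_position(np.broadcast_to(pos_ids, (B, n_seg + 1)))
        kmask = np.concatenate(
            [np.ones((B, 1), dtype=np.float32),
             seg_mask.astype(np.float32)], axis=1)
        states = self.aggregator(x, kmask)
        pooled = self.pool(states[:, 0]).tanh()
        return pooled, states[:, 1:]

    def forward(self, batch: dict[str, np.ndarray]) -> Tensor:
        """Risk logits [B]."""
        seg_reps, seg_mask = self.extract_segments(batch)
        pooled, _ = self.aggregate(seg_reps, seg_mask)
        return self.head(pooled)[:, 0]

    def predict_risk(self, pooled: Tensor) -> Tensor:
        """Probability of the outcome from the pooled representation."""
        return self.head(pooled)[:, 0].sigmoid()

    def predict_proba(self, examples: Sequence[CohortExample],
                      batch_size: int = 64) -> np.ndarray:
        self.eval()
        out = []
        with nn.no_grad():
            for i in range(0, len(examples), batch_size):
                batch = batch_arrays(examples[i:i + batch_size])
                logits = self.forward(batch)
                out.append(1.0 / (1.0 + np.exp(-logits.data)))
        self.train()
        return np.concatenate(out) if out else np.zeros(0, dtype=np.float32)


class FlatRiskModel(nn.Module):
    """BERT-style baseline on the most recent `max_len - 1` records + CLS."""

    def __init__(self, cfg: FlatModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.embeddings = _EmbeddingBlock(cfg, cfg.max_len + 1, rng)
        self.encoder = nn.TransformerEncoder(
            cfg.layers, cfg.hidden, cfg.heads, cfg.intermediate,
            cfg.dropout, cfg.attn_dropout, rng)
        self.pool = nn.Linear(cfg.hidden, cfg.hidden, rng)
        self.head = nn.Linear(cfg.hidden, 1, rng)

    def truncate_batch(self, batch: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Keep the latest `max_len - 1` real records, prepend a CLS slot."""
        L = self.cfg.max_len
        B, n = batch["token_ids"].shape
        keep = L - 1
        out = {k: np.zeros((B, L), dtype=np.int64)
               for k in ("token_ids", "age_ids", "segment_ids",
                         "position_ids", "attention_mask")}
        out["token_ids"][:, 0] = Vocabulary.CLS
        out["attention_mask"][:, 0] = 1
        lengths = batch["attention_mask"].sum(axis=1).astype(int)
        for b in range(B):
            t = int(lengths[b])
            k = min(t, keep)
            sl = slice(t - k, t)
            for key in ("token_ids", "age_ids", "segment_ids", "position_ids"):
                out[key][b, 1:1 + k] = batch[key][b, sl]
            out["attention_mask"][b, 1:1 + k] = 1
            out["age_ids"][b, 0] = out["age_ids"][b, 1] if k else 0
            # re-base visit positions so the embedding table is never exceeded
            if k:
                out["position_ids"][b, 1:1 + k] -= out["position_ids"][b, 1]
        out["labels"] = batch.get("labels")
        return out

    def forward(self, batch: dict[str, np.ndarray]) -> Tensor:
        t = self.truncate_batch(batch)
        x = self.embeddings(t["token_ids"], t["age_ids"],
                            t["segment_ids"], t["position_ids"])
        states = self.encoder(x, t["attention_mask"].astype(np.float32))
        pooled = self.pool(states[:, 0]).tanh()
        return self.head(pooled)[:, 0]

    def predict_proba(self, examples: Sequence[CohortExample],
                      batch_size: int = 64) -> np.ndarray:
        self.eval()
        out = []
        with nn.no_grad():
            for i in range(0, len(examples), batch_size):
                batch = batch_arrays(examples[i:i + batch_size])
                logits = self.forward(batch)
                out.append(1.0 / (1.0 + np.exp(-logits.data)))
        self.train()
        return np.concatenate(out) if out else np.zeros(0, dtype=np.float32)


# ---------------------------------------------------------------------------
# checkpoints (single file, config embedded)
# ---------------------------------------------------------------------------


def save_checkpoint(model: nn.Module, path: str | pathlib.Path) -> None:
    cfg = model.cfg
    kind = "hierarchical" if isinstance(model, HierarchicalRiskModel) else "flat"
    meta = {"kind": kind, "config": dataclasses.asdict(cfg)}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | pathlib.Path,
                    ) -> "HierarchicalRiskModel | FlatRiskModel":
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["kind"] == "hierarchical":
        model = HierarchicalRiskModel(HiModelConfig(**meta["config"]))
    else:
        model = FlatRiskModel(FlatModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model
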