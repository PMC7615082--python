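"""Schedule, early stopping, metric oracles, and evaluation protocols."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from hibehrt.model import small_hier_config, HierarchicalRiskModel
from hibehrt.records import PatientHistory, RecordEvent, Vocabulary
from hibehrt.train import (ScheduleConfig, auprc, auroc, early_stop,
                           evaluate, filter_modalities, fraction_curve,
                           lr_at, modality_ablation, subgroup_eval)

from test_model import make_example


# ---------------------------------------------------------------------------
# learning-rate schedule and early stopping
# ---------------------------------------------------------------------------


class TestSchedule:
    CFG = ScheduleConfig(total_epochs=100, peak_lr=1e-4)

    def test_peak_at_warmup_end_and_hold_end(self):
        assert lr_at(100, 1000, self.CFG) == pytest.approx(1e-4)
        assert lr_at(500, 1000, self.CFG) == pytest.approx(1e-4)

    def test_zero_at_start_and_finish(self):
        assert lr_at(0, 1000, self.CFG) == 0.0
        assert lr_at(1000, 1000, self.CFG) == pytest.approx(0.0, abs=1e-18)

    def test_continuous_at_stage_boundaries(self):
        total = 10000
        for boundary in (1000, 5000):
            below = lr_at(boundary - 1, total, self.CFG)
            above = lr_at(boundary + 1, total, self.CFG)
            at = lr_at(boundary, total, self.CFG)
            assert abs(below - at) / self.CFG.peak_lr < 1e-2
            assert abs(above - at) / self.CFG.peak_lr < 1e-2

    def test_cosine_midpoint_is_half_peak(self):
        assert lr_at(750, 1000, self.CFG) == pytest.approx(5e-5, rel=1e-6)

    def test_fracs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ScheduleConfig(warmup_frac=0.2, hold_frac=0.4, decay_frac=0.5)


class TestEarlyStop:
    def test_strictly_decreasing_never_stops(self):
        losses = list(np.linspace(1.0, 0.1, 20))
        assert not early_stop(losses)

    def test_fires_after_seven_stale_epochs(self):
        assert early_stop([1.0] + [1.1] * 7)
        assert not early_stop([1.0] + [1.1] * 6)

    def test_late_improvement_resets_counter(self):
        assert not early_stop([1.0, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 0.9])

    def test_plateau_at_minimum_counts_as_stale(self):
        """A repeat of the minimum is not a strict improvement."""
        assert early_stop([1.0] + [1.0] * 7)


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------


def auroc_oracle(labels, scores):
    """Brute force over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_oracle(labels, scores):
    """All-threshold step interpolation: sum of P(t) * dR(t)."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores)[order]
    tp = fp = 0
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestMetrics:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_pairwise_example(self):
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_match_brute_force_oracles_on_random_instances(self):
        """AUROC/AUPRC equal pairwise / all-threshold oracles, 200 draws."""
        rng = np.random.default_rng(123)
        for trial in range(200):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert auroc(labels, scores) == pytest.approx(
                auroc_oracle(labels, scores), abs=1e-10)
            assert auprc(labels, scores) == pytest.approx(
                auprc_oracle(labels, scores), abs=1e-10)


# ---------------------------------------------------------------------------
# protocols (with a deterministic stand-in model)
# ---------------------------------------------------------------------------


class OracleModel:
    """Scores each example by a fixed per-patient table (no learning)."""

    def __init__(self, table):
        self.table = table

    def predict_proba(self, examples, batch_size=64):
        return np.array([self.table[e.patient_id] for e in examples])


def _cohort(n=60, seed=0, frac_long=0.5, p_short=0.2, p_long=0.4):
    rng = np.random.default_rng(seed)
    examples, scores = [], {}
    for i in range(n):
        long_ = rng.random() < frac_long
        length = int(rng.integers(300, 400)) if long_ else int(
            rng.integers(20, 200))
        label = int(rng.random() < (p_long if long_ else p_short))
        ex = make_example(np.arange(4, 24), max_len=32, label=label)
        ex.ehr_length = length
        ex.patient_id = f"P{i}"
        examples.append(ex)
        scores[f"P{i}"] = 0.6 * label + 0.4 * rng.random()
    return examples, OracleModel(scores)


class TestSubgroupEval:
    def test_three_reports_with_matched_rate(self):
        examples, model = _cohort(n=400, seed=1)
        reports = subgroup_eval(examples, model,
                                rng=np.random.default_rng(0))
        assert set(reports) == {"short", "long", "long_matched"}
        short, matched = reports["short"], reports["long_matched"]
        rate_short = short.n_pos / short.n
        rate_matched = matched.n_pos / matched.n
        # realized rate within one positive count of the target
        assert abs(rate_matched - rate_short) <= 1.5 / matched.n

    def test_reproducible_with_fixed_seed(self):
        examples, model = _cohort(n=300, seed=2)
        a = subgroup_eval(examples, model, rng=np.random.default_rng(7))
        b = subgroup_eval(examples, model, rng=np.random.default_rng(7))
        assert a["long_matched"].auroc == b["long_matched"].auroc

    def test_infeasible_when_long_rate_below_short(self):
        examples, model = _cohort(n=300, seed=3, p_short=0.5, p_long=0.05)
        reports = subgroup_eval(examples, model,
                                rng=np.random.default_rng(0))
        assert reports["long_matched"] is None


class TestFractionCurve:
    def _factory(self, seed):
        return OracleModel({f"P{i}": (i * 37 % 100) / 100 for i in range(500)})

    def test_full_fraction_uses_whole_training_set(self, monkeypatch):
        import hibehrt.train as train_mod
        seen = {}

        def fake_train(model, subset, val, schedule, seed=0, restore_best=True):
            seen.setdefault("sizes", []).append(len(subset))
            return pd.DataFrame()

        monkeypatch.setattr(train_mod, "train_supervised", fake_train)
        examples, _ = _cohort(n=100, seed=4)
        fraction_curve(examples[:80], examples[80:], self._factory,
                       ScheduleConfig(total_epochs=1), fractions=(1.0,),
                       n_seeds=2)
        assert seen["sizes"] == [80, 80]

    def test_invalid_fraction_rejected(self):
        examples, _ = _cohort(n=20, seed=5)
        with pytest.raises(ValueError):
            fraction_curve(examples[:10], examples[10:], self._factory,
                           ScheduleConfig(total_epochs=1), fractions=(0.0,))

    def test_deterministic_subsampling(self, monkeypatch):
        import hibehrt.train as train_mod
        picked = []

        def fake_train(model, subset, val, schedule, seed=0, restore_best=True):
            picked.append(tuple(e.patient_id for e in subset))
            return pd.DataFrame()

        monkeypatch.setattr(train_mod, "train_supervised", fake_train)
        examples, _ = _cohort(n=100, seed=6)
        for _ in range(2):
            fraction_curve(examples[:80], examples[80:], self._factory,
                           ScheduleConfig(total_epochs=1), fractions=(0.2,),
                           n_seeds=1, base_seed=3)
        assert picked[0] == picked[1]


def _histories_for_ablation(n=30, seed=0):
    rng = np.random.default_rng(seed)
    histories, baselines = [], {}
    for i in range(n):
        pid = f"P{i}"
        label = int(rng.random() < 0.4)
        events = [RecordEvent(dt.date(2005, 1, 1) + dt.timedelta(days=int(d)),
                              "diagnosis", code=f"DIAG_{rng.integers(5):03d}")
                  for d in sorted(rng.integers(0, 900, size=12))]
        events += [RecordEvent(dt.date(2006, 1, 1), "medication",
                               code="MED_001")]
        if label:
            events.append(RecordEvent(dt.date(2006, 6, 1), "test",
                                      code="TEST_SIGNAL"))
        events.sort(key=lambda e: e.date)
        histories.append(PatientHistory(pid, dt.date(1950, 1, 1), events))
        baselines[pid] = (dt.date(2008, 1, 1), label)
    return histories, baselines


class TestModalityAblation:
    def test_eval_only_base_equals_absent_modality(self):
        """Adding a modality with no records leaves metrics unchanged."""
        histories, baselines = _histories_for_ablation()
        vocab = Vocabulary.from_histories(histories)
        scores = {pid: np.random.default_rng(hash(pid) % 2**32).random()
                  for pid in baselines}
        model = OracleModel(scores)
        table = modality_ablation(histories, baselines, vocab, max_len=32,
                                  model=model,
                                  add_one_of=["procedure", "test"])
        base = table[table.config == "base"].iloc[0]
        proc = table[table.config == "base+procedure"].iloc[0]
        assert proc.auroc == pytest.approx(base.auroc, abs=1e-6)
        assert proc.auprc == pytest.approx(base.auprc, abs=1e-6)

    def test_output_has_row_per_arm(self):
        histories, baselines = _histories_for_ablation()
        vocab = Vocabulary.from_histories(histories)
        model = OracleModel({pid: 0.5 for pid in baselines})
        table = modality_ablation(histories, baselines, vocab, max_len=32,
                                  model=model)
        assert list(table.config)[0] == "base"
        assert len(table) == 1 + 7  # base + each remaining modality

    def test_filter_modalities_drops_records(self):
        histories, _ = _histories_for_ablation()
        kept = filter_modalities(histories, {"medication"})
        assert all(ev.modality == "medication"
                   for h in kept for ev in h.events)

    def test_requires_exactly_one_of_model_trainer(self):
        histories, baselines = _histories_for_ablation()
        vocab = Vocabulary.from_histories(histories)
        with pytest.raises(ValueError):
            modality_ablation(histories, baselines, vocab, max_len=32)


class TestEvaluateOnModel:
    def test_learnability_smoke(self):
        """A separable toy cohort is fit to high AUROC quickly."""
        rng = np.random.default_rng(0)
        import hibehrt.train as train_mod
        train, val = [], []
        for i in range(160):
            y = i % 2
            toks = rng.integers(5, 30, size=40)
            if y:
                toks[rng.integers(0, 40, size=6)] = 4
            ex = make_example(toks, max_len=64, label=y)
            ex.patient_id = f"P{i}"
            (train if i < 120 else val).append(ex)
        model = HierarchicalRiskModel(
            small_hier_config(30, max_len=64, window=16, stride=10), seed=0)
        sched = ScheduleConfig(total_epochs=20, peak_lr=3e-3, batch_size=16,
                               patience=20)
        train_mod.train_supervised(model, train, val, sched, seed=0)
        rep = evaluate(model, val)
        assert rep.auroc > 0.95
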