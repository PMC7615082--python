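"""Seeded simulator of multimodal longitudinal EHR cohorts.

The generator emulates primary-care-like timelines: visits arrive as a
gamma renewal process (shape 2, giving the overdispersed inter-visit gaps
and long right tail of sequence lengths seen in routine EHR), each visit
carries a Poisson number of records whose modalities follow a configurable
mix, and continuous modalities draw values inside their plausibility
ranges. A known long-range risk signal can be planted: a small set of
marker codes inserted either among recent records or strictly deeper than
the newest 256 records, and the binary five-year outcome is drawn from a
logistic model on signal carriage. Ground truth (carrier flag, linear
predictor, outcome, baseline and incident dates) is emitted alongside, so
every downstream claim is testable without access-restricted data.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (CohortExample, PatientHistory, RecordEvent, Vocabulary,
                      default_schemes, encode_history, year_window_days)

__all__ = [
    "SyntheticCohortParams", "SyntheticTruth",
    "generate_patient", "generate", "generate_cohort",
    "build_examples", "split_examples",
]

_DATA_START = dt.date(1985, 1, 1)
_DATA_END = dt.date(2015, 9, 30)

_DEFAULT_MIX = {
    "diagnosis": 0.12, "medication": 0.35, "test": 0.30, "procedure": 0.02,
    "systolic_bp": 0.06, "diastolic_bp": 0.06, "bmi": 0.03,
    "smoking": 0.04, "drinking": 0.02,
}
_DEFAULT_VOCAB_SIZES = {
    "diagnosis": 200, "medication": 100, "test": 80, "procedure": 60,
}
_STATUS_LEVELS = ("current", "ex", "non")

#: Measurement value distributions (mean, sd, clip range inside the bins).
_VALUE_DISTS = {
    "systolic_bp": (130.0, 17.0, 81.0, 199.0),
    "diastolic_bp": (80.0, 12.0, 51.0, 139.0),
    "bmi": (27.0, 5.0, 16.5, 49.5),
}


@dataclasses.dataclass
class SyntheticCohortParams:
    """Generative knobs for one synthetic cohort.

    Defaults describe the long-range benchmark condition: ~9-year learning
    periods at ~10 visits/year and ~4 codes/visit (several hundred records
    per patient), a 4-token marker set planted deeper than the newest 256
    records in 20% of patients, and a logistic outcome with ~10% prevalence
    (carriers at ~50% risk, non-carriers at ~2%).
    """

    n_patients: int = 5000
    visit_rate: float = 10.0              # mean visits / year
    gamma_shape: float = 2.0              # inter-visit gap shape (overdispersion)
    codes_per_visit: float = 4.0          # Poisson mean (min 1 per visit)
    learning_years_mean: float = 8.5
    learning_years_sd: float = 1.5
    learning_years_min: float = 4.0
    modality_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_MIX))
    vocab_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_VOCAB_SIZES))
    signal_tokens: tuple[str, ...] = tuple(f"DIAG_SIGNAL_{i}" for i in range(4))
    n_signal_insertions: int = 20     # marker records per carrier (recurring)
    # latent phenotype mixing: a per-patient topic biases code choice toward
    # a phenotype-specific sub-vocabulary, emulating comorbidity-style code
    # co-occurrence (0 phenotypes = codes i.i.d. within a modality)
    n_phenotypes: int = 0
    phenotype_weight: float = 0.5     # P(coded record drawn from sub-vocab)
    phenotype_code_frac: float = 0.15  # sub-vocab size as fraction of vocab
    signal_phenotype: bool = False    # carriers get their own sub-vocabulary
    signal_frac: float = 0.2
    signal_depth: str = "deep"            # "recent" | "deep"
    deep_depth_range: tuple[int, int] = (265, 370)
    recent_depth_range: tuple[int, int] = (5, 100)
    min_records: int = 0                  # regenerate visit stream below this
    beta0: float = -3.9                   # baseline log-odds of outcome
    beta1: float = 3.9                    # marker log-odds effect
    followup_years: float = 5.5
    outcome_code: str = "DIAG_TARGET"
    disease: str = "synthetic_target"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.modality_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"modality_mix sums to {total}, expected 1")
        if self.visit_rate <= 0 or self.codes_per_visit <= 0:
            raise ValueError("rates must be positive")
        if self.signal_depth not in ("recent", "deep"):
            raise ValueError("signal_depth must be 'recent' or 'deep'")
        if self.signal_depth == "deep" and self.min_records == 0:
            # deep planting needs room beyond the newest-256 boundary; the
            # depth cap itself adapts to each patient's record count
            self.min_records = self.deep_depth_range[0] + 25


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    has_signal: bool
    linear_predictor: float
    outcome: int
    baseline_date: dt.date
    incident_date: dt.date | None
    n_records: int


def _visit_dates(params: SyntheticCohortParams, start: dt.date, end: dt.date,
                 rng: np.random.Generator) -> list[dt.date]:
    """Gamma renewal process over (start, end); always at least one visit."""
    span_years = (end.toordinal() - start.toordinal()) / 365.25
    k = params.gamma_shape
    scale = 1.0 / (k * params.visit_rate)   # mean gap = 1 / visit_rate years
    n_guess = max(8, int(span_years * params.visit_rate * 1.6))
    t, dates = 0.0, []
    while True:
        gaps = rng.gamma(k, scale, size=n_guess)
        for g in gaps:
            t += g
            if t >= span_years:
                break
            dates.append(start.toordinal() + int(t * 365.25))
        else:
            continue
        break
    if not dates:
        dates = [start.toordinal() + (end.toordinal() - start.toordinal()) // 2]
    return [dt.date.fromordinal(d) for d in sorted(set(dates))]


def _record_stream(params: SyntheticCohortParams, history_start: dt.date,
                   baseline: dt.date, rng: np.random.Generator,
                   phenotype: int = -1, carrier: bool = False,
                   ) -> list[RecordEvent]:
    modalities = list(params.modality_mix)
    cum = np.cumsum([params.modality_mix[m] for m in modalities])
    cum[-1] = 1.0
    prefixes = {"diagnosis": "DIAG", "medication": "MED",
                "test": "TEST", "procedure": "PROC"}
    dates = _visit_dates(params, history_start, baseline, rng)
    n_per_visit = np.maximum(1, rng.poisson(params.codes_per_visit,
                                            size=len(dates)))
    total = int(n_per_visit.sum())
    which = np.searchsorted(cum, rng.random(total))
    u_code = rng.random(total)          # one uniform per record for its code
    u_val = rng.normal(size=total)      # one normal per record for its value
    u_blk = rng.random(total)           # sub-vocabulary selection
    w_phen = params.phenotype_weight if phenotype >= 0 else 0.0
    use_carrier_block = carrier and params.signal_phenotype

    def code_index(m: str, k: int) -> int:
        size = params.vocab_sizes[m]
        if u_blk[k] < w_phen:
            block = max(1, int(params.phenotype_code_frac * size))
            if use_carrier_block and u_blk[k] < 0.5 * w_phen:
                start = params.n_phenotypes * block   # carrier sub-vocabulary
            else:
                start = phenotype * block
            return (start + int(u_code[k] * block)) % size
        return int(u_code[k] * size)

    events: list[RecordEvent] = []
    k = 0
    for date, n_rec in zip(dates, n_per_visit):
        for w in which[k:k + n_rec]:
            m = modalities[w]
            if m in _VALUE_DISTS:
                mu, sd, lo, hi = _VALUE_DISTS[m]
                val = min(max(mu + sd * u_val[k], lo), hi)
                events.append(RecordEvent(date, m, value=round(val, 1)))
            elif m in ("smoking", "drinking"):
                lvl = _STATUS_LEVELS[int(u_code[k] * len(_STATUS_LEVELS))]
                events.append(RecordEvent(date, m, code=f"{m.upper()}_{lvl}"))
            else:
                events.append(RecordEvent(
                    date, m, code=f"{prefixes[m]}_{code_index(m, k):04d}"))
            k += 1
    return events


def _plant_signal(events: list[RecordEvent], params: SyntheticCohortParams,
                  rng: np.random.Generator) -> list[RecordEvent]:
    """Replace records at sampled depths-from-the-end with marker codes."""
    n = len(events)
    lo, hi = (params.deep_depth_range if params.signal_depth == "deep"
              else params.recent_depth_range)
    hi = min(hi, n - 1)
    if hi < lo:
        raise ValueError(f"sequence of {n} records too short to plant at depth {lo}")
    k = min(params.n_signal_insertions, hi - lo + 1)
    depths = rng.choice(np.arange(lo, hi + 1), size=k, replace=False)
    out = list(events)
    for j, d in enumerate(depths):
        tok = params.signal_tokens[j % len(params.signal_tokens)]
        idx = n - 1 - int(d)
        out[idx] = RecordEvent(out[idx].date, "diagnosis", code=tok)
    return out


def generate_patient(params: SyntheticCohortParams, rng: np.random.Generator,
                     patient_id: str = "P0",
                     ) -> tuple[PatientHistory, SyntheticTruth]:
    """Simulate one patient timeline with ground truth."""
    followup_days = year_window_days(params.followup_years)
    has_signal = bool(rng.random() < params.signal_frac)
    phenotype = (int(rng.integers(params.n_phenotypes))
                 if params.n_phenotypes > 0 else -1)
    for _attempt in range(200):
        learn = max(params.learning_years_min,
                    rng.normal(params.learning_years_mean,
                               params.learning_years_sd))
        lo = _DATA_START.toordinal() + int(learn * 365.25) + 1
        hi = _DATA_END.toordinal() - followup_days
        baseline = dt.date.fromordinal(int(rng.integers(lo, hi + 1)))
        history_start = dt.date.fromordinal(
            baseline.toordinal() - int(learn * 365.25))
        events = _record_stream(params, history_start, baseline, rng,
                                phenotype=phenotype, carrier=has_signal)
        if len(events) >= params.min_records:
            break
    else:
        raise RuntimeError(
            "could not reach min_records; visit_rate / learning period "
            "parameters are inconsistent with the requested minimum length")
    age_at_baseline = min(max(rng.normal(53.0, 18.0), 16.0), 90.0)
    birth = dt.date.fromordinal(
        max(1, baseline.toordinal() - int(age_at_baseline * 365.25)
            - int(learn * 365.25)))

    if has_signal:
        events = _plant_signal(events, params, rng)

    lin = params.beta0 + params.beta1 * has_signal
    p = 1.0 / (1.0 + np.exp(-lin))
    outcome = int(rng.random() < p)
    incident: dt.date | None = None
    incident_dates: dict[str, dt.date] = {}
    if outcome:
        offset = int(rng.integers(year_window_days(1) + 1,
                                  year_window_days(5) + 1))
        incident = dt.date.fromordinal(baseline.toordinal() + offset)
        events.append(RecordEvent(incident, "diagnosis", code=params.outcome_code))
        incident_dates[params.disease] = incident

    history = PatientHistory(patient_id=patient_id, birth_date=birth,
                             events=events, incident_dates=incident_dates)
    n_learning = sum(1 for ev in events if ev.date < baseline)
    truth = SyntheticTruth(patient_id=patient_id, has_signal=has_signal,
                           linear_predictor=float(lin), outcome=outcome,
                           baseline_date=baseline, incident_date=incident,
                           n_records=n_learning)
    return history, truth


def generate(params: SyntheticCohortParams,
             ) -> tuple[list[PatientHistory], list[SyntheticTruth]]:
    """Simulate the whole cohort (deterministic in params.seed)."""
    rng = np.random.default_rng(params.seed)
    histories, truths = [], []
    for i in range(params.n_patients):
        h, t = generate_patient(params, rng, patient_id=f"P{i:06d}")
        histories.append(h)
        truths.append(t)
    return histories, truths


# ---------------------------------------------------------------------------
# file emission (the exact external formats of the records module)
# ---------------------------------------------------------------------------


def histories_to_frames(histories: Sequence[PatientHistory],
                        truths: Sequence[SyntheticTruth],
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    ev_rows = []
    for h in histories:
        for ev in h.events:
            ev_rows.append((h.patient_id, ev.date.isoformat(), ev.modality,
                            "" if ev.code is None else ev.code,
                            "" if ev.value is None else f"{ev.value:g}",
                            h.birth_date.isoformat()))
    events = pd.DataFrame(ev_rows, columns=[
        "patient_id", "date", "modality", "code", "value", "birth_date"])
    out_rows = [(t.patient_id, "synthetic_target", t.incident_date.isoformat())
                for t in truths if t.incident_date is not None]
    outcomes = pd.DataFrame(out_rows,
                            columns=["patient_id", "disease", "incident_date"])
    truth_rows = [(t.patient_id, int(t.has_signal), f"{t.linear_predictor:.6f}",
                   t.outcome, t.baseline_date.isoformat(),
                   "" if t.incident_date is None else t.incident_date.isoformat(),
                   t.n_records) for t in truths]
    truth = pd.DataFrame(truth_rows, columns=[
        "patient_id", "has_signal", "linear_predictor", "outcome",
        "baseline_date", "incident_date", "n_records"])
    return events, outcomes, truth


def generate_cohort(params: SyntheticCohortParams, out_dir: str | pathlib.Path,
                    ) -> dict[str, pathlib.Path]:
    """Simulate and write events.csv / outcomes.csv / truth.csv.

    Output is byte-identical for identical params (including seed).
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    histories, truths = generate(params)
    events, outcomes, truth = histories_to_frames(histories, truths)
    paths = {"events": out / "events.csv", "outcomes": out / "outcomes.csv",
             "truth": out / "truth.csv"}
    events.to_csv(paths["events"], index=False, lineterminator="\n")
    outcomes.to_csv(paths["outcomes"], index=False, lineterminator="\n")
    truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    return paths


# ---------------------------------------------------------------------------
# convenience: examples with generator baselines (exact depth control)
# ---------------------------------------------------------------------------


def build_examples(histories: Sequence[PatientHistory],
                   truths: Sequence[SyntheticTruth], vocab: Vocabulary,
                   max_len: int) -> list[CohortExample]:
    """Encode cohorts at their generator-assigned baselines and true labels.

    This preserves the planted signal's exact depth relative to the
    newest-256 boundary; the stochastic baseline-selection pipeline is
    exercised separately through `records.build_cohort`.
    """
    schemes = default_schemes()
    out = []
    for h, t in zip(histories, truths):
        out.append(encode_history(h, t.baseline_date, vocab, max_len, schemes,
                                  label=t.outcome))
    return out


def split_examples(examples: Sequence[CohortExample], seed: int,
                   fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
                   ) -> tuple[list[CohortExample], list[CohortExample],
                              list[CohortExample]]:
    """Label-stratified train / tuning / validation split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, tune, val = [], [], []
    for lbl in (0, 1):
        idx = [i for i, ex in enumerate(examples) if ex.label == lbl]
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_tune = int(round(fractions[1] * n))
        train += [examples[i] for i in idx[:n_train]]
        tune += [examples[i] for i in idx[n_train:n_train + n_tune]]
        val += [examples[i] for i in idx[n_train + n_tune:]]
    perm = np.random.default_rng(seed + 1)
    for part in (train, tune, val):
        perm.shuffle(part)
    return train, tune, val
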