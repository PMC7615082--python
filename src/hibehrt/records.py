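"""Patient timelines, cohort construction, and model-ready sequence encoding.

A patient history is a date-ordered list of multimodal clinical records
(diagnoses, medications, procedures, tests, blood-pressure / BMI readings,
smoking and drinking status). Cohort construction picks a *baseline date*
per patient, keeps everything strictly before it as the learning period, and
assigns a binary label for incidence of the target condition between one and
five years after baseline (the first post-baseline year is blanked out to
absorb recording-delay noise). Learning-period records are tokenized —
continuous measurements are discretized into fixed-width bins — and encoded
as parallel integer arrays (token / age / visit-segment / visit-position)
for the sequence models.

Date arithmetic uses a 365.25-day year; multi-year windows are rounded to
whole days (1y -> 365, 3y -> 1096, 5y -> 1826), which keeps baseline
sampling windows and label windows mutually consistent at the boundaries.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MODALITIES", "VALUE_MODALITIES", "CATEGORICAL_MODALITIES",
    "REJECTED", "EXCLUDE", "YEAR_DAYS",
    "RecordEvent", "PatientHistory", "BinningScheme", "Vocabulary",
    "EncodedSequence", "CohortExample",
    "bin_value", "count_bins", "default_schemes",
    "find_incident_date", "effective_incident",
    "select_baseline_positive", "select_baseline_negative",
    "assign_label", "encode_history", "decode_tokens", "year_window_days",
]

YEAR_DAYS = 365.25

VALUE_MODALITIES = frozenset({"systolic_bp", "diastolic_bp", "bmi"})
CATEGORICAL_MODALITIES = frozenset(
    {"diagnosis", "medication", "procedure", "test", "smoking", "drinking"}
)
MODALITIES = VALUE_MODALITIES | CATEGORICAL_MODALITIES

#: Sentinel for a continuous reading outside its plausible range (record dropped).
REJECTED = None

#: Sentinel label for patients excluded from the cohort at a given baseline.
EXCLUDE = "EXCLUDE"


def year_window_days(n_years: float) -> int:
    """Whole-day length of an n-year window under the 365.25-day year."""
    return round(n_years * YEAR_DAYS)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RecordEvent:
    """One clinical record: a coded event or a continuous measurement."""

    date: dt.date
    modality: str
    code: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        has_code, has_value = self.code is not None, self.value is not None
        if has_code == has_value:
            raise ValueError("exactly one of code/value must be set")
        if self.modality in VALUE_MODALITIES and not has_value:
            raise ValueError(f"{self.modality} requires a numeric value")
        if self.modality in CATEGORICAL_MODALITIES and not has_code:
            raise ValueError(f"{self.modality} requires a code")


@dataclasses.dataclass
class PatientHistory:
    """Date-ordered multimodal timeline of a single patient."""

    patient_id: str
    birth_date: dt.date
    events: list[RecordEvent]
    incident_dates: dict[str, dt.date] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        prev = None
        for ev in self.events:
            if ev.date < self.birth_date:
                raise ValueError(
                    f"patient {self.patient_id}: event on {ev.date} precedes birth")
            if prev is not None and ev.date < prev:
                raise ValueError(f"patient {self.patient_id}: events not date-ordered")
            prev = ev.date

    @property
    def history_start(self) -> dt.date:
        if not self.events:
            raise ValueError(f"patient {self.patient_id} has no events")
        return self.events[0].date


@dataclasses.dataclass(frozen=True)
class BinningScheme:
    """Fixed-width bins for a continuous measurement, inclusive of both ends."""

    lo: float
    hi: float
    step: float
    prefix: str

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = (self.hi - self.lo) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"range ({self.lo}, {self.hi}) is not a multiple of step {self.step}")


def default_schemes() -> dict[str, BinningScheme]:
    """Plausibility ranges and bin widths for BP (mmHg) and BMI (kg/m^2)."""
    return {
        "systolic_bp": BinningScheme(80, 200, 5, "SBP"),
        "diastolic_bp": BinningScheme(50, 140, 5, "DBP"),
        "bmi": BinningScheme(16, 50, 1, "BMI"),
    }


def _fmt(x: float) -> str:
    return f"{x:g}"


def bin_value(value: float, scheme: BinningScheme) -> str | None:
    """Map a reading to its bin token, or REJECTED (None) if out of range.

    Bins are half-open [lo + k*step, lo + (k+1)*step); the upper range
    boundary is closed so a reading equal to `hi` lands in the last bin.
    """
    if value is None or not math.isfinite(value):
        return REJECTED
    if value < scheme.lo or value > scheme.hi:
        return REJECTED
    k = int((value - scheme.lo) // scheme.step)
    k = min(k, count_bins(scheme) - 1)  # value == hi -> last bin
    lo = scheme.lo + k * scheme.step
    return f"{scheme.prefix}_{_fmt(lo)}_{_fmt(lo + scheme.step)}"


def count_bins(scheme: BinningScheme) -> int:
    return round((scheme.hi - scheme.lo) / scheme.step)


class Vocabulary:
    """Bijective token <-> id map with reserved PAD/UNK/MASK/CLS ids."""

    PAD, UNK, MASK, CLS = 0, 1, 2, 3
    RESERVED = ("[PAD]", "[UNK]", "[MASK]", "[CLS]")

    def __init__(self, tokens: Iterable[str] = ()):
        self._token_to_id: dict[str, int] = {
            t: i for i, t in enumerate(self.RESERVED)}
        for tok in sorted(set(tokens)):
            if tok in self._token_to_id:
                raise ValueError(f"token {tok!r} collides with a reserved token")
            self._token_to_id[tok] = len(self._token_to_id)
        self._id_to_token = {i: t for t, i in self._token_to_id.items()}

    def __len__(self) -> int:
        return len(self._token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self._token_to_id

    def encode(self, token: str) -> int:
        return self._token_to_id.get(token, self.UNK)

    def decode(self, idx: int) -> str:
        return self._id_to_token[idx]

    def to_json(self) -> str:
        data_tokens = [t for t in self._token_to_id if t not in self.RESERVED]
        return json.dumps({"tokens": data_tokens})

    @classmethod
    def from_json(cls, s: str) -> "Vocabulary":
        return cls(json.loads(s)["tokens"])

    @classmethod
    def from_histories(cls, histories: Iterable[PatientHistory],
                       schemes: Mapping[str, BinningScheme] | None = None,
                       ) -> "Vocabulary":
        schemes = default_schemes() if schemes is None else schemes
        tokens: set[str] = set()
        for h in histories:
            for ev in h.events:
                tok = record_token(ev, schemes)
                if tok is not REJECTED:
                    tokens.add(tok)
        return cls(tokens)


@dataclasses.dataclass
class EncodedSequence:
    """Model-ready parallel arrays for one learning-period sequence."""

    token_ids: np.ndarray
    age_ids: np.ndarray
    segment_ids: np.ndarray
    position_ids: np.ndarray
    attention_mask: np.ndarray
    true_length: int

    def validate(self) -> None:
        n = len(self.token_ids)
        for name in ("age_ids", "segment_ids", "position_ids", "attention_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if not (np.all(self.attention_mask[: self.true_length] == 1)
                and np.all(self.attention_mask[self.true_length:] == 0)):
            raise ValueError("attention_mask must be 1 on the true prefix, 0 after")


@dataclasses.dataclass
class CohortExample:
    """Encoded learning period plus 5-year outcome label and metadata."""

    encoded: EncodedSequence
    label: int | None
    baseline_date: dt.date
    ehr_length: int
    patient_id: str


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------


def find_incident_date(history: PatientHistory,
                       code_set: set[str]) -> dt.date | None:
    """Earliest event date whose code is in `code_set`; None if never."""
    if not code_set:
        raise ValueError("code_set must be non-empty")
    for ev in history.events:  # events are date-ordered
        if ev.code is not None and ev.code in code_set:
            return ev.date
    return None


def effective_incident(history: PatientHistory, disease: str,
                       code_set: set[str] | None) -> dt.date | None:
    """First occurrence from the outcomes table and/or disease code set."""
    dates = []
    if disease in history.incident_dates:
        dates.append(history.incident_dates[disease])
    if code_set:
        d = find_incident_date(history, code_set)
        if d is not None:
            dates.append(d)
    return min(dates) if dates else None


MIN_LEARNING_DAYS = year_window_days(3)   # 1096
BLANKING_DAYS = year_window_days(1)       # 365
HORIZON_DAYS = year_window_days(5)        # 1826


def select_baseline_positive(incident: dt.date, history_start: dt.date,
                             rng: np.random.Generator) -> dt.date | None:
    """Uniform baseline 1-5 years before the incident, requiring a >=3-year
    learning period; None when the window is infeasible (patient excluded)."""
    inc = incident.toordinal()
    lo = inc - HORIZON_DAYS
    hi = inc - BLANKING_DAYS - 1  # strictly more than the blanked year before
    lo = max(lo, history_start.toordinal() + MIN_LEARNING_DAYS)
    if lo > hi:
        return None
    return dt.date.fromordinal(int(rng.integers(lo, hi + 1)))


def select_baseline_negative(history_start: dt.date, data_end: dt.date,
                             rng: np.random.Generator) -> dt.date | None:
    """Uniform baseline with >=3 years of history before and >=5 years of
    follow-up after; None when infeasible."""
    lo = history_start.toordinal() + MIN_LEARNING_DAYS
    hi = data_end.toordinal() - HORIZON_DAYS
    if lo > hi:
        return None
    return dt.date.fromordinal(int(rng.integers(lo, hi + 1)))


def assign_label(history: PatientHistory, baseline: dt.date,
                 code_set: set[str] | None, follow_up_end: dt.date,
                 disease: str = "") -> int | str:
    """Five-year incidence label with a 1-year post-baseline blanking window.

    Returns 1 for an incident in (baseline+1y, baseline+5y], EXCLUDE for an
    incident inside the blanked first year or when follow-up does not reach
    baseline+5y, and 0 otherwise.
    """
    incident = effective_incident(history, disease, code_set)
    b = baseline.toordinal()
    if incident is not None:
        diff = incident.toordinal() - b
        if 0 < diff <= BLANKING_DAYS:
            return EXCLUDE
        if BLANKING_DAYS < diff <= HORIZON_DAYS:
            return 1
    if follow_up_end.toordinal() - b < HORIZON_DAYS:
        return EXCLUDE
    return 0


# ---------------------------------------------------------------------------
# sequence encoding
# ---------------------------------------------------------------------------


def record_token(event: RecordEvent,
                 schemes: Mapping[str, BinningScheme]) -> str | None:
    """Token for a record: the code itself, or the bin token for a reading."""
    if event.modality in VALUE_MODALITIES:
        return bin_value(event.value, schemes[event.modality])
    return event.code


def encode_history(history: PatientHistory, baseline: dt.date,
                   vocab: Vocabulary, max_len: int,
                   schemes: Mapping[str, BinningScheme] | None = None,
                   label: int | None = None) -> CohortExample:
    """Encode the learning period (events strictly before baseline).

    Continuous readings are binned (out-of-range readings dropped), codes are
    mapped through the vocabulary (UNK for unseen tokens). Records sharing a
    calendar date form one visit: segment ids alternate 0/1 across visits and
    position ids increment per visit. If more than `max_len` records survive,
    the most recent `max_len` are kept; `ehr_length` reports the
    pre-truncation count. The sequence is right-padded to `max_len`.
    """
    schemes = default_schemes() if schemes is None else schemes
    kept: list[tuple[dt.date, str]] = []
    for ev in history.events:
        if ev.date >= baseline:
            break
        tok = record_token(ev, schemes)
        if tok is REJECTED:
            continue
        kept.append((ev.date, tok))
    ehr_length = len(kept)
    if ehr_length == 0:
        raise ValueError(f"patient {history.patient_id}: empty learning period")
    kept = kept[-max_len:]
    n = len(kept)

    token_ids = np.zeros(max_len, dtype=np.int64)
    age_ids = np.zeros(max_len, dtype=np.int64)
    segment_ids = np.zeros(max_len, dtype=np.int64)
    position_ids = np.zeros(max_len, dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.int64)

    birth = history.birth_date.toordinal()
    visit = -1
    prev_date: dt.date | None = None
    for i, (date, tok) in enumerate(kept):
        if date != prev_date:
            visit += 1
            prev_date = date
        token_ids[i] = vocab.encode(tok)
        age = int((date.toordinal() - birth) / YEAR_DAYS)
        age_ids[i] = min(max(age, 0), 110)
        segment_ids[i] = visit % 2
        position_ids[i] = visit
        mask[i] = 1

    encoded = EncodedSequence(token_ids, age_ids, segment_ids, position_ids,
                              mask, true_length=n)
    return CohortExample(encoded=encoded, label=label, baseline_date=baseline,
                         ehr_length=ehr_length, patient_id=history.patient_id)


def decode_tokens(encoded: EncodedSequence, vocab: Vocabulary) -> list[str]:
    """Tokens of the real (unpadded) positions, for round-trip checks."""
    return [vocab.decode(int(i))
            for i in encoded.token_ids[: encoded.true_length]]


def build_cohort(histories: Sequence[PatientHistory], disease: str,
                 code_set: set[str], data_end: dt.date, vocab: Vocabulary,
                 max_len: int, rng: np.random.Generator,
                 schemes: Mapping[str, BinningScheme] | None = None,
                 ) -> list[CohortExample]:
    """Full pipeline: incident lookup, baseline sampling, labelling, encoding.

    Patients whose feasible baseline window is empty, whose label is EXCLUDE,
    or whose learning period is empty are dropped.
    """
    examples: list[CohortExample] = []
    for h in histories:
        incident = effective_incident(h, disease, code_set)
        if not h.events:
            continue
        if incident is not None:
            baseline = select_baseline_positive(incident, h.history_start, rng)
        else:
            baseline = select_baseline_negative(h.history_start, data_end, rng)
        if baseline is None:
            continue
        label = assign_label(h, baseline, code_set, data_end, disease)
        if label == EXCLUDE:
            continue
        try:
            ex = encode_history(h, baseline, vocab, max_len, schemes,
                                label=int(label))
        except ValueError:
            continue
        examples.append(ex)
    return examples
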