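"""File contracts: event/outcome tables, run configs, encoded-example stores.

Events are long-format CSV or JSONL, one row per clinical record with
columns ``patient_id, date, modality, code, value`` (ISO-8601 dates) and an
optional ``birth_date`` column used for per-event age; when absent, ages
are counted from the first observed record. Outcomes are
``patient_id, disease, incident_date``. Run configuration is a single YAML
or JSON file with one section per concern; unknown keys are rejected so a
typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import pathlib
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import (CohortExample, EncodedSequence, MODALITIES,
                      PatientHistory, RecordEvent)

__all__ = [
    "read_events", "read_outcomes", "load_config", "write_manifest",
    "save_examples", "load_examples",
]


def _parse_date(s: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(s))
    except ValueError as e:
        raise ValueError(f"{where}: bad ISO-8601 date {s!r}") from e


def _events_frame(path: str | pathlib.Path) -> pd.DataFrame:
    path = pathlib.Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.strip():
                    try:
                        rows.append(json.loads(line))
                    except json.JSONDecodeError as e:
                        raise ValueError(f"{path}:{i}: malformed JSON") from e
        return pd.DataFrame(rows)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_events(path: str | pathlib.Path) -> list[PatientHistory]:
    """Parse an events file into validated, date-ordered patient histories."""
    df = _events_frame(path)
    required = {"patient_id", "date", "modality"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    histories: dict[str, list[tuple[int, RecordEvent]]] = {}
    births: dict[str, dt.date] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path}:{i}"
        modality = row.modality
        if modality not in MODALITIES:
            raise ValueError(f"{where}: unknown modality {modality!r}")
        date = _parse_date(row.date, where)
        code = getattr(row, "code", "") or None
        raw_value = getattr(row, "value", "")
        value = None
        if raw_value not in ("", None) and not (
                isinstance(raw_value, float) and np.isnan(raw_value)):
            try:
                value = float(raw_value)
            except (TypeError, ValueError) as e:
                raise ValueError(f"{where}: bad numeric value {raw_value!r}") from e
        try:
            ev = RecordEvent(date=date, modality=modality, code=code, value=value)
        except ValueError as e:
            raise ValueError(f"{where}: {e}") from e
        pid = str(row.patient_id)
        histories.setdefault(pid, []).append((i, ev))
        b = getattr(row, "birth_date", "")
        if b and pid not in births:
            births[pid] = _parse_date(b, where)
    out = []
    for pid, tagged in histories.items():
        # stable sort by date keeps same-day records in file order
        tagged.sort(key=lambda t: t[1].date)
        events = [ev for _, ev in tagged]
        birth = births.get(pid, events[0].date)
        h = PatientHistory(patient_id=pid, birth_date=birth, events=events)
        h.validate()
        out.append(h)
    return out


def read_outcomes(path: str | pathlib.Path,
                  histories: Sequence[PatientHistory] | None = None,
                  ) -> dict[str, dict[str, dt.date]]:
    """Outcome table -> {patient_id: {disease: incident_date}}.

    When `histories` is given, their `incident_dates` maps are filled in.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "disease", "incident_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    table: dict[str, dict[str, dt.date]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        date = _parse_date(row.incident_date, f"{path}:{i}")
        entry = table.setdefault(str(row.patient_id), {})
        if row.disease not in entry or date < entry[row.disease]:
            entry[row.disease] = date
    if histories is not None:
        for h in histories:
            if h.patient_id in table:
                h.incident_dates.update(table[h.patient_id])
    return table


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _reject_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"config section {section!r}: unknown key(s) {sorted(unknown)}")


_KNOWN_SECTIONS = {
    "paths", "cohort", "simulate", "model", "augmentation", "schedule",
    "pretrain", "seed",
}


def load_config(path: str | pathlib.Path) -> dict[str, Any]:
    """Load a YAML/JSON run config, rejecting unknown sections and keys."""
    text = pathlib.Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    _reject_unknown("<root>", cfg, _KNOWN_SECTIONS)
    from .byol import AugmentationConfig
    from .model import FlatModelConfig, HiModelConfig
    from .synthetic import SyntheticCohortParams
    from .train import ScheduleConfig
    field_names = lambda cls: {f.name for f in dataclasses.fields(cls)}
    if "simulate" in cfg:
        _reject_unknown("simulate", cfg["simulate"],
                        field_names(SyntheticCohortParams))
    if "model" in cfg:
        allowed = field_names(HiModelConfig) | field_names(FlatModelConfig)
        _reject_unknown("model", cfg["model"], allowed | {"kind", "profile"})
    if "augmentation" in cfg:
        _reject_unknown("augmentation", cfg["augmentation"],
                        field_names(AugmentationConfig))
    if "schedule" in cfg:
        _reject_unknown("schedule", cfg["schedule"], field_names(ScheduleConfig))
    if "pretrain" in cfg:
        _reject_unknown("pretrain", cfg["pretrain"],
                        {"steps", "batch_size", "lr", "tau"})
    if "cohort" in cfg:
        _reject_unknown("cohort", cfg["cohort"],
                        {"disease", "code_set", "data_end", "max_len"})
    return cfg


def write_manifest(out_dir: str | pathlib.Path, command: str,
                   config: dict[str, Any], seed: int | None) -> pathlib.Path:
    """Capture the full run configuration next to its outputs."""
    from . import __version__
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps(
        {"command": command, "config": config, "seed": seed,
         "package_version": __version__}, indent=2, default=str) + "\n")
    return path


# ---------------------------------------------------------------------------
# encoded-example store (single .npz per cohort)
# ---------------------------------------------------------------------------


def save_examples(examples: Sequence[CohortExample],
                  path: str | pathlib.Path) -> None:
    n = len(examples)
    if n == 0:
        raise ValueError("no examples to save")
    np.savez_compressed(
        path,
        token_ids=np.stack([e.encoded.token_ids for e in examples]),
        age_ids=np.stack([e.encoded.age_ids for e in examples]),
        segment_ids=np.stack([e.encoded.segment_ids for e in examples]),
        position_ids=np.stack([e.encoded.position_ids for e in examples]),
        attention_mask=np.stack([e.encoded.attention_mask for e in examples]),
        true_length=np.array([e.encoded.true_length for e in examples]),
        label=np.array([-1 if e.label is None else e.label for e in examples]),
        ehr_length=np.array([e.ehr_length for e in examples]),
        baseline=np.array([e.baseline_date.isoformat() for e in examples]),
        patient_id=np.array([e.patient_id for e in examples]),
    )


def load_examples(path: str | pathlib.Path) -> list[CohortExample]:
    with np.load(path, allow_pickle=False) as z:
        n = z["token_ids"].shape[0]
        out = []
        for i in range(n):
            enc = EncodedSequence(
                token_ids=z["token_ids"][i], age_ids=z["age_ids"][i],
                segment_ids=z["segment_ids"][i],
                position_ids=z["position_ids"][i],
                attention_mask=z["attention_mask"][i],
                true_length=int(z["true_length"][i]))
            label = int(z["label"][i])
            out.append(CohortExample(
                encoded=enc, label=None if label < 0 else label,
                baseline_date=dt.date.fromisoformat(str(z["baseline"][i])),
                ehr_length=int(z["ehr_length"][i]),
                patient_id=str(z["patient_id"][i])))
    return out
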