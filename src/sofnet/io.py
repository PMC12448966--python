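"""Delimited-text readers and writers binding the pipeline stages.

All tabular artifacts are UTF-8 CSV with headers; connectivity matrices carry
network-name header rows and columns so the feature order is self-describing.
Trial logs round-trip bit-exactly through ``write_trial_log`` /
``read_trial_log``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .connectome import ConnectivityMatrix, Parcellation
from .phenotype import Phenotype
from .task import TrialRecord

__all__ = [
    "TRIAL_LOG_HEADER",
    "read_trial_log",
    "write_trial_log",
    "read_matrix",
    "write_matrix",
    "read_parcellation",
    "write_parcellation",
    "write_phenotypes",
    "read_phenotypes",
    "write_json_report",
]

TRIAL_LOG_HEADER = ["participant", "item", "onset_s", "kind", "correct", "rt_s"]


class TrialLogError(ValueError):
    """Malformed or inconsistent trial log."""


def write_trial_log(records: Sequence[TrialRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(TRIAL_LOG_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.participant},{r.item},{r.onset!r},{r.kind},"
                f"{'true' if r.correct else 'false'},{r.rt!r}\n"
            )


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    """Parse and validate a trial log; onsets must strictly increase within
    each participant."""
    path = Path(path)
    records: list[TrialRecord] = []
    last_onset: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header != TRIAL_LOG_HEADER:
            raise TrialLogError(
                f"{path}: bad header {header}, expected {TRIAL_LOG_HEADER}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 6:
                raise TrialLogError(f"{path}:{lineno}: expected 6 fields")
            pid, item, onset_s, kind, correct_s, rt_s = fields
            if kind not in ("study", "test"):
                raise TrialLogError(
                    f"{path}:{lineno}: kind must be study/test, got {kind!r}"
                )
            if correct_s not in ("true", "false"):
                raise TrialLogError(
                    f"{path}:{lineno}: correct must be true/false, got {correct_s!r}"
                )
            try:
                onset, rt = float(onset_s), float(rt_s)
            except ValueError as exc:
                raise TrialLogError(f"{path}:{lineno}: {exc}") from None
            if pid in last_onset and onset <= last_onset[pid]:
                raise TrialLogError(
                    f"{path}:{lineno}: onsets not strictly increasing for {pid!r}"
                )
            last_onset[pid] = onset
            try:
                records.append(
                    TrialRecord(pid, item, onset, kind, correct_s == "true", rt)
                )
            except ValueError as exc:
                raise TrialLogError(f"{path}:{lineno}: {exc}") from None
    return records


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(path, index_label="network")


def read_matrix(path: str | Path, kind: str = "partial") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col="network")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column networks disagree")
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float),
        networks=tuple(df.columns),
        kind=kind,  # type: ignore[arg-type]
    )


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "networks": [
            {"name": n, "group": parcellation.groups[n]}
            for n in parcellation.networks
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_parcellation(path: str | Path) -> Parcellation:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    entries = payload["networks"]
    return Parcellation(
        networks=tuple(e["name"] for e in entries),
        groups={e["name"]: e["group"] for e in entries},
    )


def write_phenotypes(phenotypes: Sequence[Phenotype], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"participant": p.participant, "sof": p.sof, "n_items_used": p.n_items_used}
        for p in phenotypes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant", "sof"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_json_report(report: Mapping, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=default)
        fh.write("\n")
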