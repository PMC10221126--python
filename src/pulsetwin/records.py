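"""Raw signal records and dataset manifests.

A :class:`SignalRecord` is one single-channel pulse waveform with its
sampling rate and subject label.  Record files are deliberately simple —
one amplitude per line, optional single header line, UTF-8 — so that any
public PPG dump can be converted with a one-liner.  A manifest is a
delimited table mapping record files to subject labels and a train/test
split tag.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

_SPLITS = ("train", "test")


@dataclass(frozen=True)
class SignalRecord:
    """One raw single-channel waveform.

    Attributes
    ----------
    samples : amplitudes in file order (arbitrary units; raw PPG is
        strictly positive).
    sampling_rate_hz : sampling rate, > 0.
    subject_id, record_id : opaque labels.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    subject_id: str
    record_id: str

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError(f"record {self.record_id!r}: need >= 2 samples, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"record {self.record_id!r}: non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError(f"record {self.record_id!r}: sampling_rate_hz must be > 0")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    subject_id: str
    record_id: str
    split: str


@dataclass
class DatasetManifest:
    """Validated list of (record file, subject, record, split) entries."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for e in self.entries:
            if e.record_id in seen:
                raise ValueError(f"duplicate record_id {e.record_id!r} in manifest")
            seen.add(e.record_id)
            if e.split not in _SPLITS:
                raise ValueError(f"record {e.record_id!r}: unknown split {e.split!r} (expected train/test)")

    def split(self, tag: str) -> list[ManifestEntry]:
        if tag not in _SPLITS:
            raise ValueError(f"unknown split {tag!r}")
        return [e for e in self.entries if e.split == tag]

    def subjects(self, tag: str | None = None) -> list[str]:
        pool = self.entries if tag is None else self.split(tag)
        return sorted({e.subject_id for e in pool})

    def __len__(self) -> int:
        return len(self.entries)


def read_record(path: str | os.PathLike, sampling_rate_hz: float,
                subject_id: str = "", record_id: str = "") -> SignalRecord:
    """Read one record file: one numeric value per line, optional header.

    The first line may be a non-numeric header and is then skipped; every
    remaining non-blank line must parse as a single float (the first column
    of delimited text is used, extra columns are rejected only if the first
    token is non-numeric).
    """
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise OSError(f"cannot read record file {path}: {exc}") from exc
    values: list[float] = []
    for i, line in enumerate(lines):
        token = line.split(",")[0].split()[0] if line.strip() else ""
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError:
            if i == 0 and not values:  # tolerated header line
                continue
            raise ValueError(f"{path}:{i + 1}: non-numeric value {token!r}") from None
    if len(values) < 2:
        raise ValueError(f"{path}: fewer than 2 numeric samples")
    rid = record_id or path.stem
    return SignalRecord(np.asarray(values), sampling_rate_hz, subject_id, rid)


def write_record(record: SignalRecord, path: str | os.PathLike) -> None:
    """Write one amplitude per line with full float precision (round-trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for v in record.samples:
            fh.write(format(float(v), ".17g") + "\n")


def load_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Load a manifest table with columns ``path, subject, record, split``.

    Paths are resolved relative to the manifest's directory.  Raises on
    duplicate record ids, unknown split tags, or unresolvable files.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"path", "subject", "record", "split"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    base = path.parent
    entries = []
    for row in table.itertuples(index=False):
        rec_path = base / str(row.path)
        if not rec_path.is_file():
            raise FileNotFoundError(f"{path}: record file {rec_path} not found")
        entries.append(ManifestEntry(rec_path, str(row.subject), str(row.record), str(row.split)))
    return DatasetManifest(entries)


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    """Write a manifest as TSV with paths relative to the manifest location."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent
    rows = []
    for e in manifest.entries:
        rel = os.path.relpath(e.path, base)
        rows.append({"path": rel, "subject": e.subject_id, "record": e.record_id, "split": e.split})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def manifest_records(manifest: DatasetManifest, sampling_rate_hz: float,
                     split: str | None = None) -> list[SignalRecord]:
    """Read every record file referenced by the manifest (optionally one split)."""
    entries = manifest.entries if split is None else manifest.split(split)
    return [read_record(e.path, sampling_rate_hz, e.subject_id, e.record_id) for e in entries]
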