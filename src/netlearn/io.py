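"""Reading and writing EEG recordings, task schedules and behavioral tables.

Two on-disk dialects are supported for recordings:

* **EDF** (European Data Format, 16-bit): read through :mod:`mne`; a minimal
  writer is included so synthetic cohorts can be stored in the same format a
  clinical amplifier would produce.  Non-integer sampling rates (the study
  hardware ran at 254.31 Hz) are handled by sizing one data record to 100 s,
  which makes the samples-per-record integral.
* a plain-text channel-matrix dialect: headerless CSV, one row per channel,
  plus a JSON sidecar ``{"fs": ..., "labels": [...], "reference": ...}`` with
  the same stem.  This keeps small fixtures human-readable and diffable.

Electro-oculogram channels (labels starting with ``EOG``) are recorded
alongside the scalp EEG but are never network nodes; ``read_recording`` strips
them and remembers their labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    BoundsError,
    DegenerateInputError,
    FormatError,
    LookupError_,
)

__all__ = [
    "Recording",
    "TaskSchedule",
    "SubjectRecord",
    "read_recording",
    "write_recording",
    "extract_segment",
    "read_schedule",
    "write_schedule",
    "read_behavior",
    "write_behavior",
]

#: number of words presented per learning list; recall counts cannot exceed it
WORD_LIST_LENGTH = 15

EOG_PREFIX = "EOG"


@dataclass
class Recording:
    """A multichannel EEG recording (or a segment of one).

    Attributes
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    fs
        Sampling rate in Hz (may be non-integer; the study used 254.31 Hz).
    channel_labels
        Unique electrode names (10-20 nomenclature), one per row of ``data``.
    reference
        Label of the physical reference electrode ("RM" = right mastoid in
        the study design), or ``""`` when unknown.
    excluded_labels
        Labels of channels (EOG) removed from the node set at read time.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference: str = ""
    excluded_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DegenerateInputError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise DegenerateInputError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise DegenerateInputError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DegenerateInputError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TaskSchedule:
    """Ordered task markers: ``(label, onset_s, duration_s)`` triples."""

    entries: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_end = -math.inf
        prev_onset = -math.inf
        for label, onset, dur in self.entries:
            if dur <= 0:
                raise DegenerateInputError(f"task {label!r} has non-positive duration {dur}")
            if onset < prev_onset:
                raise DegenerateInputError("task onsets must be non-decreasing")
            if onset < prev_end - 1e-9:
                raise DegenerateInputError(f"task {label!r} overlaps the previous segment")
            prev_onset, prev_end = onset, onset + dur

    def lookup(self, label: str) -> tuple[float, float]:
        """Return ``(onset_s, duration_s)`` of the first entry with ``label``."""
        for lab, onset, dur in self.entries:
            if lab == label:
                return onset, dur
        raise LookupError_(f"task label {label!r} not in schedule "
                           f"(have {[e[0] for e in self.entries]})")

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]


@dataclass
class SubjectRecord:
    """Behavioral row: recall counts for the two free-recall tasks.

    ``recall_incidental`` is the number of correctly retrieved words after the
    incidental learning task (block 1), ``recall_intentional`` after the
    intentional task (block 2); both are capped by the 15-word list length.
    """

    subject_id: str
    group: str  # "control" | "patient"
    recall_incidental: int
    recall_intentional: int

    def __post_init__(self) -> None:
        for name in ("recall_incidental", "recall_intentional"):
            v = getattr(self, name)
            if not (0 <= v <= WORD_LIST_LENGTH):
                raise DegenerateInputError(
                    f"{name}={v} outside 0..{WORD_LIST_LENGTH}")
        if self.group not in ("control", "patient"):
            raise DegenerateInputError(f"unknown group {self.group!r}")


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def read_recording(path: str | Path) -> Recording:
    """Read an EEG recording from EDF or the plain-text channel-matrix dialect.

    EOG channels are excluded from the node set (their labels are kept in
    :attr:`Recording.excluded_labels`).  Raises :class:`FormatError` for
    unreadable files and :class:`DegenerateInputError` when fewer than three
    node channels remain.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        data, fs, labels, reference = _read_edf(path)
    else:
        data, fs, labels, reference = _read_csv_dialect(path)
    keep = [i for i, lab in enumerate(labels) if not lab.upper().startswith(EOG_PREFIX)]
    excluded = [lab for lab in labels if lab.upper().startswith(EOG_PREFIX)]
    rec = Recording(
        data=data[keep],
        fs=fs,
        channel_labels=[labels[i] for i in keep],
        reference=reference,
        excluded_labels=excluded,
    )
    if rec.n_channels < 3:
        raise DegenerateInputError(
            f"{rec.n_channels} node channels in {path.name}; need at least 3")
    return rec


def _read_csv_dialect(path: Path) -> tuple[np.ndarray, float, list[str], str]:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"channel-matrix dialect needs a JSON sidecar: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except (ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    labels = list(meta["labels"])
    if data.shape[0] != len(labels):
        raise FormatError(
            f"{path.name}: {data.shape[0]} rows but {len(labels)} labels in sidecar")
    return data, float(meta["fs"]), labels, str(meta.get("reference", ""))


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str], str]:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises bare ValueError/OSError on bad files
        raise FormatError(f"cannot parse EDF {path.name}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts; we store microvolts
    reference = _edf_reference_field(path)
    return data, float(raw.info["sfreq"]), list(raw.ch_names), reference


def _edf_reference_field(path: Path) -> str:
    # the writer stashes "ref=<label>" in the 80-byte recording-id field
    with open(path, "rb") as fh:
        fh.seek(88)
        rec_id = fh.read(80).decode("ascii", errors="replace")
    for token in rec_id.split():
        if token.startswith("ref="):
            return token[4:]
    return ""


def write_recording(rec: Recording, path: str | Path,
                    physical_range_uv: float = 3276.7) -> Path:
    """Write a recording in the dialect implied by the file suffix.

    ``.edf`` writes 16-bit EDF (quantization step ``physical_range_uv/32767``
    microvolts, 0.1 µV at the default range); anything else writes the
    channel-matrix CSV plus its JSON sidecar.  EOG channels that were excluded
    at read time are *not* resurrected — what you hold is what is written.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path, physical_range_uv)
    else:
        np.savetxt(path, rec.data, delimiter=",", fmt="%.6f")
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"fs": rec.fs, "labels": rec.channel_labels, "reference": rec.reference},
            indent=1))
    return path


def _edf_record_duration(fs: float) -> float:
    # smallest duration in a fixed ladder giving an integer samples-per-record
    for d in (1.0, 2.0, 4.0, 5.0, 10.0, 20.0, 50.0, 100.0):
        if abs(fs * d - round(fs * d)) < 1e-6:
            return d
    raise FormatError(f"sampling rate {fs} not representable in EDF records up to 100 s")


def _write_edf(rec: Recording, path: Path, physical_range_uv: float) -> None:
    nch = rec.n_channels
    rec_dur = _edf_record_duration(rec.fs)
    spr = int(round(rec.fs * rec_dur))
    ndr = rec.n_samples // spr
    if ndr == 0:
        raise DegenerateInputError(
            f"recording shorter than one EDF data record ({rec_dur} s at fs={rec.fs})")
    pmin, pmax = -physical_range_uv, physical_range_uv
    dmin, dmax = -32768, 32767

    def fld(values, width):
        out = b""
        for v in values:
            s = str(v).encode("ascii")[:width]
            out += s.ljust(width)
        return out

    hdr = b"0".ljust(8)                                    # version
    hdr += b"X X X X".ljust(80)                            # patient id
    hdr += (f"Startdate X ref={rec.reference or 'X'}".encode()).ljust(80)[:80]
    hdr += b"01.01.01" + b"00.00.00"
    hdr += str(256 * (nch + 1)).encode().ljust(8)          # header bytes
    hdr += b"".ljust(44)                                   # reserved
    hdr += str(ndr).encode().ljust(8)
    hdr += (f"{rec_dur:g}".encode()).ljust(8)
    hdr += str(nch).encode().ljust(4)
    hdr += fld(rec.channel_labels, 16)
    hdr += fld(["EEG"] * nch, 80)                          # transducer
    hdr += fld(["uV"] * nch, 8)
    hdr += fld([f"{pmin:g}"] * nch, 8)
    hdr += fld([f"{pmax:g}"] * nch, 8)
    hdr += fld([dmin] * nch, 8)
    hdr += fld([dmax] * nch, 8)
    hdr += fld([""] * nch, 80)                             # prefiltering
    hdr += fld([spr] * nch, 8)
    hdr += fld([""] * nch, 32)                             # reserved

    clipped = np.clip(rec.data, pmin, pmax)
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((clipped - pmin) / scale + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(ndr):
            fh.write(np.ascontiguousarray(digital[:, r * spr:(r + 1) * spr]).tobytes())


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def extract_segment(rec: Recording, sched: TaskSchedule, label: str) -> Recording:
    """Slice out one task segment.

    Onset and offset map to sample indices by round-half-even; the segment is
    the half-open index range ``[round(onset*fs), round((onset+duration)*fs))``.
    """
    onset, dur = sched.lookup(label)
    start = _round_half_even(onset * rec.fs)
    stop = _round_half_even((onset + dur) * rec.fs)
    if start < 0 or stop > rec.n_samples:
        raise BoundsError(
            f"task {label!r} spans samples [{start}, {stop}) but recording has "
            f"{rec.n_samples}")
    return Recording(
        data=rec.data[:, start:stop].copy(),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        reference=rec.reference,
        excluded_labels=list(rec.excluded_labels),
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_schedule(path: str | Path) -> TaskSchedule:
    """Read a task-marker CSV with header ``onset_s,duration_s,label``."""
    try:
        df = pd.read_csv(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse schedule {path}: {exc}") from exc
    missing = {"onset_s", "duration_s", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"schedule {path} lacks columns {sorted(missing)}")
    entries = [(str(r.label), float(r.onset_s), float(r.duration_s))
               for r in df.itertuples()]
    return TaskSchedule(entries)


def write_schedule(sched: TaskSchedule, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"onset_s": o, "duration_s": d, "label": l} for l, o, d in sched.entries]
    ).to_csv(path, index=False)
    return path


def read_behavior(path: str | Path) -> list[SubjectRecord]:
    """Read the behavioral table ``subject_id,group,recall_incidental,recall_intentional``."""
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse behavior table {path}: {exc}") from exc
    needed = {"subject_id", "group", "recall_incidental", "recall_intentional"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"behavior table {path} lacks columns {sorted(missing)}")
    return [
        SubjectRecord(str(r.subject_id), str(r.group),
                      int(r.recall_incidental), int(r.recall_intentional))
        for r in df.itertuples()
    ]


def write_behavior(records: Sequence[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group,
          "recall_incidental": r.recall_incidental,
          "recall_intentional": r.recall_intentional} for r in records]
    ).to_csv(path, index=False)
    return path
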