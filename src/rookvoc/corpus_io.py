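"""Reading and writing of annotated vocal-unit corpora.

A *vocal unit* is a single vocalization corresponding to one continuous
trace on the spectrogram; annotations give its time interval, the emitting
individual and (optionally) a perceptual type tag and behavioural context.
Units are classified as *song* units when they occur inside a song — a
same-individual run of at least ``min_units`` units of at least
``min_types`` perceptually different types with gaps shorter than
``max_gap_s`` between successive units — and as *call* units otherwise.

Annotations are exchanged as Audacity label tracks (TSV: start, end,
label) and as a flat unit-table CSV; audio is 48 kHz PCM WAV.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

EXPECTED_SAMPLE_RATE = 48_000

#: Label convention "Individual[;type][;context]" (semicolon-separated).
DEFAULT_LABEL_PATTERN = re.compile(
    r"^(?P<individual>[^;]+?)\s*(?:;\s*(?P<type_tag>[^;]*?)\s*)?(?:;\s*(?P<context>[^;]*?)\s*)?$"
)

#: Mandatory columns of the unit-table CSV.
UNIT_TABLE_COLUMNS = [
    "unit_id",
    "recording_id",
    "start_s",
    "end_s",
    "individual",
    "sex",
    "colony",
    "unit_type",
    "type_tag",
    "context",
    "identified",
    "overlapped",
]


class LabelParseError(ValueError):
    """A label-track line could not be parsed; message names the line."""


class SchemaError(ValueError):
    """A tabular input is missing mandatory columns."""


@dataclass
class VocalUnitRecord:
    """One annotated vocalization.

    Times are seconds; the interval is half-open ``[start_s, end_s)``.
    ``unit_type`` is ``"unassigned"`` until :func:`classify_call_vs_song`
    resolves it to ``"call"`` or ``"song"``. ``type_tag`` is the
    human-perceptual (or synthetic ground-truth) unit type used by the
    song rule; it is never inferred acoustically.
    """

    unit_id: str
    recording_id: str
    start_s: float
    end_s: float
    individual: str
    sex: str = ""
    colony: str = ""
    unit_type: str = "unassigned"
    type_tag: str = ""
    context: str | None = None
    channel_count: int = 1
    identified: bool = True
    overlapped: bool = False

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"unit {self.unit_id!r}: start_s must be >= 0, got {self.start_s}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"unit {self.unit_id!r}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )
        if self.unit_type not in ("call", "song", "unassigned"):
            raise ValueError(f"unit {self.unit_id!r}: bad unit_type {self.unit_type!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Corpus:
    """An ordered collection of vocal-unit records plus an audio index."""

    records: list[VocalUnitRecord]
    audio_index: dict[str, Path] = field(default_factory=dict)
    sample_rate: int = EXPECTED_SAMPLE_RATE

    def __post_init__(self) -> None:
        ids = [r.unit_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate unit_id(s): {dup[:5]}")
        if self.audio_index:
            missing = {r.recording_id for r in self.records} - set(self.audio_index)
            if missing:
                raise ValueError(f"recording_id(s) without audio: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.records)


def read_label_track(
    path: str | Path,
    recording_id: str,
    label_pattern: re.Pattern[str] = DEFAULT_LABEL_PATTERN,
) -> list[VocalUnitRecord]:
    """Parse an Audacity label track (TSV ``start<TAB>end<TAB>label``).

    The label encodes ``Individual[;type][;context]``. Returned records
    have ``unit_type="unassigned"``. Raises :class:`LabelParseError`
    naming the offending line on malformed input.
    """
    records: list[VocalUnitRecord] = []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LabelParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        try:
            start_s, end_s = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: unparseable time: {exc}") from exc
        m = label_pattern.match(parts[2].strip())
        if m is None or not m.group("individual"):
            raise LabelParseError(f"{path}:{lineno}: label {parts[2]!r} does not match convention")
        groups = m.groupdict()
        try:
            records.append(
                VocalUnitRecord(
                    unit_id=f"{recording_id}#{lineno}",
                    recording_id=recording_id,
                    start_s=start_s,
                    end_s=end_s,
                    individual=groups["individual"].strip(),
                    type_tag=(groups.get("type_tag") or "").strip(),
                    context=(groups.get("context") or "").strip() or None,
                )
            )
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_label_track(records: list[VocalUnitRecord], path: str | Path) -> None:
    """Write records as an Audacity label track (inverse of the reader)."""
    lines = []
    for r in sorted(records, key=lambda r: r.start_s):
        label = r.individual
        if r.type_tag or r.context:
            label += f";{r.type_tag}"
        if r.context:
            label += f";{r.context}"
        lines.append(f"{r.start_s:.6f}\t{r.end_s:.6f}\t{label}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_audio(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file as float waveform shaped (channels, samples).

    Integer PCM is scaled to [-1, 1). A sample rate other than 48 kHz is
    reported with a warning but never silently resampled.
    """
    try:
        sr, data = wavfile.read(str(path))
    except Exception as exc:  # wavfile raises assorted ValueError/OSError
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.dtype.kind == "i":
        wave = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        wave = (data.astype(np.float64) - 128.0) / 128.0
    else:
        wave = data.astype(np.float64)
    wave = wave.T if wave.ndim == 2 else wave[np.newaxis, :]
    if sr != EXPECTED_SAMPLE_RATE:
        warnings.warn(
            f"{path}: sample rate {sr} Hz differs from expected {EXPECTED_SAMPLE_RATE} Hz",
            stacklevel=2,
        )
    return wave, sr


def write_audio(path: str | Path, wave: np.ndarray, sample_rate: int = EXPECTED_SAMPLE_RATE) -> None:
    """Write a (channels, samples) float waveform as 16-bit PCM WAV."""
    wave = np.atleast_2d(np.asarray(wave, dtype=np.float64))
    peak = np.max(np.abs(wave)) if wave.size else 0.0
    if peak > 1.0:
        wave = wave / peak
    pcm = np.round(wave * 32767.0).astype(np.int16)
    wavfile.write(str(path), sample_rate, pcm.T.squeeze())


def classify_call_vs_song(
    records: list[VocalUnitRecord],
    min_units: int = 5,
    min_types: int = 2,
    max_gap_s: float = 10.0,
) -> list[VocalUnitRecord]:
    """Label every unit ``song`` or ``call`` by the song rule.

    A song is a maximal same-individual run of units with successive gaps
    strictly below ``max_gap_s`` containing at least ``min_units`` units
    of at least ``min_types`` distinct type tags; all units in such runs
    become song units, everything else a call unit. Input order is
    preserved; the input list is not mutated.
    """
    if min_types > 1 and any(not r.type_tag for r in records):
        missing = [r.unit_id for r in records if not r.type_tag][:5]
        raise ValueError(f"type_tag required for song classification; missing on {missing}")

    out = list(records)
    index_by_id = {r.unit_id: i for i, r in enumerate(out)}
    by_individual: dict[str, list[VocalUnitRecord]] = {}
    for r in records:
        by_individual.setdefault(r.individual, []).append(r)

    for recs in by_individual.values():
        recs = sorted(recs, key=lambda r: (r.start_s, r.unit_id))
        runs: list[list[VocalUnitRecord]] = [[recs[0]]] if recs else []
        for prev, cur in zip(recs, recs[1:]):
            gap = cur.start_s - prev.end_s
            if gap < max_gap_s:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            is_song = len(run) >= min_units and len({r.type_tag for r in run}) >= min_types
            label = "song" if is_song else "call"
            for r in run:
                out[index_by_id[r.unit_id]] = replace(r, unit_type=label)
    return out


def filter_analysable(records: list[VocalUnitRecord]) -> list[VocalUnitRecord]:
    """Keep units from identified individuals that do not overlap other sounds."""
    kept = [r for r in records if r.identified and not r.overlapped]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_analysable: removed %d of %d units", removed, len(records))
    if records and not kept:
        warnings.warn("filter_analysable: no analysable units remain", stacklevel=2)
    return kept


def write_unit_table(records: list[VocalUnitRecord], path: str | Path) -> None:
    """Persist records as the unit-table CSV (one row per unit)."""
    rows = [
        {
            "unit_id": r.unit_id,
            "recording_id": r.recording_id,
            "start_s": r.start_s,
            "end_s": r.end_s,
            "individual": r.individual,
            "sex": r.sex,
            "colony": r.colony,
            "unit_type": r.unit_type,
            "type_tag": r.type_tag,
            "context": "" if r.context is None else r.context,
            "identified": r.identified,
            "overlapped": r.overlapped,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=UNIT_TABLE_COLUMNS).to_csv(path, index=False)


def read_unit_table(path: str | Path, audio_index: dict[str, Path] | None = None) -> Corpus:
    """Read a unit-table CSV back into a :class:`Corpus`.

    Raises :class:`SchemaError` if any mandatory column is absent.
    """
    df = pd.read_csv(path, dtype={"context": "string"}, keep_default_na=False, na_values=[""])
    missing = [c for c in UNIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        context = None if pd.isna(row.context) else str(row.context)
        records.append(
            VocalUnitRecord(
                unit_id=str(row.unit_id),
                recording_id=str(row.recording_id),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                individual="" if pd.isna(row.individual) else str(row.individual),
                sex="" if pd.isna(row.sex) else str(row.sex),
                colony="" if pd.isna(row.colony) else str(row.colony),
                unit_type=str(row.unit_type),
                type_tag="" if pd.isna(row.type_tag) else str(row.type_tag),
                context=context,
                identified=bool(row.identified),
                overlapped=bool(row.overlapped),
            )
        )
    return Corpus(records=records, audio_index=audio_index or {})
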