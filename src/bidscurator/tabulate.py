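"""Tabulation of DICOM-header sequence information.

Each acquisition's stored ``dicom_header`` record is flattened into one
:class:`SeqInfo` row — the unit the heuristic rule engine classifies —
and rows are compiled into a project-wide table that users inspect to
write their heuristics.  Tabulation is strictly read-only on the store.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from .datastore import DICOM_HEADER_NS, ProjectRecord, SessionRecord, select_sessions

logger = logging.getLogger(__name__)

#: fixed column order of the sequence table
SEQINFO_COLUMNS = (
    "series_id",
    "subject_label",
    "session_label",
    "series_number",
    "series_description",
    "protocol_name",
    "sequence_name",
    "image_type",
    "repetition_time",
    "echo_time",
    "dim1",
    "dim2",
    "dim3",
    "dim4",
    "series_files",
)

#: DICOM-header key for each SeqInfo field (TR/TE are stored in ms)
_HEADER_KEYS = {
    "series_number": "SeriesNumber",
    "series_description": "SeriesDescription",
    "protocol_name": "ProtocolName",
    "sequence_name": "SequenceName",
    "image_type": "ImageType",
    "repetition_time": "RepetitionTime",
    "echo_time": "EchoTime",
    "dim1": "Rows",
    "dim2": "Columns",
    "dim3": "Slices",
    "dim4": "NumberOfTemporalPositions",
    "series_files": "SeriesFiles",
}

#: fields forming the deduplication key in unique mode: the acquisition
#: parameters a heuristic typically branches on, excluding per-subject
#: identity fields
UNIQUE_KEY_FIELDS = (
    "series_description",
    "protocol_name",
    "sequence_name",
    "image_type",
    "repetition_time",
    "echo_time",
    "dim1",
    "dim2",
    "dim3",
    "dim4",
)


@dataclass(frozen=True)
class SeqInfo:
    """One acquisition's header-derived sequence description.

    ``series_id`` is ``<subject>_<session>_<series_number>`` so that
    heuristic assignments are reproducible across runs.  Times are in
    seconds; missing numeric header fields stay ``None`` (serialized as
    empty string) to avoid spurious dedup collisions.
    """

    series_id: str
    subject_label: str
    session_label: str
    series_number: int
    series_description: str = ""
    protocol_name: str = ""
    sequence_name: str = ""
    image_type: tuple[str, ...] = ()
    repetition_time: float | None = None
    echo_time: float | None = None
    dim1: int | None = None
    dim2: int | None = None
    dim3: int | None = None
    dim4: int | None = None
    series_files: int = 1

    def unique_key(self) -> tuple:
        return tuple(getattr(self, f) for f in UNIQUE_KEY_FIELDS)


def _ms_to_s(value) -> float | None:
    return None if value is None else float(value) / 1000.0


def extract_seqinfo(session: SessionRecord) -> list[SeqInfo]:
    """One SeqInfo per acquisition holding a ``dicom_header`` record.

    Acquisitions without a DICOM header are skipped with a warning.
    """
    subject = session.subject_label or ""
    rows: list[SeqInfo] = []
    for acq in session.acquisitions:
        dicom = acq.dicom_file
        header = dicom.info.get(DICOM_HEADER_NS) if dicom is not None else None
        if header is None:
            logger.warning(
                "acquisition %r in session %r has no DICOM header; skipped",
                acq.label, session.label,
            )
            continue
        series_number = int(header.get("SeriesNumber", len(rows) + 1))
        image_type = header.get("ImageType", [])
        if isinstance(image_type, str):
            image_type = [image_type]
        rows.append(
            SeqInfo(
                series_id=f"{subject}_{session.label}_{series_number}",
                subject_label=subject,
                session_label=session.label,
                series_number=series_number,
                series_description=str(header.get("SeriesDescription", "")),
                protocol_name=str(header.get("ProtocolName", "")),
                sequence_name=str(header.get("SequenceName", "")),
                image_type=tuple(image_type),
                repetition_time=_ms_to_s(header.get("RepetitionTime")),
                echo_time=_ms_to_s(header.get("EchoTime")),
                dim1=header.get("Rows"),
                dim2=header.get("Columns"),
                dim3=header.get("Slices"),
                dim4=header.get("NumberOfTemporalPositions"),
                series_files=int(header.get("SeriesFiles", 1)),
            )
        )
    return rows


def tabulate_project(
    project: ProjectRecord,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
    unique: bool = False,
) -> list[SeqInfo]:
    """Compile SeqInfo rows over the selected sessions.

    ``unique=True`` keeps the first-seen row per distinct acquisition
    parameter key (see :data:`UNIQUE_KEY_FIELDS`) — the view used when
    drafting a heuristic; ``unique=False`` keeps one row per acquisition.
    """
    rows: list[SeqInfo] = []
    for ses in select_sessions(project, subject_labels, session_labels):
        rows.extend(extract_seqinfo(ses))
    if unique:
        seen: set[tuple] = set()
        deduped = []
        for row in rows:
            key = row.unique_key()
            if key not in seen:
                seen.add(key)
                deduped.append(row)
        rows = deduped
    return rows


def to_dataframe(table: list[SeqInfo]) -> pd.DataFrame:
    """Sequence table as a DataFrame in the fixed column order.

    ``image_type`` lists are joined with ``_``; missing numerics become
    empty strings so the TSV round-trips without inventing zeros.
    """
    records = []
    for row in table:
        rec = {f.name: getattr(row, f.name) for f in fields(SeqInfo)}
        rec["image_type"] = "_".join(rec["image_type"])
        for key, value in rec.items():
            if value is None:
                rec[key] = ""
        records.append(rec)
    return pd.DataFrame(records, columns=list(SEQINFO_COLUMNS))


def write_seq_table(table: list[SeqInfo], path: str | Path) -> Path:
    """Write the table as TSV: header row first, one line per SeqInfo."""
    path = Path(path)
    to_dataframe(table).to_csv(path, sep="\t", index=False)
    return path


def read_seq_table(path: str | Path) -> list[SeqInfo]:
    """Read back a TSV written by :func:`write_seq_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for _, rec in df.iterrows():
        def num(key, cast):
            return cast(rec[key]) if rec[key] != "" else None

        rows.append(
            SeqInfo(
                series_id=rec["series_id"],
                subject_label=rec["subject_label"],
                session_label=rec["session_label"],
                series_number=int(rec["series_number"]),
                series_description=rec["series_description"],
                protocol_name=rec["protocol_name"],
                sequence_name=rec["sequence_name"],
                image_type=tuple(rec["image_type"].split("_")) if rec["image_type"] else (),
                repetition_time=num("repetition_time", float),
                echo_time=num("echo_time", float),
                dim1=num("dim1", int),
                dim2=num("dim2", int),
                dim3=num("dim3", int),
                dim4=num("dim4", int),
                series_files=int(rec["series_files"]),
            )
        )
    return rows
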