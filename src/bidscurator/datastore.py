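"""Backend-independent model and persistence of an imaging project hierarchy.

The store mirrors the container model used by hosted imaging databases:
a project holds subjects, subjects hold sessions, sessions hold
acquisitions, and every container can carry files, free-form metadata,
and attached analysis records.  Instead of a remote database the
hierarchy is persisted as a mirrored directory tree of JSON documents —
one index document per container — with file payloads stored next to
their container:

.. code-block:: text

    <root>/project.json
    <root>/files/<name>
    <root>/analyses/<NNN>_<label>.json
    <root>/subjects/<label>/subject.json
    <root>/subjects/<label>/sessions/<label>/session.json
    <root>/subjects/<label>/sessions/<label>/acquisitions/<label>/acquisition.json

The layout is human-inspectable and diff-friendly; saving is canonical
(stable key order, trailing newline) so identical records always produce
byte-identical stores.

Two metadata namespaces on files are special: ``dicom_header`` holds the
scanner-derived header record and is immutable, and ``BIDS`` holds the
curated BIDS identity and is absent until curation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path, PurePosixPath
from typing import Iterator

from .errors import ImmutableMetadataError, IntegrityError, NotFoundError, StoreError

logger = logging.getLogger(__name__)

DICOM_HEADER_NS = "dicom_header"
BIDS_NS = "BIDS"

FILE_KINDS = ("dicom", "nifti", "tabular", "text", "other")


def _check_label(label: str) -> str:
    if not label or "/" in label or label.startswith("."):
        raise IntegrityError(f"invalid container label: {label!r}")
    return label


@dataclass
class FileRecord:
    """A file attached to a container.

    ``info`` is an open string→value map; ``content_ref`` points to the
    payload relative to the store root (``None`` for metadata-only
    records, e.g. DICOM header stubs without payload bytes).  ``payload``
    holds in-memory bytes not yet persisted; it is never serialized.
    """

    name: str
    kind: str = "other"
    info: dict = field(default_factory=dict)
    content_ref: str | None = None
    payload: bytes | None = None

    def __post_init__(self) -> None:
        if self.kind not in FILE_KINDS:
            raise IntegrityError(f"unknown file kind {self.kind!r} for {self.name!r}")

    def to_doc(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "info": self.info,
            "content_ref": self.content_ref,
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "FileRecord":
        return cls(
            name=doc["name"],
            kind=doc["kind"],
            info=doc.get("info", {}),
            content_ref=doc.get("content_ref"),
        )


def _parse_ts(value: str) -> datetime:
    dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt


@dataclass
class AnalysisRecord:
    """A recorded pipeline ("gear") run attached to any container."""

    label: str
    gear_name: str
    gear_version: str
    status: str  # "complete" | "failed"
    started: str  # ISO-8601 UTC
    finished: str
    parent_ref: str = ""
    runtime_seconds: float | None = None
    outputs: list[FileRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in ("complete", "failed"):
            raise IntegrityError(f"analysis {self.label!r}: bad status {self.status!r}")
        if self.runtime_seconds is None:
            delta = _parse_ts(self.finished) - _parse_ts(self.started)
            self.runtime_seconds = delta.total_seconds()
        if self.runtime_seconds < 0:
            raise IntegrityError(f"analysis {self.label!r}: negative runtime")

    def to_doc(self) -> dict:
        return {
            "label": self.label,
            "gear_name": self.gear_name,
            "gear_version": self.gear_version,
            "status": self.status,
            "started": self.started,
            "finished": self.finished,
            "parent_ref": self.parent_ref,
            "runtime_seconds": self.runtime_seconds,
            "outputs": [f.to_doc() for f in self.outputs],
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "AnalysisRecord":
        return cls(
            label=doc["label"],
            gear_name=doc["gear_name"],
            gear_version=doc["gear_version"],
            status=doc["status"],
            started=doc["started"],
            finished=doc["finished"],
            parent_ref=doc.get("parent_ref", ""),
            runtime_seconds=doc.get("runtime_seconds"),
            outputs=[FileRecord.from_doc(d) for d in doc.get("outputs", [])],
        )


@dataclass
class _Container:
    label: str
    metadata: dict = field(default_factory=dict)
    files: list[FileRecord] = field(default_factory=list)
    analyses: list[AnalysisRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_label(self.label)

    def get_file(self, name: str) -> FileRecord:
        for f in self.files:
            if f.name == name:
                return f
        raise NotFoundError(f"no file {name!r} in container {self.label!r}")

    def _check_file_names(self, path: str) -> None:
        names = [f.name for f in self.files]
        if len(names) != len(set(names)):
            raise IntegrityError(f"duplicate file names in container {path or '<project>'}")


@dataclass
class AcquisitionRecord(_Container):
    """One scanning-sequence instance: at most one DICOM file plus NIfTIs."""

    def __post_init__(self) -> None:
        super().__post_init__()
        n_dicom = sum(1 for f in self.files if f.kind == "dicom")
        if n_dicom > 1:
            raise IntegrityError(f"acquisition {self.label!r} holds {n_dicom} DICOM files")

    @property
    def dicom_file(self) -> FileRecord | None:
        for f in self.files:
            if f.kind == "dicom":
                return f
        return None

    @property
    def nifti_files(self) -> list[FileRecord]:
        return [f for f in self.files if f.kind == "nifti"]


@dataclass
class SessionRecord(_Container):
    acquisitions: list[AcquisitionRecord] = field(default_factory=list)
    #: label of the owning subject; maintained by selection/walk helpers,
    #: never serialized
    subject_label: str | None = None


@dataclass
class SubjectRecord(_Container):
    sessions: list[SessionRecord] = field(default_factory=list)


@dataclass
class ProjectRecord(_Container):
    subjects: list[SubjectRecord] = field(default_factory=list)
    #: root directory of the persisted store; set by load/save, not serialized
    root: Path | None = None

    # -- addressing ---------------------------------------------------

    def container_path(self, *labels: str) -> str:
        """Build a container path from subject[/session[/acquisition]] labels."""
        parts = []
        for level, label in zip(("subjects", "sessions", "acquisitions"), labels):
            parts += [level, label]
        return "/".join(parts)

    def resolve(self, ref: str) -> _Container:
        """Resolve a container path like ``subjects/S/sessions/X`` ("" = project)."""
        if ref in ("", "."):
            return self
        parts = PurePosixPath(ref).parts
        node: _Container = self
        levels = {"subjects": "subjects", "sessions": "sessions", "acquisitions": "acquisitions"}
        i = 0
        while i < len(parts):
            kind = parts[i]
            if kind not in levels or i + 1 >= len(parts):
                raise NotFoundError(f"malformed container path {ref!r}")
            label = parts[i + 1]
            children = getattr(node, levels[kind], None)
            if children is None:
                raise NotFoundError(f"container path {ref!r} descends below the hierarchy")
            for child in children:
                if child.label == label:
                    node = child
                    break
            else:
                raise NotFoundError(f"no container {label!r} under {kind} (path {ref!r})")
            i += 2
        return node

    def walk(self) -> Iterator[tuple[str, _Container]]:
        """Yield (container_path, container) in store order, project first."""
        yield "", self
        for sub in self.subjects:
            sp = f"subjects/{sub.label}"
            yield sp, sub
            for ses in sub.sessions:
                qp = f"{sp}/sessions/{ses.label}"
                yield qp, ses
                for acq in ses.acquisitions:
                    yield f"{qp}/acquisitions/{acq.label}", acq

    def iter_analyses(self) -> Iterator[tuple[str, AnalysisRecord]]:
        for path, node in self.walk():
            for ana in node.analyses:
                yield path, ana


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_CHILD_ATTR = {"project": "subjects", "subject": "sessions", "session": "acquisitions"}
_CHILD_DIR = {"project": "subjects", "subject": "sessions", "session": "acquisitions"}
_LEVEL_CLS = {
    "project": ProjectRecord,
    "subject": SubjectRecord,
    "session": SessionRecord,
    "acquisition": AcquisitionRecord,
}
_NEXT_LEVEL = {"project": "subject", "subject": "session", "session": "acquisition"}


def _dump_json(doc: dict) -> bytes:
    return (json.dumps(doc, indent=2, sort_keys=True) + "\n").encode()


def _container_doc(node: _Container, level: str) -> dict:
    doc = {
        "label": node.label,
        "metadata": node.metadata,
        "files": [f.to_doc() for f in node.files],
    }
    child_attr = _CHILD_ATTR.get(level)
    if child_attr is not None:
        doc[child_attr] = [c.label for c in getattr(node, child_attr)]
    return doc


def save_project(project: ProjectRecord, root: str | Path) -> list[str]:
    """Persist *project* under *root*, returning the written-paths manifest.

    The write is canonical: after saving, the tree under *root* contains
    exactly the manifest paths — stale documents and payloads from a
    previous save are removed — so identical records yield byte-identical
    stores.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(rel: str, data: bytes) -> None:
        target = root / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(data)
        manifest.append(rel)

    def save_files(node: _Container, dir_rel: str) -> None:
        node._check_file_names(dir_rel)
        for f in node.files:
            if f.payload is not None:
                f.content_ref = f"{dir_rel}/files/{f.name}" if dir_rel else f"files/{f.name}"
                emit(f.content_ref, f.payload)
                f.payload = None
            elif f.content_ref is not None:
                src = root / f.content_ref
                if src.is_file():
                    manifest.append(f.content_ref)

    def save_analyses(node: _Container, dir_rel: str, self_ref: str) -> None:
        for i, ana in enumerate(node.analyses):
            ana.parent_ref = self_ref
            rel = f"{dir_rel}/analyses/{i:03d}_{ana.label}.json" if dir_rel else f"analyses/{i:03d}_{ana.label}.json"
            emit(rel, _dump_json(ana.to_doc()))

    def save_node(node: _Container, level: str, dir_rel: str, self_ref: str) -> None:
        doc_name = f"{level}.json"
        children = getattr(node, _CHILD_ATTR[level], []) if level in _CHILD_ATTR else []
        labels = [c.label for c in children]
        if len(labels) != len(set(labels)):
            raise IntegrityError(f"duplicate sibling labels under {self_ref or '<project>'}")
        save_files(node, dir_rel)  # assigns content_refs before the doc is serialized
        emit(f"{dir_rel}/{doc_name}" if dir_rel else doc_name, _dump_json(_container_doc(node, level)))
        save_analyses(node, dir_rel, self_ref)
        if level in _CHILD_ATTR:
            child_dir = _CHILD_DIR[level]
            for child in children:
                crel = f"{dir_rel}/{child_dir}/{child.label}" if dir_rel else f"{child_dir}/{child.label}"
                cref = f"{self_ref}/{child_dir}/{child.label}" if self_ref else f"{child_dir}/{child.label}"
                save_node(child, _NEXT_LEVEL[level], crel, cref)

    save_node(project, "project", "", "")

    # canonical store: drop anything not in the manifest
    keep = set(manifest)
    for p in sorted(root.rglob("*"), reverse=True):
        rel = p.relative_to(root).as_posix()
        if p.is_file() and rel not in keep:
            p.unlink()
        elif p.is_dir() and not any(p.iterdir()):
            p.rmdir()

    project.root = root
    return manifest


def load_project(root: str | Path) -> ProjectRecord:
    """Materialize the full hierarchy stored under *root*.

    Unknown metadata keys are preserved verbatim; duplicate sibling labels
    or duplicate file names raise :class:`IntegrityError` naming the path.
    """
    root = Path(root)
    index = root / "project.json"
    if not index.is_file():
        raise StoreError(f"no project index at {index}")

    def load_analyses(dir_path: Path, self_ref: str) -> list[AnalysisRecord]:
        adir = dir_path / "analyses"
        out = []
        if adir.is_dir():
            for doc_path in sorted(adir.glob("*.json")):
                ana = AnalysisRecord.from_doc(json.loads(doc_path.read_text()))
                ana.parent_ref = self_ref
                out.append(ana)
        return out

    def load_node(level: str, dir_path: Path, self_ref: str) -> _Container:
        doc_path = dir_path / f"{level}.json"
        if not doc_path.is_file():
            raise StoreError(f"missing index document {doc_path}")
        doc = json.loads(doc_path.read_text())
        cls = _LEVEL_CLS[level]
        node = cls(
            label=doc["label"],
            metadata=doc.get("metadata", {}),
            files=[FileRecord.from_doc(d) for d in doc.get("files", [])],
        )
        node._check_file_names(self_ref)
        node.analyses = load_analyses(dir_path, self_ref)
        if level in _CHILD_ATTR:
            labels = doc.get(_CHILD_ATTR[level], [])
            if len(labels) != len(set(labels)):
                raise IntegrityError(f"duplicate sibling labels under {self_ref or '<project>'}")
            child_dir = _CHILD_DIR[level]
            children = []
            for label in labels:
                cdir = dir_path / child_dir / label
                cref = f"{self_ref}/{child_dir}/{label}" if self_ref else f"{child_dir}/{label}"
                children.append(load_node(_NEXT_LEVEL[level], cdir, cref))
            setattr(node, _CHILD_ATTR[level], children)
        return node

    project = load_node("project", root, "")
    assert isinstance(project, ProjectRecord)
    project.root = root
    return project


# ---------------------------------------------------------------------------
# queries and metadata writes
# ---------------------------------------------------------------------------

def select_sessions(
    project: ProjectRecord,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
) -> list[SessionRecord]:
    """Select sessions, optionally filtered by subject and session labels.

    No filters → every session in store order.  Both filters intersect.
    Unknown labels yield an empty (or partial) selection with a logged
    warning rather than an error.  Each returned session carries its
    owning subject's label in ``subject_label``.
    """
    if subject_labels is not None:
        known = {s.label for s in project.subjects}
        for label in subject_labels:
            if label not in known:
                logger.warning("subject label %r not found in project %r", label, project.label)
    selected = []
    seen_sessions: set[str] = set()
    for sub in project.subjects:
        if subject_labels is not None and sub.label not in subject_labels:
            continue
        for ses in sub.sessions:
            ses.subject_label = sub.label
            seen_sessions.add(ses.label)
            if session_labels is not None and ses.label not in session_labels:
                continue
            selected.append(ses)
    if session_labels is not None:
        for label in session_labels:
            if label not in seen_sessions:
                logger.warning("session label %r not found in selection", label)
    return selected


def set_file_info(
    project: ProjectRecord,
    container_path: str,
    file_name: str,
    namespace: str,
    record: dict | None,
) -> FileRecord:
    """Replace (or, with ``record=None``, delete) one info namespace on a file.

    Only the named namespace changes; every other key of ``info`` is left
    untouched.  Writing or deleting ``dicom_header`` is forbidden — the
    scanner-derived header is immutable ground truth.
    """
    if namespace == DICOM_HEADER_NS:
        raise ImmutableMetadataError(
            f"namespace {DICOM_HEADER_NS!r} is immutable (attempted write to "
            f"{container_path or '<project>'}/{file_name})"
        )
    node = project.resolve(container_path)
    f = node.get_file(file_name)
    if record is None:
        f.info.pop(namespace, None)
    else:
        f.info[namespace] = record
    return f


def store_checksum(root: str | Path) -> str:
    """SHA-256 digest over every file (path + bytes) under *root*.

    Used to assert that read-only operations and dry runs leave the
    persisted store byte-identical.
    """
    root = Path(root)
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(b"\0")
            h.update(p.read_bytes())
            h.update(b"\0")
    return h.hexdigest()
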