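"""Materializing a curated project as a BIDS directory tree.

Export walks the ``BIDS`` namespaces written by curation and copies each
NIfTI payload to ``sub-<L>/ses-<L>/<folder>/<filename>``, writing one
JSON sidecar per image.  Sidecars merge a minimal set of header-derived
fields (RepetitionTime, EchoTime, TaskName is left to extras) with the
heuristic's hardcoded extras; extras win on conflict, since they are
deliberate.  Fieldmap sidecars additionally carry the resolved
``IntendedFor`` list.  Export is strictly read-only on the store.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from .datastore import BIDS_NS, DICOM_HEADER_NS, ProjectRecord, select_sessions
from .curate import BIDS_PATH_KEY
from .errors import ExportError
from .heuristic import BIDSInfo

logger = logging.getLogger(__name__)

#: BIDS specification version recorded in generated dataset descriptions
BIDS_VERSION = "1.8.0"

DATASET_DESCRIPTION_KEY = "dataset_description"


@dataclass
class ExportManifest:
    """Ordered record of everything an export wrote."""

    paths: list[str] = field(default_factory=list)
    counts_by_folder: dict[str, int] = field(default_factory=dict)

    @property
    def image_paths(self) -> list[str]:
        return [p for p in self.paths if p.endswith(".nii.gz")]


def ensure_dataset_description(project: ProjectRecord) -> dict:
    """Return the project's dataset description, creating a minimal one.

    If the project metadata carries no description, one is created (in
    memory) with the two required fields: ``Name`` (the project label)
    and ``BIDSVersion``.  An existing description is returned unchanged.
    """
    existing = project.metadata.get(DATASET_DESCRIPTION_KEY)
    if existing is not None:
        return existing
    desc = {"Name": project.label, "BIDSVersion": BIDS_VERSION}
    project.metadata[DATASET_DESCRIPTION_KEY] = desc
    return desc


def _sidecar_content(bids: BIDSInfo, header: dict | None) -> dict:
    sidecar: dict = {}
    if header is not None:
        if header.get("RepetitionTime") is not None:
            sidecar["RepetitionTime"] = float(header["RepetitionTime"]) / 1000.0
        if header.get("EchoTime") is not None:
            sidecar["EchoTime"] = float(header["EchoTime"]) / 1000.0
    sidecar.update(bids.sidecar_extras)  # hardcoded extras override header fields
    if bids.folder == "fmap" and bids.intended_for:
        sidecar["IntendedFor"] = list(bids.intended_for)
    return sidecar


def export_bids(
    project: ProjectRecord,
    destination: str | Path,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
) -> ExportManifest:
    """Write the curated selection as a BIDS tree under *destination*.

    Images without a ``BIDS`` namespace are skipped with a warning.
    Raises :class:`ExportError` on path collisions or when a NIfTI's
    payload bytes are missing from the store.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    manifest = ExportManifest()
    written: set[str] = set()

    def emit_bytes(rel: str, data: bytes) -> None:
        if rel in written:
            raise ExportError(f"export path collision: {rel!r}")
        target = destination / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(data)
        written.add(rel)
        manifest.paths.append(rel)

    desc = ensure_dataset_description(project)
    emit_bytes(
        "dataset_description.json",
        (json.dumps(desc, indent=2, sort_keys=True) + "\n").encode(),
    )

    def emit_attachments(container) -> None:
        for f in container.files:
            rel = f.info.get(BIDS_PATH_KEY)
            if rel is None:
                continue
            if f.payload is not None:
                emit_bytes(rel, f.payload)
            elif f.content_ref is not None and project.root is not None:
                emit_bytes(rel, (project.root / f.content_ref).read_bytes())
            else:
                raise ExportError(f"attachment {f.name!r} has no payload bytes")

    emit_attachments(project)

    for session in select_sessions(project, subject_labels, session_labels):
        emit_attachments(session)
        for acq in session.acquisitions:
            dicom = acq.dicom_file
            header = dicom.info.get(DICOM_HEADER_NS) if dicom is not None else None
            for f in acq.nifti_files:
                raw = f.info.get(BIDS_NS)
                if raw is None:
                    logger.warning(
                        "NIfTI %r in acquisition %r has no BIDS identity; skipped",
                        f.name, acq.label,
                    )
                    continue
                bids = BIDSInfo.from_dict(raw)
                if bids.ignore:
                    continue
                if f.payload is not None:
                    emit_bytes(bids.relative_path, f.payload)
                elif f.content_ref is not None and project.root is not None:
                    src = project.root / f.content_ref
                    if not src.is_file():
                        raise ExportError(f"missing payload bytes for {f.name!r} ({src})")
                    if bids.relative_path in written:
                        raise ExportError(f"export path collision: {bids.relative_path!r}")
                    target = destination / bids.relative_path
                    target.parent.mkdir(parents=True, exist_ok=True)
                    shutil.copyfile(src, target)
                    written.add(bids.relative_path)
                    manifest.paths.append(bids.relative_path)
                else:
                    raise ExportError(f"missing payload bytes for {f.name!r}")
                manifest.counts_by_folder[bids.folder] = (
                    manifest.counts_by_folder.get(bids.folder, 0) + 1
                )
                sidecar = _sidecar_content(bids, header)
                if sidecar:
                    rel = bids.relative_path[: -len(".nii.gz")] + ".json"
                    emit_bytes(
                        rel, (json.dumps(sidecar, indent=2, sort_keys=True) + "\n").encode()
                    )
    return manifest
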