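"""Applying a heuristic to a project: planning and writing BIDS metadata.

Curation never touches DICOM files or the ``dicom_header`` namespace —
the scanner output is ground truth.  All it does is attach a ``BIDS``
namespace to NIfTI files (plus optional extra BIDS files declared by the
heuristic), which is why curation can be repeated, updated, or cleared
at any time.

Every run first builds a :class:`CurationPlan`; with ``dry_run=True``
the plan is returned without mutating anything, which is the recommended
way to iterate on a heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .datastore import (
    BIDS_NS,
    DICOM_HEADER_NS,
    FileRecord,
    ProjectRecord,
    SessionRecord,
    load_project,
    save_project,
    select_sessions,
    set_file_info,
)
from .errors import CurationError
from .heuristic import BIDSInfo, HeuristicSpec, classify, load_heuristic, resolve_bids_name, transform_label
from .naming import folder_for_suffix, suffix_of
from .tabulate import extract_seqinfo

logger = logging.getLogger(__name__)

#: marker key (inside a file's info map) identifying attachments created
#: by curation, so that clear removes exactly what curate added
GENERATED_MARKER = "curation_generated"
BIDS_PATH_KEY = "BIDS_path"


@dataclass
class PlannedChange:
    container_path: str
    file_name: str
    action: str  # "set_bids" | "attach_file" | "skip"
    bids: BIDSInfo | None = None
    attachment: tuple[str, str] | None = None  # (relative BIDS path, content)
    reason: str = ""


@dataclass
class CurationPlan:
    changes: list[PlannedChange] = field(default_factory=list)
    dry_run: bool = True

    @property
    def set_bids_changes(self) -> list[PlannedChange]:
        return [c for c in self.changes if c.action == "set_bids"]

    @property
    def attachments(self) -> list[PlannedChange]:
        return [c for c in self.changes if c.action == "attach_file"]

    @property
    def skips(self) -> list[PlannedChange]:
        return [c for c in self.changes if c.action == "skip"]

    def to_records(self) -> list[dict]:
        recs = []
        for c in self.changes:
            recs.append(
                {
                    "container": c.container_path,
                    "file": c.file_name,
                    "action": c.action,
                    "bids_path": (
                        c.bids.relative_path if c.bids else (c.attachment[0] if c.attachment else "")
                    ),
                    "reason": c.reason,
                }
            )
        return recs


def _series_to_acquisition(session: SessionRecord) -> dict[str, str]:
    """Map series_id -> acquisition label, mirroring SeqInfo extraction."""
    subject = session.subject_label or ""
    mapping = {}
    n = 0
    for acq in session.acquisitions:
        dicom = acq.dicom_file
        header = dicom.info.get(DICOM_HEADER_NS) if dicom is not None else None
        if header is None:
            continue
        n += 1
        series_number = int(header.get("SeriesNumber", n))
        mapping[f"{subject}_{session.label}_{series_number}"] = acq.label
    return mapping


def _resolve_intended_for(
    spec: HeuristicSpec, key: str, subject_label: str, session_label: str
) -> list[str]:
    """Turn IntendedFor naming templates into subject-relative paths.

    The heuristic declares targets as naming templates; BIDS sidecars
    expect ``ses-<L>/<folder>/<filename>`` relative to the subject
    directory, so targets are resolved and re-rooted here.
    """
    paths = []
    for target in spec.intended_for.get(key, []):
        filename = target.replace("{SubjectLabel}", subject_label).replace(
            "{SessionLabel}", session_label
        )
        folder = folder_for_suffix(suffix_of(filename))
        paths.append(f"ses-{session_label}/{folder}/{filename}")
    return paths


def build_plan(
    project: ProjectRecord,
    spec: HeuristicSpec,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
) -> CurationPlan:
    """Classify every selected session and plan the metadata writes."""
    plan = CurationPlan(dry_run=True)
    for session in select_sessions(project, subject_labels, session_labels):
        sub_raw = session.subject_label or ""
        sub = transform_label(spec, sub_raw, "subject")
        ses = transform_label(spec, session.label, "session")
        seqinfos = extract_seqinfo(session)
        assignments = classify(spec, seqinfos)
        sid_to_acq = _series_to_acquisition(session)
        assigned_acqs = set()
        base = f"subjects/{sub_raw}/sessions/{session.label}"
        for key, sids in assignments.items():
            template = spec.templates[key]
            for i, sid in enumerate(sids, start=1):
                acq_label = sid_to_acq[sid]
                assigned_acqs.add(acq_label)
                acq = session.acquisitions[
                    [a.label for a in session.acquisitions].index(acq_label)
                ]
                cpath = f"{base}/acquisitions/{acq_label}"
                niftis = acq.nifti_files
                if not niftis:
                    plan.changes.append(
                        PlannedChange(cpath, "", "skip", reason="DICOM present but no NIfTI file")
                    )
                    continue
                bids = resolve_bids_name(template, sub, ses, item=i, n_items=len(sids))
                bids.sidecar_extras = dict(spec.metadata_extras.get(key, {}))
                bids.intended_for = _resolve_intended_for(spec, key, sub, ses)
                plan.changes.append(PlannedChange(cpath, niftis[0].name, "set_bids", bids=bids))
                for extra in niftis[1:]:
                    plan.changes.append(
                        PlannedChange(
                            cpath, extra.name, "skip",
                            reason="additional NIfTI in acquisition; template already assigned",
                        )
                    )
        for acq in session.acquisitions:
            if acq.label not in assigned_acqs and acq.dicom_file is not None:
                plan.changes.append(
                    PlannedChange(
                        f"{base}/acquisitions/{acq.label}", "", "skip",
                        reason="no template matched",
                    )
                )
        for path, content in spec.session_attachments:
            plan.changes.append(
                PlannedChange(base, "", "attach_file", attachment=(path, content))
            )
    for path, content in spec.project_attachments:
        plan.changes.append(PlannedChange("", "", "attach_file", attachment=(path, content)))

    _check_collisions(plan)
    return plan


def _check_collisions(plan: CurationPlan) -> None:
    seen: dict[str, str] = {}
    for c in plan.changes:
        if c.action == "set_bids":
            rel = c.bids.relative_path
            src = f"{c.container_path}/{c.file_name}"
        elif c.action == "attach_file":
            rel = c.attachment[0]
            src = f"{c.container_path or '<project>'} attachment"
        else:
            continue
        if rel in seen:
            raise CurationError(
                f"duplicate resolved BIDS path {rel!r}: {seen[rel]} and {src}"
            )
        seen[rel] = src


def _attachment_record(path: str, content: str) -> FileRecord:
    name = path.replace("/", "_")
    kind = "tabular" if path.endswith((".tsv", ".csv")) else "text"
    return FileRecord(
        name=name,
        kind=kind,
        info={BIDS_PATH_KEY: path, GENERATED_MARKER: True},
        payload=content.encode(),
        content_ref=None,
    )


def _apply_attachment(container, path: str, content: str) -> FileRecord:
    record = _attachment_record(path, content)
    for existing in list(container.files):
        if existing.name == record.name:
            if not existing.info.get(GENERATED_MARKER):
                raise CurationError(
                    f"attachment path {path!r} collides with existing file {existing.name!r}"
                )
            container.files.remove(existing)
    container.files.append(record)
    return record


def apply_plan(project: ProjectRecord, plan: CurationPlan) -> int:
    """Write the plan onto the in-memory project; returns changes applied."""
    applied = 0
    for c in plan.changes:
        if c.action == "set_bids":
            node = project.resolve(c.container_path)
            f = node.get_file(c.file_name)
            old = f.info.get(BIDS_NS)
            new = c.bids.to_dict()
            if old is not None and old != new:
                logger.info(
                    "re-curation overwrites BIDS on %s/%s: %s -> %s",
                    c.container_path, c.file_name, old.get("relative_path"), new["relative_path"],
                )
            set_file_info(project, c.container_path, c.file_name, BIDS_NS, new)
            applied += 1
        elif c.action == "attach_file":
            node = project.resolve(c.container_path)
            _apply_attachment(node, *c.attachment)
            applied += 1
    return applied


def curate_project(
    project: ProjectRecord,
    spec: HeuristicSpec,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
    dry_run: bool = False,
) -> CurationPlan:
    """Plan and (unless *dry_run*) apply BIDS curation to the record graph.

    Persistence is the caller's concern; see :func:`curate_store` for the
    load→curate→save convenience used by the CLI.
    """
    plan = build_plan(project, spec, subject_labels, session_labels)
    plan.dry_run = dry_run
    if not dry_run:
        apply_plan(project, plan)
    return plan


def curate_store(
    root: str | Path,
    heuristic_path: str | Path,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
    dry_run: bool = False,
) -> CurationPlan:
    """Load the store, curate, and save back (no save on dry runs)."""
    project = load_project(root)
    spec = load_heuristic(heuristic_path)
    plan = curate_project(project, spec, subject_labels, session_labels, dry_run=dry_run)
    if not dry_run:
        save_project(project, root)
    return plan


def attach_extra_files(
    project: ProjectRecord,
    spec: HeuristicSpec,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
) -> list[FileRecord]:
    """Attach the heuristic's extra BIDS files without running curation.

    Project-level attachments land on the project container; session-level
    ones on each selected session.  Each record carries its relative BIDS
    path in metadata so export places it correctly.
    """
    attached = []
    for path, content in spec.project_attachments:
        attached.append(_apply_attachment(project, path, content))
    for session in select_sessions(project, subject_labels, session_labels):
        for path, content in spec.session_attachments:
            attached.append(_apply_attachment(session, path, content))
    return attached


def clear_bids(
    project: ProjectRecord,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
) -> int:
    """Remove curation state from the selection; returns removal count.

    Drops the ``BIDS`` namespace from every selected NIfTI file and
    deletes curation-generated attachments.  Project-level attachments
    are removed only on an unfiltered clear.  All other metadata — in
    particular ``dicom_header`` — is untouched.
    """
    removed = 0
    for session in select_sessions(project, subject_labels, session_labels):
        for acq in session.acquisitions:
            for f in acq.nifti_files:
                if BIDS_NS in f.info:
                    del f.info[BIDS_NS]
                    removed += 1
        for f in list(session.files):
            if f.info.get(GENERATED_MARKER):
                session.files.remove(f)
                removed += 1
    if subject_labels is None and session_labels is None:
        for f in list(project.files):
            if f.info.get(GENERATED_MARKER):
                project.files.remove(f)
                removed += 1
    return removed


def clear_store(
    root: str | Path,
    subject_labels: list[str] | None = None,
    session_labels: list[str] | None = None,
) -> int:
    project = load_project(root)
    removed = clear_bids(project, subject_labels, session_labels)
    save_project(project, root)
    return removed
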