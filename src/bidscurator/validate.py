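"""Subset BIDS validation with stable rule codes.

The full BIDS specification is large; this validator commits to a small
rule set (R1–R8) covering the structural properties curation and export
are responsible for, with stable codes so issues can be tabulated and
diffed.  It runs on an exported tree or directly on a project's in-store
``BIDS`` namespaces.  For full-spec checking the CLI can delegate to an
external validator command.

Rules (all errors unless noted):

- **R1** ``dataset_description.json`` present and parseable with
  ``Name`` and ``BIDSVersion``.
- **R2** every image filename matches the committed entity grammar.
- **R3** ``sub-``/``ses-`` filename entities match the enclosing
  directories.
- **R4** filename suffix consistent with its datatype folder
  (unknown suffixes are warnings).
- **R5** every ``func`` image has a ``task`` entity.
- **R6** every fieldmap ``IntendedFor`` target resolves to an existing
  image.
- **R7** subject/session directory labels are alphanumeric.
- **R8** no duplicate paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bids_export import DATASET_DESCRIPTION_KEY, _sidecar_content, BIDS_VERSION
from .curate import BIDS_PATH_KEY
from .datastore import BIDS_NS, DICOM_HEADER_NS, ProjectRecord
from .errors import StoreError
from .heuristic import BIDSInfo
from .naming import ALNUM_RE, IMAGE_EXT, SUFFIX_FOLDER, parse_filename

SEVERITIES = ("error", "warning")


@dataclass(frozen=True)
class Issue:
    code: str
    severity: str
    path: str
    message: str

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity,
            "path": self.path,
            "message": self.message,
        }


@dataclass
class ValidationResult:
    issues: list[Issue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    def to_json(self) -> str:
        return json.dumps(
            {"valid": self.valid, "issues": [i.to_dict() for i in self.issues]},
            indent=2,
            sort_keys=True,
        ) + "\n"


@dataclass
class _Listing:
    """Backend-neutral view of a dataset: what both adapters produce."""

    description_raw: object  # dict, None (absent), or Exception (unparseable)
    image_paths: list[str]
    sidecars: dict[str, dict]
    all_paths: list[str]


def _listing_from_tree(root: Path) -> _Listing:
    if not root.is_dir():
        raise StoreError(f"not a readable directory: {root}")
    desc_path = root / "dataset_description.json"
    if desc_path.is_file():
        try:
            description = json.loads(desc_path.read_text())
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            description = exc
    else:
        description = None
    images = sorted(
        p.relative_to(root).as_posix() for p in root.rglob(f"*{IMAGE_EXT}")
    )
    sidecars = {}
    for rel in images:
        sc = root / (rel[: -len(IMAGE_EXT)] + ".json")
        if sc.is_file():
            try:
                sidecars[rel] = json.loads(sc.read_text())
            except json.JSONDecodeError:
                sidecars[rel] = {}
    all_paths = sorted(p.relative_to(root).as_posix() for p in root.rglob("*") if p.is_file())
    return _Listing(description, images, sidecars, all_paths)


def _listing_from_project(project: ProjectRecord) -> _Listing:
    # the exporter auto-populates a minimal description, so in-store
    # validation applies the same rule rather than reporting a spurious R1
    description = project.metadata.get(DATASET_DESCRIPTION_KEY) or {
        "Name": project.label,
        "BIDSVersion": BIDS_VERSION,
    }
    images: list[str] = []
    sidecars: dict[str, dict] = {}
    extra: list[str] = []
    for container in [project] + [
        ses for sub in project.subjects for ses in sub.sessions
    ]:
        for f in container.files:
            if f.info.get(BIDS_PATH_KEY):
                extra.append(f.info[BIDS_PATH_KEY])
    for _, node in project.walk():
        if not hasattr(node, "nifti_files"):
            continue
        dicom = node.dicom_file
        header = dicom.info.get(DICOM_HEADER_NS) if dicom is not None else None
        for f in node.nifti_files:
            raw = f.info.get(BIDS_NS)
            if raw is None:
                continue
            bids = BIDSInfo.from_dict(raw)
            if bids.ignore:
                continue
            images.append(bids.relative_path)
            sc = _sidecar_content(bids, header)
            if sc:
                sidecars[bids.relative_path] = sc
    all_paths = ["dataset_description.json"] + sorted(extra) + sorted(images)
    return _Listing(description, sorted(images), sidecars, all_paths)


def _check(listing: _Listing) -> list[Issue]:
    issues: list[Issue] = []

    # R1 dataset description
    if listing.description_raw is None:
        issues.append(Issue("R1", "error", "dataset_description.json", "missing dataset description"))
    elif isinstance(listing.description_raw, Exception):
        issues.append(Issue("R1", "error", "dataset_description.json", "unparseable dataset description"))
    else:
        for key in ("Name", "BIDSVersion"):
            if key not in listing.description_raw:
                issues.append(
                    Issue("R1", "error", "dataset_description.json", f"missing required field {key!r}")
                )

    image_set = set(listing.image_paths)
    for rel in listing.image_paths:
        parts = rel.split("/")
        filename = parts[-1]
        entities = parse_filename(filename)

        # R2 filename grammar
        if entities is None:
            issues.append(Issue("R2", "error", rel, "filename does not match the entity grammar"))
            continue

        # R3 entity/directory consistency
        dir_sub = parts[0][len("sub-"):] if parts[0].startswith("sub-") else None
        dir_ses = (
            parts[1][len("ses-"):]
            if len(parts) > 1 and parts[1].startswith("ses-")
            else None
        )
        if dir_sub is None or entities["sub"] != dir_sub:
            issues.append(Issue("R3", "error", rel, "sub- entity does not match enclosing directory"))
        if entities["ses"] != dir_ses:
            issues.append(Issue("R3", "error", rel, "ses- entity does not match enclosing directory"))

        # R4 suffix/folder consistency
        folder = parts[-2] if len(parts) >= 2 else ""
        suffix = entities["suffix"]
        expected = SUFFIX_FOLDER.get(suffix)
        if expected is None:
            issues.append(Issue("R4", "warning", rel, f"suffix {suffix!r} not in the datatype table"))
        elif folder != expected:
            issues.append(
                Issue("R4", "error", rel, f"suffix {suffix!r} belongs in {expected!r}, found in {folder!r}")
            )

        # R5 func images need a task entity
        if expected == "func" and suffix == "bold" and not entities["task"]:
            issues.append(Issue("R5", "error", rel, "func image lacks a task entity"))

        # R6 IntendedFor resolution
        sidecar = listing.sidecars.get(rel, {})
        for target in sidecar.get("IntendedFor", []):
            resolved = f"{parts[0]}/{target}"
            if resolved not in image_set:
                issues.append(
                    Issue("R6", "error", rel, f"IntendedFor target {target!r} does not resolve")
                )

        # R7 alphanumeric labels
        if dir_sub is not None and not ALNUM_RE.match(dir_sub):
            issues.append(Issue("R7", "error", rel, f"subject label {dir_sub!r} not alphanumeric"))
        if dir_ses is not None and not ALNUM_RE.match(dir_ses):
            issues.append(Issue("R7", "error", rel, f"session label {dir_ses!r} not alphanumeric"))

    # R8 duplicate paths
    seen: set[str] = set()
    for rel in listing.all_paths:
        if rel in seen:
            issues.append(Issue("R8", "error", rel, "duplicate path"))
        seen.add(rel)

    issues.sort(key=lambda i: (i.code, i.path, i.message))
    return issues


def validate_dataset(target: str | Path | ProjectRecord) -> ValidationResult:
    """Validate an exported tree (path) or a project's in-store curation.

    Pure: the same input always yields byte-identical serialized issues.
    Unreadable roots raise :class:`StoreError` — an I/O problem, distinct
    from a validation failure.
    """
    if isinstance(target, ProjectRecord):
        listing = _listing_from_project(target)
    else:
        listing = _listing_from_tree(Path(target))
    return ValidationResult(issues=_check(listing))


def tabulate_validation(result: ValidationResult) -> pd.DataFrame:
    """Summarize issues: one row per distinct code with count + example."""
    rows = []
    by_code: dict[str, list[Issue]] = {}
    for issue in result.issues:
        by_code.setdefault(issue.code, []).append(issue)
    for code in sorted(by_code):
        group = by_code[code]
        rows.append(
            {
                "code": code,
                "severity": group[0].severity,
                "count": len(group),
                "example_path": group[0].path,
            }
        )
    return pd.DataFrame(rows, columns=["code", "severity", "count", "example_path"])
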