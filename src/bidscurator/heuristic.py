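"""Loading and evaluation of heuristic rule files.

A heuristic is a plain Python module that declares BIDS naming templates
and the Boolean logic assigning scanning sequences to them.  Reserved
identifiers, matched by exact name:

``classify(seqinfos)`` (required)
    The classification rule.  Receives the list of :class:`SeqInfo` rows
    for one session and returns ``{template_key: [series_id, ...]}``.
    ``infotodict`` is accepted as an alias for compatibility with the
    conventional rule-file idiom.
``ReplaceSubject`` / ``ReplaceSession`` (optional)
    Pure ``label -> label`` functions applied before sanitization.
``MetadataExtras`` (optional)
    ``{template_key: {sidecar field: value}}`` — hardcoded JSON sidecar
    fields merged into every file curated under that key.
``IntendedFor`` (optional)
    ``{fieldmap template_key: [naming template string, ...]}`` — points
    fieldmap scans at the images they correct.  Targets are declared as
    naming templates; curation emits them as subject-relative paths.
``AttachToProject`` / ``AttachToSession`` (optional)
    Extra BIDS files (README, participants/events TSV...) as a list of
    ``(relative BIDS path, content)`` pairs, or a zero-argument callable
    returning such a list.

Any other module-level string containing the ``{SubjectLabel}``
placeholder is taken as a naming template, keyed by its variable name.
Placeholders: ``{SubjectLabel}``, ``{SessionLabel}``, and ``{item}`` for
repeated matches.
"""

from __future__ import annotations

import hashlib
import importlib.util
import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path

from .errors import HeuristicError
from .naming import folder_for_suffix, insert_run, suffix_of
from .tabulate import SeqInfo

logger = logging.getLogger(__name__)

_PLACEHOLDERS = {"SubjectLabel", "SessionLabel", "item"}
_PLACEHOLDER_RE = re.compile(r"\{([^{}]*)\}")


@dataclass(frozen=True)
class NamingTemplate:
    key: str
    template: str

    def __post_init__(self) -> None:
        for name in _PLACEHOLDER_RE.findall(self.template):
            if name not in _PLACEHOLDERS:
                raise HeuristicError(
                    f"template {self.key!r} references unknown placeholder {{{name}}}"
                )


@dataclass
class BIDSInfo:
    """Resolved BIDS identity of one NIfTI file.

    Stored under the ``BIDS`` info namespace of the file; absent until
    curation.
    """

    template_key: str
    filename: str
    folder: str
    relative_path: str
    sidecar_extras: dict = field(default_factory=dict)
    intended_for: list[str] = field(default_factory=list)
    ignore: bool = False

    def to_dict(self) -> dict:
        return {
            "template_key": self.template_key,
            "filename": self.filename,
            "folder": self.folder,
            "relative_path": self.relative_path,
            "sidecar_extras": self.sidecar_extras,
            "intended_for": self.intended_for,
            "ignore": self.ignore,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BIDSInfo":
        return cls(
            template_key=d["template_key"],
            filename=d["filename"],
            folder=d["folder"],
            relative_path=d["relative_path"],
            sidecar_extras=d.get("sidecar_extras", {}),
            intended_for=d.get("intended_for", []),
            ignore=d.get("ignore", False),
        )


@dataclass
class HeuristicSpec:
    """A loaded heuristic rule file."""

    templates: dict[str, NamingTemplate]
    classify_fn: object  # callable(list[SeqInfo]) -> dict[str, list[str]]
    replace_subject: object | None = None
    replace_session: object | None = None
    metadata_extras: dict[str, dict] = field(default_factory=dict)
    intended_for: dict[str, list[str]] = field(default_factory=dict)
    project_attachments: list[tuple[str, str]] = field(default_factory=list)
    session_attachments: list[tuple[str, str]] = field(default_factory=list)
    source_path: str = ""
    source_hash: str = ""

    def signature(self) -> tuple:
        """Comparable view of the declarative parts (load determinism)."""
        return (
            tuple(sorted((k, t.template) for k, t in self.templates.items())),
            tuple(sorted((k, tuple(sorted(v.items()))) for k, v in self.metadata_extras.items())),
            tuple(sorted((k, tuple(v)) for k, v in self.intended_for.items())),
            tuple(self.project_attachments),
            tuple(self.session_attachments),
            self.source_hash,
        )


def _normalize_attachments(value, keyword: str) -> list[tuple[str, str]]:
    if callable(value):
        value = value()
    if isinstance(value, dict):
        value = list(value.items())
    out = []
    for entry in value:
        try:
            path, content = entry
        except (TypeError, ValueError):
            raise HeuristicError(f"{keyword} entries must be (path, content) pairs") from None
        out.append((str(path), str(content)))
    return out


def load_heuristic(path: str | Path) -> HeuristicSpec:
    """Load a heuristic rule module from *path*.

    Raises :class:`HeuristicError` if the classification rule is missing,
    a template uses an unknown placeholder, or an ``IntendedFor`` target
    is not a declared template string.
    """
    path = Path(path)
    if not path.is_file():
        raise HeuristicError(f"heuristic file not found: {path}")
    source = path.read_bytes()
    mod_name = f"_bidscurator_heuristic_{hashlib.sha1(bytes(path.resolve().as_posix(), 'utf8')).hexdigest()[:10]}"
    spec = importlib.util.spec_from_file_location(mod_name, path)
    module = importlib.util.module_from_spec(spec)
    sys.modules[mod_name] = module
    try:
        spec.loader.exec_module(module)
    except Exception as exc:  # malformed user code
        raise HeuristicError(f"cannot execute heuristic {path}: {exc}") from exc

    templates: dict[str, NamingTemplate] = {}
    for name, value in vars(module).items():
        if name.startswith("_"):
            continue
        if isinstance(value, str) and "{SubjectLabel}" in value:
            templates[name] = NamingTemplate(key=name, template=value)

    classify_fn = getattr(module, "classify", None) or getattr(module, "infotodict", None)
    if not callable(classify_fn):
        raise HeuristicError(
            f"heuristic {path} defines no classification rule "
            "(expected a function named 'classify' or 'infotodict')"
        )

    intended_for: dict[str, list[str]] = {}
    declared = {t.template for t in templates.values()}
    for key, targets in getattr(module, "IntendedFor", {}).items():
        if key not in templates:
            raise HeuristicError(f"IntendedFor key {key!r} is not a declared template")
        targets = list(targets)
        for target in targets:
            if target not in declared:
                raise HeuristicError(
                    f"IntendedFor target {target!r} is not a declared template string"
                )
        intended_for[key] = targets

    metadata_extras = dict(getattr(module, "MetadataExtras", {}))
    for key in metadata_extras:
        if key not in templates:
            logger.warning("MetadataExtras key %r matches no declared template", key)

    out = HeuristicSpec(
        templates=templates,
        classify_fn=classify_fn,
        replace_subject=getattr(module, "ReplaceSubject", None),
        replace_session=getattr(module, "ReplaceSession", None),
        metadata_extras=metadata_extras,
        intended_for=intended_for,
        project_attachments=_normalize_attachments(
            getattr(module, "AttachToProject", []), "AttachToProject"
        ),
        session_attachments=_normalize_attachments(
            getattr(module, "AttachToSession", []), "AttachToSession"
        ),
        source_path=str(path),
        source_hash=hashlib.sha256(source).hexdigest(),
    )
    return out


def classify(spec: HeuristicSpec, seqinfos: list[SeqInfo]) -> dict[str, list[str]]:
    """Apply the heuristic's rule to a session's SeqInfo rows.

    Returns ``{template_key: [series_id, ...]}`` where every key is a
    declared template, each series appears under at most one key (the
    first-declared key wins, with a warning), unmatched series are
    absent, and ids within a key are ordered by ascending series number.
    """
    raw = spec.classify_fn(list(seqinfos))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise HeuristicError("classification rule must return a mapping key -> series ids")
    by_id = {s.series_id: s for s in seqinfos}
    assigned: set[str] = set()
    out: dict[str, list[str]] = {}
    # iterate in template-declaration order so tie-breaking is stable
    ordered_keys = [k for k in spec.templates if k in raw] + [k for k in raw if k not in spec.templates]
    for key in ordered_keys:
        if key not in spec.templates:
            raise HeuristicError(f"classification rule assigned unknown template key {key!r}")
        ids = []
        for sid in raw[key]:
            if sid not in by_id:
                logger.warning("rule assigned unknown series id %r to %r; dropped", sid, key)
                continue
            if sid in assigned:
                logger.warning(
                    "series %r matched several template keys; keeping first-declared, dropping from %r",
                    sid, key,
                )
                continue
            assigned.add(sid)
            ids.append(sid)
        if ids:
            ids.sort(key=lambda sid: by_id[sid].series_number)
            out[key] = ids
    return out


def transform_label(spec: HeuristicSpec, raw_label: str, which: str) -> str:
    """Apply the optional user label transform, then sanitize.

    Sanitization strips every non-alphanumeric character (BIDS labels
    are alphanumeric).  An empty result is a contract violation.
    """
    if which == "subject":
        fn = spec.replace_subject
    elif which == "session":
        fn = spec.replace_session
    else:
        raise ValueError(f"which must be 'subject' or 'session', got {which!r}")
    label = fn(raw_label) if callable(fn) else raw_label
    sanitized = re.sub(r"[^a-zA-Z0-9]", "", str(label))
    if not sanitized:
        raise HeuristicError(
            f"{which} label {raw_label!r} is empty after transform/sanitization"
        )
    return sanitized


def resolve_bids_name(
    template: NamingTemplate,
    subject_label: str,
    session_label: str,
    item: int = 1,
    n_items: int = 1,
) -> BIDSInfo:
    """Substitute placeholders and derive the file's BIDS location.

    *subject_label* / *session_label* must already be transformed and
    sanitized.  ``{item}`` is substituted only when the template declares
    it; when the key matched several series (*n_items* > 1) and the
    template has no ``{item}``, a ``run-<item>`` entity is inserted
    before the suffix so resolved paths stay unique.
    """
    filename = template.template.replace("{SubjectLabel}", subject_label).replace(
        "{SessionLabel}", session_label
    )
    if "{item}" in filename:
        filename = filename.replace("{item}", str(item))
    elif n_items > 1:
        filename = insert_run(filename, item)
    leftover = _PLACEHOLDER_RE.search(filename)
    if leftover:
        raise HeuristicError(
            f"unresolved placeholder {leftover.group(0)} in template {template.key!r}"
        )
    suffix = suffix_of(filename)
    folder = folder_for_suffix(suffix)
    if folder == "other":
        logger.warning(
            "template %r: suffix %r not in the datatype table; using folder 'other'",
            template.key, suffix,
        )
    relative_path = f"sub-{subject_label}/ses-{session_label}/{folder}/{filename}"
    return BIDSInfo(
        template_key=template.key,
        filename=filename,
        folder=folder,
        relative_path=relative_path,
    )
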