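"""Deterministic synthetic project generator.

Builds small but structurally complete project stores for testing and
demonstration: every acquisition carries a scanner-style DICOM header
record and a minimal valid NIfTI-1 payload (a 2×2×2×1 volume, gzipped
with a zeroed timestamp so stores are byte-identical across runs), and
pipeline outcomes are materialized as analysis records with plausible
runtimes.

Two presets reproduce the demonstration scenarios the toolkit's reports
are designed around:

- :func:`fixture_overview` — 20 subjects, one session each, with one
  T1-weighted scan, three B0-map fieldmap acquisitions, and one
  resting-state BOLD run (so the B0map sequence owns 60 files).
- :func:`fixture_completeness` — the same plus a diffusion scan and
  three pipelines (fMRIPrep, QSIPrep, XCPEngine), with subjects
  ``cec4ba54`` and ``f53cd86f`` missing DWI and a successful QSIPrep
  run, and ``f53cd86f`` additionally failing fMRIPrep and XCPEngine.

Image content is deliberately unrealistic: headers carry only the fields
the curation pipeline reads.
"""

from __future__ import annotations

import gzip
import json
import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .datastore import (
    AcquisitionRecord,
    AnalysisRecord,
    FileRecord,
    ProjectRecord,
    SessionRecord,
    SubjectRecord,
    save_project,
)
from .errors import ConfigError

#: subject labels printed in the demonstration figures; force-inserted
#: into hex8 label sequences so the scenarios are reproducible verbatim
KNOWN_LABELS = {2: "cec4ba54", 7: "f53cd86f"}

_BASE_TIME = datetime(2021, 1, 4, 9, 0, 0, tzinfo=timezone.utc)


@dataclass
class SequenceSpec:
    """One entry of the scanning menu applied to every session."""

    series_description: str
    repeats: int = 1
    tr_ms: float = 2000.0
    te_ms: float = 30.0
    dims: tuple[int, int, int, int] = (64, 64, 40, 1)
    sequence_name: str = "epfid2d1_64"
    image_type: tuple[str, ...] = ("ORIGINAL", "PRIMARY", "M", "ND")

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ConfigError(f"sequence {self.series_description!r}: repeats must be >= 1")


@dataclass
class GearSpec:
    """A pipeline and its per-subject outcomes ('complete'/'failed')."""

    name: str
    version: str
    statuses: dict[str, str] = field(default_factory=dict)
    typical_runtime_s: float = 3600.0


@dataclass
class FixtureConfig:
    n_subjects: int = 20
    label_scheme: str = "hex8"  # or "numeric"
    sessions_per_subject: int = 1
    sequence_menu: list[SequenceSpec] = field(default_factory=list)
    #: subject label -> series descriptions to omit for that subject
    missing: dict[str, list[str]] = field(default_factory=dict)
    gears: list[GearSpec] = field(default_factory=list)
    seed: int = 0
    project_label: str = "synthetic_project"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.sessions_per_subject < 1:
            raise ConfigError("sessions_per_subject must be >= 1")
        if self.label_scheme not in ("hex8", "numeric"):
            raise ConfigError(f"unknown label_scheme {self.label_scheme!r}")


def subject_labels(config: FixtureConfig) -> list[str]:
    """Deterministic subject labels for *config* (seed-driven for hex8)."""
    if config.label_scheme == "numeric":
        return [f"{i + 1:03d}" for i in range(config.n_subjects)]
    rng = random.Random(config.seed)
    labels: list[str] = []
    used = set(KNOWN_LABELS.values())
    while len(labels) < config.n_subjects:
        label = "".join(rng.choice("0123456789abcdef") for _ in range(8))
        if label not in used:
            used.add(label)
            labels.append(label)
    for pos, label in KNOWN_LABELS.items():
        if pos < config.n_subjects:
            labels[pos] = label
    return labels


def _nifti_stub(dims: tuple[int, int, int, int]) -> bytes:
    # tiny but structurally valid NIfTI-1; the real dims live in the header
    # record, the payload volume is always 2x2x2x1
    img = nib.Nifti1Image(np.zeros((2, 2, 2, 1), dtype=np.uint8), np.eye(4))
    return gzip.compress(img.to_bytes(), mtime=0)


def _header(seq: SequenceSpec, series_number: int) -> dict:
    d1, d2, d3, d4 = seq.dims
    return {
        "SeriesNumber": series_number,
        "SeriesDescription": seq.series_description,
        "ProtocolName": seq.series_description,
        "SequenceName": seq.sequence_name,
        "ImageType": list(seq.image_type),
        "RepetitionTime": seq.tr_ms,
        "EchoTime": seq.te_ms,
        "Rows": d1,
        "Columns": d2,
        "Slices": d3,
        "NumberOfTemporalPositions": d4,
        "SeriesFiles": d3 * d4,
    }


def generate_project(config: FixtureConfig, root: str | Path) -> ProjectRecord:
    """Build and persist a project store under *root*.

    Deterministic given ``config.seed``: the same config always produces
    a byte-identical store.
    """
    labels = subject_labels(config)
    unknown = set(config.missing) - set(labels)
    if unknown:
        raise ConfigError(f"missing-map references unknown subject labels: {sorted(unknown)}")
    for gear in config.gears:
        bad = set(gear.statuses) - set(labels)
        if bad:
            raise ConfigError(f"gear {gear.name!r} references unknown subject labels: {sorted(bad)}")

    rng = random.Random(config.seed + 1)
    project = ProjectRecord(label=config.project_label, metadata={"generated_seed": config.seed})

    for si, sub_label in enumerate(labels):
        subject = SubjectRecord(label=sub_label)
        omitted = set(config.missing.get(sub_label, []))
        for j in range(config.sessions_per_subject):
            session = SessionRecord(label=f"{j + 1:02d}", subject_label=sub_label)
            series_number = 0
            for seq in config.sequence_menu:
                if seq.series_description in omitted:
                    continue
                for _ in range(seq.repeats):
                    series_number += 1
                    acq_label = f"{series_number:02d}-{seq.series_description}"
                    acq = AcquisitionRecord(label=acq_label)
                    acq.files.append(
                        FileRecord(
                            name=f"{acq_label}.dicom",
                            kind="dicom",
                            info={"dicom_header": _header(seq, series_number)},
                        )
                    )
                    acq.files.append(
                        FileRecord(
                            name=f"{acq_label}.nii.gz",
                            kind="nifti",
                            payload=_nifti_stub(seq.dims),
                        )
                    )
                    session.acquisitions.append(acq)
            subject.sessions.append(session)

        for gi, gear in enumerate(config.gears):
            status = gear.statuses.get(sub_label)
            if status is None:
                continue
            if status not in ("complete", "failed"):
                raise ConfigError(f"gear {gear.name!r}: bad status {status!r} for {sub_label!r}")
            runtime = round(gear.typical_runtime_s * rng.uniform(0.7, 1.3), 1)
            started = _BASE_TIME + timedelta(days=si, hours=2 * gi)
            finished = started + timedelta(seconds=runtime)
            subject.analyses.append(
                AnalysisRecord(
                    label=f"{gear.name}_{sub_label}",
                    gear_name=gear.name,
                    gear_version=gear.version,
                    status=status,
                    started=started.isoformat().replace("+00:00", "Z"),
                    finished=finished.isoformat().replace("+00:00", "Z"),
                )
            )
        project.subjects.append(subject)

    save_project(project, root)
    return project


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

OVERVIEW_MENU = [
    SequenceSpec("anat_T1w", repeats=1, tr_ms=2400.0, te_ms=2.2, dims=(176, 256, 256, 1),
                 sequence_name="tfl3d1", image_type=("ORIGINAL", "PRIMARY", "M", "ND", "NORM")),
    SequenceSpec("B0map", repeats=3, tr_ms=580.0, te_ms=4.9, dims=(64, 64, 40, 1),
                 sequence_name="fm2d2r"),
    SequenceSpec("task-rest_bold", repeats=1, tr_ms=800.0, te_ms=30.0, dims=(64, 64, 40, 420),
                 sequence_name="epfid2d1_64"),
]

DWI_SEQUENCE = SequenceSpec("DWI_dir64", repeats=1, tr_ms=3500.0, te_ms=89.0,
                            dims=(128, 128, 70, 65), sequence_name="ep_b0_1000")


def overview_config(seed: int = 0) -> FixtureConfig:
    return FixtureConfig(
        n_subjects=20,
        sequence_menu=list(OVERVIEW_MENU),
        seed=seed,
        project_label="demo_overview",
    )


def completeness_config(seed: int = 0) -> FixtureConfig:
    config = FixtureConfig(
        n_subjects=20,
        sequence_menu=list(OVERVIEW_MENU) + [DWI_SEQUENCE],
        seed=seed,
        project_label="demo_completeness",
    )
    labels = subject_labels(config)
    no_dwi = ["cec4ba54", "f53cd86f"]
    config.missing = {label: [DWI_SEQUENCE.series_description] for label in no_dwi}
    config.gears = [
        GearSpec(
            "fMRIPrep", "20.2.3",
            statuses={l: ("failed" if l == "f53cd86f" else "complete") for l in labels},
            typical_runtime_s=5 * 3600,
        ),
        GearSpec(
            "QSIPrep", "0.14.2",
            statuses={l: ("failed" if l in no_dwi else "complete") for l in labels},
            typical_runtime_s=4 * 3600,
        ),
        GearSpec(
            "XCPEngine", "1.2.3",
            statuses={l: ("failed" if l == "f53cd86f" else "complete") for l in labels},
            typical_runtime_s=1800,
        ),
    ]
    return config


def fixture_overview(root: str | Path, seed: int = 0) -> ProjectRecord:
    """The sequence-enumeration demo: 20 subjects, 3 B0map repeats each."""
    return generate_project(overview_config(seed), root)


def fixture_completeness(root: str | Path, seed: int = 0) -> ProjectRecord:
    """The completeness demo: DWI and pipeline gaps for two known subjects."""
    return generate_project(completeness_config(seed), root)


def complete_template_subject(config: FixtureConfig) -> str:
    """First subject unaffected by missing data or failed runs."""
    incomplete = set(config.missing)
    for gear in config.gears:
        incomplete |= {l for l, s in gear.statuses.items() if s != "complete"}
    for label in subject_labels(config):
        if label not in incomplete:
            return label
    raise ConfigError("no complete subject in config")


def demo_heuristic_path() -> Path:
    """Path of the bundled heuristic matching the preset sequence menus."""
    return Path(__file__).parent / "data" / "demo_heuristic.py"


# ---------------------------------------------------------------------------
# config file loading (YAML or JSON)
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> FixtureConfig:
    """Read a FixtureConfig from a YAML or JSON document."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text()) if path.suffix in (".yaml", ".yml") else json.loads(path.read_text())
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse fixture config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"fixture config {path} must be a mapping")
    try:
        menu = [
            SequenceSpec(
                series_description=e["series_description"],
                repeats=e.get("repeats", 1),
                tr_ms=e.get("tr_ms", 2000.0),
                te_ms=e.get("te_ms", 30.0),
                dims=tuple(e.get("dims", (64, 64, 40, 1))),
                sequence_name=e.get("sequence_name", "epfid2d1_64"),
            )
            for e in doc.get("sequence_menu", [])
        ]
        gears = [
            GearSpec(
                name=g["name"],
                version=g["version"],
                statuses=dict(g.get("statuses", {})),
                typical_runtime_s=g.get("typical_runtime_s", 3600.0),
            )
            for g in doc.get("gears", [])
        ]
        return FixtureConfig(
            n_subjects=doc.get("n_subjects", 20),
            label_scheme=doc.get("label_scheme", "hex8"),
            sessions_per_subject=doc.get("sessions_per_subject", 1),
            sequence_menu=menu,
            missing={k: list(v) for k, v in doc.get("missing", {}).items()},
            gears=gears,
            seed=doc.get("seed", 0),
            project_label=doc.get("project_label", "synthetic_project"),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid fixture config {path}: {exc}") from exc
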