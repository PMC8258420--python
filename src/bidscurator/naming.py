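"""BIDS filename grammar shared by the heuristic resolver and the validator.

The committed entity grammar covers the common MRI raw-data entities in
their standard order:

    sub-<alnum>[_ses-<alnum>][_task-<alnum>][_acq-<alnum>][_dir-<alnum>]
    [_run-<int>]_<suffix>.nii.gz
"""

from __future__ import annotations

import re

IMAGE_EXT = ".nii.gz"

FILENAME_RE = re.compile(
    r"^sub-(?P<sub>[a-zA-Z0-9]+)"
    r"(?:_ses-(?P<ses>[a-zA-Z0-9]+))?"
    r"(?:_task-(?P<task>[a-zA-Z0-9]+))?"
    r"(?:_acq-(?P<acq>[a-zA-Z0-9]+))?"
    r"(?:_dir-(?P<dir>[a-zA-Z0-9]+))?"
    r"(?:_run-(?P<run>[0-9]+))?"
    r"_(?P<suffix>[a-zA-Z0-9]+)"
    r"\.nii\.gz$"
)

#: image-filename suffix → BIDS datatype folder
SUFFIX_FOLDER = {
    "T1w": "anat",
    "T2w": "anat",
    "FLAIR": "anat",
    "bold": "func",
    "sbref": "func",
    "dwi": "dwi",
    "epi": "fmap",
    "magnitude": "fmap",
    "magnitude1": "fmap",
    "magnitude2": "fmap",
    "phasediff": "fmap",
    "phase1": "fmap",
    "phase2": "fmap",
    "fieldmap": "fmap",
}

FOLDERS = ("anat", "func", "dwi", "fmap", "perf", "other")

ALNUM_RE = re.compile(r"^[a-zA-Z0-9]+$")


def parse_filename(filename: str) -> dict | None:
    """Parse a BIDS image filename into its entities, or None if malformed."""
    m = FILENAME_RE.match(filename)
    return m.groupdict() if m else None


def suffix_of(filename: str) -> str | None:
    """Extract the suffix of a ``*.nii.gz`` filename (last ``_`` segment)."""
    if not filename.endswith(IMAGE_EXT):
        return None
    stem = filename[: -len(IMAGE_EXT)]
    return stem.rsplit("_", 1)[-1] if "_" in stem else stem


def folder_for_suffix(suffix: str | None) -> str:
    return SUFFIX_FOLDER.get(suffix or "", "other")


def insert_run(filename: str, run: int) -> str:
    """Insert a ``run-<i>`` entity before the suffix segment.

    Used to disambiguate when one naming template matches several series
    in a session and the template carries no ``{item}`` placeholder.
    """
    if not filename.endswith(IMAGE_EXT):
        raise ValueError(f"not an image filename: {filename!r}")
    stem = filename[: -len(IMAGE_EXT)]
    head, _, suffix = stem.rpartition("_")
    if not head:
        raise ValueError(f"cannot place run entity in {filename!r}")
    return f"{head}_run-{run}_{suffix}{IMAGE_EXT}"
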