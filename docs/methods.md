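# Methods

## Data model

A project is a four-level container hierarchy —
project → subject → session → acquisition — where every container
carries a label, a free-form metadata map, attached files, and attached
analysis records. Files have a *kind* (`dicom`, `nifti`, `tabular`,
`text`, `other`) and an open `info` map with two reserved namespaces:

- `dicom_header` — the scanner-derived header record. Treated as
  immutable ground truth: no operation in the package can write or
  delete it (`set_file_info` raises), and the test suite asserts a
  store-wide checksum across whole workflows.
- `BIDS` — the curated identity of a NIfTI file (template key, resolved
  filename, datatype folder, relative path, sidecar extras,
  IntendedFor list, ignore flag). Absent until curation; removable by
  `clear`.

Persistence is a mirrored directory tree of JSON documents
(`project.json`, `subjects/<label>/subject.json`, …) with payloads
under each container's `files/` directory and analysis records as
separate documents under `analyses/`. Saving is canonical: stable key
ordering, trailing newline, and removal of any file not in the written
manifest, so identical record graphs always produce byte-identical
stores. This is what makes properties like "clear ∘ curate = identity"
and "dry runs change nothing" testable as checksum equalities rather
than approximate claims.

Design choices where the model was open:

- Session labels are scoped per subject, not project-wide.
- Sibling order is insertion order, preserved on save.
- Timestamps are ISO-8601 UTC strings; an analysis's
  `runtime_seconds` is derived from `finished − started` when absent.
- The multi-tenant group/instance levels of hosted platforms are
  collapsed to a single project root, since every command operates at
  project scope.

## Tabulation

Each acquisition's `dicom_header` is flattened to a `SeqInfo` row.
Committed columns: `series_id`, subject/session labels, series number,
series description, protocol name, sequence name, image type,
repetition/echo time, `dim1..dim4`, and the series file count. Headers
store TR/TE in milliseconds (the DICOM convention); `SeqInfo` reports
seconds. `series_id` is `<subject>_<session>_<series_number>`, making
rule assignments reproducible across runs.

*Unique* mode deduplicates on the 10-field acquisition-parameter key
(description, protocol, sequence name, image type, TR, TE, dims) —
the fields heuristics typically branch on — keeping the first-seen
row. Missing numeric fields serialize as empty strings, never 0, so
absent values cannot collide with real ones.

## The heuristic rule engine

A heuristic is an executable Python module loaded dynamically, which
preserves the full expressive power of arbitrary Boolean logic over
`SeqInfo` attributes. Reserved identifiers are matched by exact name
(`classify`/`infotodict`, `ReplaceSubject`, `ReplaceSession`,
`MetadataExtras`, `IntendedFor`, `AttachToProject`, `AttachToSession`);
any other module-level string containing `{SubjectLabel}` is a naming
template keyed by its variable name.

Evaluation contracts, chosen where behavior was open:

- **Tie-breaking.** If the rule assigns one series to several keys, the
  first-declared key wins and a warning is logged. Within a key, series
  are ordered by ascending series number.
- **Repeats.** `{item}` substitutes the 1-based match index. When a key
  matches n > 1 series and its template lacks `{item}`, a `run-<i>`
  entity is inserted before the suffix — BIDS forbids duplicate paths,
  so repeats must be disambiguated somehow.
- **Labels.** `ReplaceSubject`/`ReplaceSession` are pure label→label
  functions applied before sanitization, which strips every
  non-alphanumeric character (BIDS labels are alphanumeric). An empty
  post-sanitization label is an error, not a silent skip.
- **IntendedFor.** Targets are declared as naming templates (the
  natural way to write them next to the template definitions) but
  stored and emitted as subject-relative `ses-<L>/<folder>/<file>`
  paths, the form BIDS sidecars require.
- **Datatype folders** derive from the filename suffix:
  T1w/T2w/FLAIR → `anat`, bold/sbref → `func`, dwi → `dwi`,
  epi/magnitude*/phase*/phasediff/fieldmap → `fmap`. Unknown suffixes
  fall back to `other` with a warning rather than failing, so partial
  heuristics stay usable during development.

## Curation

Curation always builds a full plan first (classification + name
resolution + attachment list), validates that all resolved paths are
pairwise distinct (a collision aborts with both sources named), and
only then applies it. A dry run stops after planning. Applying writes
the `BIDS` namespace via the same guarded `set_file_info` path as any
other metadata write, merges `MetadataExtras` into sidecar extras,
resolves `IntendedFor` onto fieldmap files, and materializes
attachments.

Attachments created by curation carry a marker key in their file
metadata, so `clear` removes exactly what `curate` added — nothing
more. Re-curation overwrites a differing existing `BIDS` namespace with
a logged diff; curation is therefore idempotent, and
`clear ∘ curate` restores the pre-curation store byte-for-byte.
Project-level attachments are cleared only by an unfiltered clear,
since a subject-filtered clear should not disturb shared files.

## Export and validation

Export walks the `BIDS` namespaces and writes
`sub-<L>/ses-<L>/<folder>/<filename>`, one JSON sidecar per image, the
dataset description, and attachments at their recorded paths. Sidecars
merge a minimal header-derived set (RepetitionTime, EchoTime, in
seconds) with the heuristic's extras; extras win on conflict because
they are deliberate hardcoding. If the project has no dataset
description, a minimal one is created with the two required fields
(`Name` = project label, `BIDSVersion`, committed as one constant,
currently 1.8.0). Sessionless layouts are not produced.

The validator is a committed subset of the BIDS rules with stable
codes R1–R8 (description present and complete; filename grammar;
entity/directory consistency; suffix/folder consistency; func task
entity; IntendedFor resolution; alphanumeric labels; no duplicate
paths) rather than a vendored copy of the official validator — full
BIDS coverage (derivatives, PET, EEG, …) is out of scope, and a
self-contained rule set keeps validation pure and deterministic. All
subset rules are errors; unknown suffixes are warnings. The CLI can
delegate to an external validator command when one is available. A
structural guarantee worth stating: any tree produced by `export` from
a collision-free plan passes R2–R4, R7, and R8 by construction, which
the cross-module tests assert.

## Auditing

Three overview tables: NIfTI file counts per sequence (sequence
identity = exact series-description string, since headers offer no
canonical grouping), distinct-subject counts per (sequence, BIDS
template) pair with uncurated files shown under an empty template, and
per-(gear, version) run statistics. Gear completion uses subject-level
latest-run semantics — a failed run followed by a success counts as
complete — matching how analysts read per-subject pipeline state;
percentages are rounded to the nearest integer (19/20 → 95).

Completeness matrices compare every non-template subject to the
template subject: columns are derived solely from the template's
sequences, BIDS templates, and (gear, version) pairs, and a cell is
complete iff the row subject has at least as many matching items. Gear
cells additionally require the subject's latest run of that gear to
match the template's version exactly — mixed pipeline versions are a
reproducibility hazard, so they count as incomplete.

The report is a static HTML page (stdlib string templating + pandas
HTML tables) plus one CSV per table, so results remain scriptable.

## The synthetic generator

The generator emulates the structure real stores have — hierarchy,
DICOM-header records, NIfTI payloads, pipeline run records — without
emulating image content: payloads are minimal valid NIfTI-1 volumes
(2×2×2×1, uint8), gzipped with a zeroed timestamp so stores are
byte-identical across runs, and headers carry only the fields the
pipeline reads, with nominal MRI parameter values (e.g. T1w TR 2.4 s,
BOLD TR 0.8 s, DWI TE 89 ms). Hex8 subject labels come from a seeded
generator with the two demonstration labels (`cec4ba54`, `f53cd86f`)
force-inserted at fixed positions so the documented scenarios are
reproducible verbatim. Gear runtimes are drawn uniformly within ±30%
of a per-gear typical duration (hours for preprocessing pipelines,
minutes for post-processing).

The preset scenarios define the study conditions used throughout the
tests: `overview` (20 subjects × [1 T1w, 3 B0map, 1 rest-BOLD] → 100
acquisitions, 60 B0map files) and `completeness` (adds one DWI
acquisition and three gears; `cec4ba54` and `f53cd86f` lack DWI and a
successful QSIPrep run; `f53cd86f` also failed fMRIPrep and XCPEngine,
leaving fMRIPrep at 19/20 = 95% complete). These sizes run the whole
pipeline in seconds, which is the package's chosen desk scale for its
demonstration project.

What passing tests on synthetic stores do **not** show: robustness to
real scanner header idiosyncrasies (vendor-specific fields, missing or
malformed values beyond the covered cases), DICOM byte-stream parsing
(ingest is assumed done — stores arrive with NIfTIs already
converted), multi-echo/multi-run protocols beyond the committed entity
grammar, and performance at thousands of subjects.

## Known limitations

- The validator covers the committed R1–R8 subset only; it is not a
  substitute for full-specification validation of a dataset destined
  for publication.
- The entity grammar covers sub/ses/task/acq/dir/run; datatypes
  outside anat/func/dwi/fmap resolve to `other`.
- No concurrent multi-writer access to a store; no network backends.
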