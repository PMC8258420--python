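# bidscurator

Heuristic-driven curation of hierarchically stored neuroimaging
projects into [BIDS](https://bids.neuroimaging.io/) (Brain Imaging Data
Structure), plus a project auditor that inventories sequences, curation
state, and pipeline-run completeness.

## The problem

Imaging studies accumulate data as a hierarchy — a project holds
subjects, subjects hold sessions, sessions hold acquisitions, and each
acquisition carries the scanner's DICOM output and its converted NIfTI
volume, all with attached metadata. Turning that hierarchy into a valid
BIDS dataset is the critical first step of a reproducible pipeline, and
doing it by hand is slow and error-prone. `bidscurator` automates it
the way `heudiconv` does: the user writes a *heuristic* — a plain
Python file declaring BIDS naming templates and Boolean rules over
DICOM-header attributes (`seqInfo` rows) that assign each acquisition
to a template:

```python
t1w = 'sub-{SubjectLabel}_ses-{SessionLabel}_T1w.nii.gz'

def classify(seqinfo):
    return {'t1w': [s.series_id for s in seqinfo
                    if 'T1w' in s.series_description]}
```

Two principles shape the design. DICOM headers are immutable ground
truth: curation only ever *adds* a BIDS identity to NIfTI files, so it
can be repeated, updated, or cleared at any time without loss. And
every run is plannable: `--dry-run` shows exactly what would change
without touching the store.

The project lives in a plain directory store — one JSON document per
container, payloads alongside — so everything is inspectable and
diff-friendly, with no database or network dependency.

## Commands

| command    | purpose                                                        |
|------------|----------------------------------------------------------------|
| `synth`    | generate a deterministic synthetic project store               |
| `tabulate` | extract DICOM-header sequence info to a TSV (input for writing a heuristic) |
| `curate`   | apply a heuristic: write BIDS identities onto NIfTI files      |
| `export`   | materialize the curated project as a BIDS directory tree       |
| `validate` | check the tree (or the in-store curation) against BIDS rules   |
| `clear`    | remove all curation state, restoring the pre-curation store    |
| `audit`    | inventory sequences, curation, and gear runs; completeness vs a template subject |

All commands run project-wide by default and accept repeatable
`--subject` / `--session` filters.

The auditor's *completeness* view takes a **template subject** — an
exemplar with complete data and analyses — and reports, for every other
subject, a Boolean matrix over the template's sequences, BIDS
templates, and pipeline (gear) runs. A gear cell counts as complete
only if the subject's latest run of that gear matches the template's
version exactly and finished successfully.

## Worked example

The bundled `completeness` preset builds a 20-subject demonstration
project: each session has a T1-weighted scan, three B0-map fieldmap
acquisitions, a resting-state BOLD run, and a diffusion scan, except
that subjects `cec4ba54` and `f53cd86f` lack DWI; three pipelines
(fMRIPrep, QSIPrep, XCPEngine) have recorded runs with known failures.

```console
$ bidscurator -q synth --preset completeness --seed 0 --out store
generated 20 subjects / 118 acquisitions at store

$ bidscurator -q curate --project store \
      --heuristic src/bidscurator/data/demo_heuristic.py
applied: 118 BIDS assignments, 1 attachments, 0 skipped

$ bidscurator -q validate --project store
✔ valid: 0 errors, 0 warnings

$ bidscurator -q audit --project store --template-subject cd18fc9f -o report
wrote 7 report files to report

$ head -4 report/sequences.csv
sequence,file_count
anat_T1w,20
B0map,60
task-rest_bold,20
```

The sequence table counts NIfTI files per scanning sequence: 60 B0map
files, because 20 subjects each acquired 3 B0map repeats. The gear
table summarizes pipeline runs per (gear, version):

```console
$ cut -d, -f1,3,4,5 report/gears.csv
gear_name,total_runs,percent_complete,percent_failed
fMRIPrep,20,95,5
QSIPrep,20,90,10
XCPEngine,20,95,5
```

fMRIPrep is 95% complete — 19 of 20 subjects have a successful latest
run, `f53cd86f` failed. The completeness matrices
(`report/completeness_*.csv`, also rendered in `report/report.html`)
flag exactly `cec4ba54` and `f53cd86f` as incomplete in the DWI
sequence column and in the QSIPrep gear column.

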