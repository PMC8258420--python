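"""Project auditing: sequence inventory, curation state, pipeline runs.

The auditor gives a project-wide view in three tables — scanning
sequences, BIDS curation, and pipeline ("gear") runs — and, given a
*template subject* chosen as an exemplar with complete data and
analyses, three completeness matrices comparing every other subject to
the template.  Results are rendered as a portable static HTML report
plus one CSV per table.  Auditing is strictly read-only on the store.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datastore import (
    BIDS_NS,
    DICOM_HEADER_NS,
    AnalysisRecord,
    ProjectRecord,
    SubjectRecord,
)
from .errors import NotFoundError

COMPLETE = "complete"
INCOMPLETE = "incomplete"

SEQUENCE_COLUMNS = ["sequence", "file_count"]
BIDS_COLUMNS = ["sequence", "bids_template", "subject_count"]
GEAR_COLUMNS = [
    "gear_name",
    "gear_version",
    "total_runs",
    "percent_complete",
    "percent_failed",
    "mean_runtime_seconds",
    "runtimes",
]


@dataclass
class AuditBundle:
    sequence_table: pd.DataFrame
    bids_table: pd.DataFrame
    gear_table: pd.DataFrame
    completeness: dict[str, pd.DataFrame] = field(default_factory=dict)
    template_subject: str | None = None


def _sequence_of(acq) -> str | None:
    dicom = acq.dicom_file
    header = dicom.info.get(DICOM_HEADER_NS) if dicom is not None else None
    if header is None:
        return None
    return str(header.get("SeriesDescription", ""))


def _subject_files(subject: SubjectRecord):
    """Yield (sequence label, nifti FileRecord) over one subject."""
    for ses in subject.sessions:
        for acq in ses.acquisitions:
            seq = _sequence_of(acq)
            if seq is None:
                continue
            for f in acq.nifti_files:
                yield seq, f


def audit_sequences(project: ProjectRecord) -> pd.DataFrame:
    """Count NIfTI files per scanning sequence (series description)."""
    counts: dict[str, int] = {}
    for sub in project.subjects:
        for seq, _ in _subject_files(sub):
            counts[seq] = counts.get(seq, 0) + 1
    rows = [{"sequence": k, "file_count": v} for k, v in counts.items()]
    return pd.DataFrame(rows, columns=SEQUENCE_COLUMNS)


def audit_bids(project: ProjectRecord) -> pd.DataFrame:
    """Distinct-subject counts per (sequence, BIDS naming template) pair.

    Files never curated appear under an empty template string, so gaps in
    curation are visible alongside completed naming.
    """
    owners: dict[tuple[str, str], set[str]] = {}
    for sub in project.subjects:
        for seq, f in _subject_files(sub):
            bids = f.info.get(BIDS_NS)
            template = bids.get("template_key", "") if bids else ""
            owners.setdefault((seq, template), set()).add(sub.label)
    rows = [
        {"sequence": seq, "bids_template": template, "subject_count": len(subs)}
        for (seq, template), subs in owners.items()
    ]
    return pd.DataFrame(rows, columns=BIDS_COLUMNS)


def _subject_of(analysis: AnalysisRecord) -> str | None:
    parts = analysis.parent_ref.split("/") if analysis.parent_ref else []
    if len(parts) >= 2 and parts[0] == "subjects":
        return parts[1]
    return None


def _latest(runs: list[AnalysisRecord]) -> AnalysisRecord:
    return max(runs, key=lambda a: (a.finished, a.started))


def audit_gears(project: ProjectRecord) -> pd.DataFrame:
    """Per (gear, version): run totals, subject-level completion, runtimes.

    Completion uses subject-level latest-run semantics: a subject counts
    as complete when their most recent run of the gear finished with
    status ``complete`` (so a failed run followed by a success counts).
    Percentages are rounded to the nearest integer.
    """
    runs_by_gear: dict[tuple[str, str], list[AnalysisRecord]] = {}
    for _, ana in project.iter_analyses():
        runs_by_gear.setdefault((ana.gear_name, ana.gear_version), []).append(ana)
    rows = []
    for (name, version), runs in runs_by_gear.items():
        by_subject: dict[str, list[AnalysisRecord]] = {}
        for run in runs:
            sub = _subject_of(run)
            if sub is not None:
                by_subject.setdefault(sub, []).append(run)
        n_subjects = len(by_subject)
        n_complete = sum(
            1 for subruns in by_subject.values() if _latest(subruns).status == "complete"
        )
        pct = round(100 * n_complete / n_subjects) if n_subjects else 0
        runtimes = [run.runtime_seconds for run in runs]
        rows.append(
            {
                "gear_name": name,
                "gear_version": version,
                "total_runs": len(runs),
                "percent_complete": pct,
                "percent_failed": 100 - pct,
                "mean_runtime_seconds": round(sum(runtimes) / len(runtimes), 1),
                "runtimes": ";".join(f"{r:g}" for r in runtimes),
            }
        )
    return pd.DataFrame(rows, columns=GEAR_COLUMNS)


def _get_subject(project: ProjectRecord, label: str) -> SubjectRecord:
    for sub in project.subjects:
        if sub.label == label:
            return sub
    raise NotFoundError(f"template subject {label!r} not found in project {project.label!r}")


def _sequence_counts(subject: SubjectRecord) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq, _ in _subject_files(subject):
        counts[seq] = counts.get(seq, 0) + 1
    return counts


def _template_counts(subject: SubjectRecord) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, f in _subject_files(subject):
        bids = f.info.get(BIDS_NS)
        if bids:
            key = bids.get("template_key", "")
            counts[key] = counts.get(key, 0) + 1
    return counts


def _gear_runs(project: ProjectRecord, label: str) -> dict[str, list[AnalysisRecord]]:
    by_name: dict[str, list[AnalysisRecord]] = {}
    for _, ana in project.iter_analyses():
        if _subject_of(ana) == label:
            by_name.setdefault(ana.gear_name, []).append(ana)
    return by_name


def completeness(project: ProjectRecord, template_label: str) -> dict[str, pd.DataFrame]:
    """Boolean completeness of every other subject against the template.

    The template subject's sequences, BIDS templates, and (gear, version)
    pairs define the columns; each cell says whether the row subject has
    at least as many matching items.  A gear cell is complete only when
    the subject's latest run of that gear carries the template's exact
    version and finished successfully — mixed pipeline versions count as
    incomplete by design.
    """
    template = _get_subject(project, template_label)
    others = [s for s in project.subjects if s.label != template_label]
    row_labels = [s.label for s in others]

    seq_cols = _sequence_counts(template)
    seq_rows = {
        sub.label: {
            seq: (COMPLETE if _sequence_counts(sub).get(seq, 0) >= need else INCOMPLETE)
            for seq, need in seq_cols.items()
        }
        for sub in others
    }
    seq_df = pd.DataFrame.from_dict(seq_rows, orient="index").reindex(
        index=row_labels, columns=list(seq_cols)
    )

    tmpl_cols = _template_counts(template)
    tmpl_rows = {
        sub.label: {
            key: (COMPLETE if _template_counts(sub).get(key, 0) >= need else INCOMPLETE)
            for key, need in tmpl_cols.items()
        }
        for sub in others
    }
    bids_df = pd.DataFrame.from_dict(tmpl_rows, orient="index").reindex(
        index=row_labels, columns=list(tmpl_cols)
    )

    template_gears = {
        name: _latest(runs).gear_version
        for name, runs in _gear_runs(project, template_label).items()
    }
    gear_cols = [f"{name} {version}" for name, version in template_gears.items()]
    gear_rows = {}
    for sub in others:
        sub_runs = _gear_runs(project, sub.label)
        row = {}
        for (name, version), col in zip(template_gears.items(), gear_cols):
            runs = sub_runs.get(name)
            if runs:
                latest = _latest(runs)
                ok = latest.status == "complete" and latest.gear_version == version
            else:
                ok = False
            row[col] = COMPLETE if ok else INCOMPLETE
        gear_rows[sub.label] = row
    gear_df = pd.DataFrame.from_dict(gear_rows, orient="index").reindex(
        index=row_labels, columns=gear_cols
    )

    for df in (seq_df, bids_df, gear_df):
        df.index.name = "subject"
    return {"sequences": seq_df, "bids": bids_df, "gears": gear_df}


def audit_project(project: ProjectRecord, template_subject: str | None = None) -> AuditBundle:
    """Run the full audit; completeness only when a template is given."""
    bundle = AuditBundle(
        sequence_table=audit_sequences(project),
        bids_table=audit_bids(project),
        gear_table=audit_gears(project),
        template_subject=template_subject,
    )
    if template_subject is not None:
        bundle.completeness = completeness(project, template_subject)
    return bundle


_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Project audit — {title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 2em; }}
th, td {{ border: 1px solid #999; padding: 0.3em 0.7em; text-align: left; }}
th {{ background: #eee; }}
td:empty::after {{ content: "—"; color: #bbb; }}
</style>
</head>
<body>
<h1>Project audit — {title}</h1>
<h2>Project overview</h2>
<h3>Sequences</h3>
{sequences}
<h3>BIDS curation</h3>
{bids}
<h3>Gear runs</h3>
{gears}
<h2>Project completeness</h2>
{completeness_note}
<h3>Sequences vs template</h3>
{c_sequences}
<h3>BIDS vs template</h3>
{c_bids}
<h3>Gear runs vs template</h3>
{c_gears}
</body>
</html>
"""


def _table_html(df: pd.DataFrame, index: bool = False) -> str:
    if df.empty:
        return "<p><em>no data</em></p>"
    return df.to_html(index=index, border=0)


def render_report(bundle: AuditBundle, out_dir: str | Path) -> list[Path]:
    """Write the static HTML report and the six CSV tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    overview = {
        "sequences.csv": bundle.sequence_table,
        "bids.csv": bundle.bids_table,
        "gears.csv": bundle.gear_table,
    }
    for name, df in overview.items():
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    comp = bundle.completeness
    for key in ("sequences", "bids", "gears"):
        path = out_dir / f"completeness_{key}.csv"
        df = comp.get(key, pd.DataFrame())
        df.to_csv(path, index=not df.empty)
        written.append(path)

    if bundle.template_subject:
        note = f"<p>Template subject: <strong>{html.escape(bundle.template_subject)}</strong></p>"
    else:
        note = "<p><em>No template subject given; completeness not computed.</em></p>"
    page = _PAGE.format(
        title=html.escape(bundle.template_subject or "project"),
        sequences=_table_html(bundle.sequence_table),
        bids=_table_html(bundle.bids_table),
        gears=_table_html(bundle.gear_table),
        completeness_note=note,
        c_sequences=_table_html(comp.get("sequences", pd.DataFrame()), index=True),
        c_bids=_table_html(comp.get("bids", pd.DataFrame()), index=True),
        c_gears=_table_html(comp.get("gears", pd.DataFrame()), index=True),
    )
    report = out_dir / "report.html"
    report.write_text(page)
    written.append(report)
    return written
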