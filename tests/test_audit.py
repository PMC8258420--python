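"""Audit tables, completeness matrices, and report rendering."""

import pandas as pd
import pytest

from bidscurator.audit import (
    audit_bids,
    audit_gears,
    audit_project,
    audit_sequences,
    completeness,
    render_report,
)
from bidscurator.curate import clear_bids
from bidscurator.datastore import (
    AnalysisRecord,
    ProjectRecord,
    SubjectRecord,
    load_project,
    store_checksum,
)
from bidscurator.errors import NotFoundError
from bidscurator.synthfix import completeness_config, complete_template_subject

TEMPLATE = complete_template_subject(completeness_config(0))


def _seq_count(table: pd.DataFrame, sequence: str) -> int:
    return int(table.set_index("sequence").loc[sequence, "file_count"])


class TestSequences:
    def test_b0map_owns_60_files_on_the_overview_fixture(self, overview_store):
        table = audit_sequences(load_project(overview_store))
        assert _seq_count(table, "B0map") == 60  # 20 subjects x 3 repeats

    def test_t1w_owns_20_files(self, overview_store):
        table = audit_sequences(load_project(overview_store))
        assert _seq_count(table, "anat_T1w") == 20

    def test_empty_project_gives_empty_table(self):
        assert audit_sequences(ProjectRecord(label="e")).empty

    def test_counts_sum_to_total_nifti_files(self, completeness_store):
        project = load_project(completeness_store)
        table = audit_sequences(project)
        oracle = sum(
            len(node.nifti_files)
            for _, node in project.walk()
            if hasattr(node, "nifti_files")
        )
        assert table["file_count"].sum() == oracle

    def test_audit_is_read_only(self, completeness_store):
        before = store_checksum(completeness_store)
        audit_project(load_project(completeness_store), TEMPLATE)
        assert store_checksum(completeness_store) == before


class TestBids:
    def test_fully_curated_t1w_template_counts_20_subjects(self, curated_overview):
        table = audit_bids(load_project(curated_overview)).set_index(["sequence", "bids_template"])
        assert int(table.loc[("anat_T1w", "t1w"), "subject_count"]) == 20

    def test_cleared_project_has_only_empty_templates(self, curated_overview):
        project = load_project(curated_overview)
        clear_bids(project)
        table = audit_bids(project)
        assert (table["bids_template"] == "").all()

    def test_missing_dwi_subjects_lower_the_dwi_template_count(self, curated_completeness):
        table = audit_bids(load_project(curated_completeness)).set_index(["sequence", "bids_template"])
        assert int(table.loc[("DWI_dir64", "dwi"), "subject_count"]) == 18  # 20 - 2 without DWI


class TestGears:
    def test_fmriprep_is_95_percent_complete_with_19_subjects(self, completeness_store):
        table = audit_gears(load_project(completeness_store)).set_index("gear_name")
        assert int(table.loc["fMRIPrep", "percent_complete"]) == 95
        assert int(table.loc["fMRIPrep", "total_runs"]) == 20
        assert int(table.loc["fMRIPrep", "percent_failed"]) == 5

    def test_gear_with_zero_runs_is_absent(self, completeness_store):
        table = audit_gears(load_project(completeness_store))
        assert set(table["gear_name"]) == {"fMRIPrep", "QSIPrep", "XCPEngine"}

    def test_all_failed_runs_give_zero_percent_complete(self):
        project = ProjectRecord(label="p", subjects=[SubjectRecord(label="s1")])
        project.subjects[0].analyses.append(
            AnalysisRecord(
                label="a", gear_name="g", gear_version="1.0", status="failed",
                started="2021-01-01T00:00:00Z", finished="2021-01-01T01:00:00Z",
                parent_ref="subjects/s1",
            )
        )
        table = audit_gears(project).set_index("gear_name")
        assert int(table.loc["g", "percent_complete"]) == 0
        assert int(table.loc["g", "percent_failed"]) == 100

    def test_failed_then_successful_run_counts_complete(self):
        project = ProjectRecord(label="p", subjects=[SubjectRecord(label="s1")])
        for status, day in (("failed", 1), ("complete", 2)):
            project.subjects[0].analyses.append(
                AnalysisRecord(
                    label=f"a{day}", gear_name="g", gear_version="1.0", status=status,
                    started=f"2021-01-0{day}T00:00:00Z", finished=f"2021-01-0{day}T01:00:00Z",
                    parent_ref="subjects/s1",
                )
            )
        table = audit_gears(project).set_index("gear_name")
        assert int(table.loc["g", "percent_complete"]) == 100


class TestCompleteness:
    def test_exactly_the_two_known_subjects_lack_dwi(self, curated_completeness):
        matrices = completeness(load_project(curated_completeness), TEMPLATE)
        seq = matrices["sequences"]
        incomplete = sorted(seq.index[seq["DWI_dir64"] == "incomplete"])
        assert incomplete == ["cec4ba54", "f53cd86f"]

    def test_same_two_subjects_incomplete_for_qsiprep(self, curated_completeness):
        matrices = completeness(load_project(curated_completeness), TEMPLATE)
        gears = matrices["gears"]
        col = next(c for c in gears.columns if c.startswith("QSIPrep"))
        assert sorted(gears.index[gears[col] == "incomplete"]) == ["cec4ba54", "f53cd86f"]

    def test_dwi_gap_propagates_to_bids_completeness(self, curated_completeness):
        matrices = completeness(load_project(curated_completeness), TEMPLATE)
        bids = matrices["bids"]
        assert sorted(bids.index[bids["dwi"] == "incomplete"]) == ["cec4ba54", "f53cd86f"]

    def test_fully_complete_subjects_are_complete_everywhere(self, curated_completeness):
        matrices = completeness(load_project(curated_completeness), TEMPLATE)
        affected = {"cec4ba54", "f53cd86f"}
        for df in matrices.values():
            clean = df.drop(index=[i for i in df.index if i in affected])
            assert (clean == "complete").all().all()

    def test_columns_come_from_the_template_subject_only(self, curated_completeness):
        project = load_project(curated_completeness)
        before = completeness(project, TEMPLATE)
        # give a non-template subject an extra gear run: columns must not change
        other = next(s for s in project.subjects if s.label != TEMPLATE)
        other.analyses.append(
            AnalysisRecord(
                label="extra", gear_name="NewGear", gear_version="9.9", status="complete",
                started="2021-06-01T00:00:00Z", finished="2021-06-01T01:00:00Z",
                parent_ref=f"subjects/{other.label}",
            )
        )
        after = completeness(project, TEMPLATE)
        for key in before:
            assert list(before[key].columns) == list(after[key].columns)

    def test_version_mismatch_counts_incomplete(self, curated_completeness):
        project = load_project(curated_completeness)
        other = next(s for s in project.subjects if s.label not in {TEMPLATE, "cec4ba54", "f53cd86f"})
        for ana in other.analyses:
            if ana.gear_name == "fMRIPrep":
                ana.gear_version = "20.0.0"  # older than the template's
        matrices = completeness(project, TEMPLATE)
        gears = matrices["gears"]
        col = next(c for c in gears.columns if c.startswith("fMRIPrep"))
        assert gears.loc[other.label, col] == "incomplete"

    def test_unknown_template_label_is_an_error(self, completeness_store):
        with pytest.raises(NotFoundError):
            completeness(load_project(completeness_store), "nobody")


class TestReport:
    def test_report_writes_html_plus_six_csvs(self, curated_completeness, tmp_path):
        bundle = audit_project(load_project(curated_completeness), TEMPLATE)
        written = render_report(bundle, tmp_path / "report")
        names = sorted(p.name for p in written)
        assert names == [
            "bids.csv",
            "completeness_bids.csv",
            "completeness_gears.csv",
            "completeness_sequences.csv",
            "gears.csv",
            "report.html",
            "sequences.csv",
        ]

    def test_csv_round_trip_equals_bundle_tables(self, curated_completeness, tmp_path):
        bundle = audit_project(load_project(curated_completeness), TEMPLATE)
        out = tmp_path / "report"
        render_report(bundle, out)
        seq = pd.read_csv(out / "sequences.csv")
        pd.testing.assert_frame_equal(seq, bundle.sequence_table)
        comp = pd.read_csv(out / "completeness_sequences.csv", index_col="subject")
        pd.testing.assert_frame_equal(comp, bundle.completeness["sequences"])

    def test_empty_project_report_renders_without_failure(self, tmp_path):
        bundle = audit_project(ProjectRecord(label="empty"))
        written = render_report(bundle, tmp_path / "report")
        assert (tmp_path / "report" / "report.html").read_text().startswith("<!DOCTYPE html>")
        assert len(written) == 7
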