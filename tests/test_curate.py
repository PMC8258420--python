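"""Curation planning, application, idempotence, and clearing."""

import textwrap

import pytest

from bidscurator.curate import (
    GENERATED_MARKER,
    attach_extra_files,
    build_plan,
    clear_bids,
    clear_store,
    curate_project,
    curate_store,
)
from bidscurator.datastore import (
    BIDS_NS,
    AcquisitionRecord,
    FileRecord,
    ProjectRecord,
    SessionRecord,
    SubjectRecord,
    load_project,
    store_checksum,
)
from bidscurator.errors import CurationError
from bidscurator.heuristic import load_heuristic


class TestDryRun:
    def test_dry_run_plans_but_never_touches_the_store(self, overview_store, heuristic_path):
        before = store_checksum(overview_store)
        plan = curate_store(overview_store, heuristic_path, dry_run=True)
        assert plan.set_bids_changes  # non-empty plan
        assert store_checksum(overview_store) == before


class TestApply:
    def test_rest_bold_files_get_the_expected_bids_filename(self, curated_overview):
        project = load_project(curated_overview)
        named = []
        for sub in project.subjects:
            for ses in sub.sessions:
                for acq in ses.acquisitions:
                    for f in acq.nifti_files:
                        bids = f.info.get(BIDS_NS)
                        if bids and bids["template_key"] == "rest_bold":
                            named.append((sub.label, ses.label, bids["filename"]))
        assert len(named) == 20
        for sub_label, ses_label, filename in named:
            assert filename == f"sub-{sub_label}_ses-{ses_label}_task-rest_bold.nii.gz"

    def test_curation_is_idempotent_on_the_store(self, overview_store, heuristic_path):
        curate_store(overview_store, heuristic_path)
        once = store_checksum(overview_store)
        curate_store(overview_store, heuristic_path)
        assert store_checksum(overview_store) == once

    def test_all_applied_relative_paths_are_unique(self, curated_overview):
        project = load_project(curated_overview)
        paths = [
            f.info[BIDS_NS]["relative_path"]
            for _, node in project.walk()
            if hasattr(node, "nifti_files")
            for f in node.nifti_files
            if BIDS_NS in f.info
        ]
        assert len(paths) == len(set(paths))

    def test_fieldmap_intended_for_resolved_to_subject_relative_paths(self, curated_overview):
        project = load_project(curated_overview)
        sub = project.subjects[0]
        fmap_infos = [
            f.info[BIDS_NS]
            for ses in sub.sessions
            for acq in ses.acquisitions
            for f in acq.nifti_files
            if f.info.get(BIDS_NS, {}).get("template_key") == "fieldmap1"
        ]
        assert len(fmap_infos) == 3
        for info in fmap_infos:
            assert info["intended_for"] == [
                f"ses-01/func/sub-{sub.label}_ses-01_task-rest_bold.nii.gz"
            ]

    def test_acquisition_without_nifti_is_skipped_with_reason(self, tmp_path):
        acq = AcquisitionRecord(
            label="01-T1w",
            files=[FileRecord(name="x.dicom", kind="dicom",
                              info={"dicom_header": {"SeriesNumber": 1, "SeriesDescription": "T1w"}})],
        )
        project = ProjectRecord(
            label="p",
            subjects=[SubjectRecord(label="s1", sessions=[SessionRecord(label="01", acquisitions=[acq])])],
        )
        heur = tmp_path / "h.py"
        heur.write_text(textwrap.dedent("""
            t1w = "sub-{SubjectLabel}_ses-{SessionLabel}_T1w.nii.gz"
            def classify(seqinfo):
                return {"t1w": [s.series_id for s in seqinfo]}
        """))
        plan = build_plan(project, load_heuristic(heur))
        assert [c.action for c in plan.changes] == ["skip"]
        assert "no NIfTI" in plan.changes[0].reason

    def test_duplicate_resolved_paths_raise_listing_both_sources(self, tmp_path):
        def acq(n, desc):
            return AcquisitionRecord(
                label=f"{n:02d}-{desc}",
                files=[
                    FileRecord(name="d.dicom", kind="dicom",
                               info={"dicom_header": {"SeriesNumber": n, "SeriesDescription": desc}}),
                    FileRecord(name="i.nii.gz", kind="nifti", payload=b"x"),
                ],
            )

        project = ProjectRecord(
            label="p",
            subjects=[SubjectRecord(label="s1", sessions=[
                SessionRecord(label="01", acquisitions=[acq(1, "T1w_a"), acq(2, "T1w_b")])
            ])],
        )
        heur = tmp_path / "h.py"
        # both series resolve to the same filename: the rule returns them
        # under distinct keys sharing one template string
        heur.write_text(textwrap.dedent("""
            t1w = "sub-{SubjectLabel}_ses-{SessionLabel}_T1w.nii.gz"
            t1w2 = "sub-{SubjectLabel}_ses-{SessionLabel}_T1w.nii.gz"
            def classify(seqinfo):
                out = {"t1w": [], "t1w2": []}
                for s in seqinfo:
                    out["t1w" if "a" in s.series_description else "t1w2"].append(s.series_id)
                return out
        """))
        with pytest.raises(CurationError, match="duplicate resolved BIDS path"):
            build_plan(project, load_heuristic(heur))


class TestAttachments:
    def test_project_readme_attachment_recorded_with_bids_path(self, curated_overview):
        project = load_project(curated_overview)
        readmes = [f for f in project.files if f.info.get("BIDS_path") == "README"]
        assert len(readmes) == 1
        assert readmes[0].info[GENERATED_MARKER] is True

    def test_no_attachments_declared_attaches_nothing(self, tmp_path, overview_store):
        heur = tmp_path / "h.py"
        heur.write_text(
            't1w = "sub-{SubjectLabel}_ses-{SessionLabel}_T1w.nii.gz"\n'
            "def classify(seqinfo):\n    return {}\n"
        )
        project = load_project(overview_store)
        assert attach_extra_files(project, load_heuristic(heur)) == []

    def test_session_attachment_lands_on_every_selected_session(self, tmp_path, overview_store):
        heur = tmp_path / "h.py"
        heur.write_text(textwrap.dedent("""
            t1w = "sub-{SubjectLabel}_ses-{SessionLabel}_T1w.nii.gz"
            def classify(seqinfo):
                return {}
            AttachToSession = [("task-rest_events.tsv", "onset\\tduration\\n")]
        """))
        project = load_project(overview_store)
        attached = attach_extra_files(project, load_heuristic(heur))
        n_sessions = sum(len(sub.sessions) for sub in project.subjects)
        assert len(attached) == n_sessions == 20


class TestClear:
    def test_clear_after_curate_restores_precuration_store(self, overview_store, heuristic_path):
        before = store_checksum(overview_store)
        curate_store(overview_store, heuristic_path)
        assert store_checksum(overview_store) != before
        removed = clear_store(overview_store)
        assert removed > 0
        assert store_checksum(overview_store) == before

    def test_clear_on_never_curated_project_removes_nothing(self, overview_store):
        assert clear_store(overview_store) == 0

    def test_filtered_clear_leaves_other_subjects_intact(self, curated_overview):
        project = load_project(curated_overview)
        target = project.subjects[0].label
        clear_bids(project, subject_labels=[target])

        def bids_count(sub):
            return sum(
                1
                for ses in sub.sessions
                for acq in ses.acquisitions
                for f in acq.nifti_files
                if BIDS_NS in f.info
            )

        assert bids_count(project.subjects[0]) == 0
        for sub in project.subjects[1:]:
            assert bids_count(sub) == 5
        # project-level attachments survive a filtered clear
        assert any(f.info.get(GENERATED_MARKER) for f in project.files)

    def test_clear_never_touches_dicom_headers(self, curated_overview):
        project = load_project(curated_overview)
        headers_before = [
            acq.dicom_file.info["dicom_header"]
            for _, acq in project.walk()
            if hasattr(acq, "dicom_file") and acq.dicom_file
        ]
        clear_bids(project)
        headers_after = [
            acq.dicom_file.info["dicom_header"]
            for _, acq in project.walk()
            if hasattr(acq, "dicom_file") and acq.dicom_file
        ]
        assert headers_before == headers_after
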