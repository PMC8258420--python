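"""Demo heuristic matching the synthetic preset sequence menus.

Naming templates are module-level strings; `classify` holds the Boolean
logic assigning each sequence (by its DICOM SeriesDescription) to a
template.  Reserved keywords demonstrate sidecar extras, fieldmap
IntendedFor wiring, and project-level attachments.
"""

t1w = "sub-{SubjectLabel}_ses-{SessionLabel}_T1w.nii.gz"
fieldmap1 = "sub-{SubjectLabel}_ses-{SessionLabel}_run-{item}_epi.nii.gz"
rest_bold = "sub-{SubjectLabel}_ses-{SessionLabel}_task-rest_bold.nii.gz"
dwi = "sub-{SubjectLabel}_ses-{SessionLabel}_dwi.nii.gz"


def classify(seqinfo):
    info = {"t1w": [], "fieldmap1": [], "rest_bold": [], "dwi": []}
    for s in seqinfo:
        if "T1w" in s.series_description:
            info["t1w"].append(s.series_id)
        elif "B0map" in s.series_description:
            info["fieldmap1"].append(s.series_id)
        elif "rest" in s.series_description:
            info["rest_bold"].append(s.series_id)
        elif "DWI" in s.series_description:
            info["dwi"].append(s.series_id)
    return info


IntendedFor = {
    "fieldmap1": ["sub-{SubjectLabel}_ses-{SessionLabel}_task-rest_bold.nii.gz"],
}

MetadataExtras = {
    "rest_bold": {"TaskName": "rest"},
}

AttachToProject = [
    ("README", "Synthetic demonstration project curated into BIDS.\n"),
]
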