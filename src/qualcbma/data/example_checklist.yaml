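# Worked example: a filled methodological-quality checklist for a CBMA of
# emotion-reappraisal fMRI activation in healthy adults (the checklist's
# canonical example case). Three criteria are unmet (1, 9, 11), each with a
# comment and a declaration that the manuscript also comments on it.
analyses:
- analysis_label: emotion-reappraisal-fmri
  modality: other
  entries:
    1:
      response: "no"
      comment: "The CBMA was not preregistered because the protocol was created retrospectively during a broader systematic review."
      manuscript_commented: true
    2:
      response: "yes"
      comment: "The databases and keywords are provided in the Methods."
    3:
      response: "yes"
      comment: "The inclusion/exclusion criteria are provided in the Methods."
    4:
      response: "yes"
      comment: "All studies used BOLD fMRI task activation."
    5:
      response: "yes"
      comment: "All studies used explicit emotion reappraisal tasks."
    6:
      response: "yes"
      comment: "All studies were on healthy adults."
    7:
      response: "yes"
      comment: "We included one contrast per dataset"
    8:
      response: "yes"
      comment: "ROI/SVC peaks were only included if surpassing whole-brain thresholds."
    9:
      response: "no"
      comment: "Two studies had partial coverage (omitting cerebellum) and were excluded in sensitivity analyses."
      manuscript_commented: true
    10:
      response: "yes"
      comment: "All coordinates were transformed to MNI."
    11:
      response: "no"
      comment: "Data was extracted by one investigator."
      manuscript_commented: true
    12:
      response: "yes"
      comment: "We included 18 datasets (19.4 after sample-size weighting)."
    13:
      response: "yes"
      comment: "Funnel plots are provided in Figure 3."
    14:
      response: "yes"
      comment: "Dataset description is provided in Table 1."
    15:
      response: "yes"
      comment: "Data sources are referenced and scripts are available on OSF."
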