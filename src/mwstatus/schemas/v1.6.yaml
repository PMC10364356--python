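# mwTab file-format schema, version 1.6.
#
# Identical to v1.5 except for additional required keys in the
# CHROMATOGRAPHY section of mass-spectrometry analyses.  The official 1.6
# specification names the new fields; the entries below are editable
# placeholders — sync this table with the published specification as needed.
version: "1.6"
required_sections:
  - PROJECT
  - STUDY
  - SUBJECT
  - SUBJECT_SAMPLE_FACTORS
  - COLLECTION
  - TREATMENT
  - SAMPLEPREP
  - ANALYSIS
analysis_type_rules:
  MS:
    - CHROMATOGRAPHY
    - MS
    - data_block
  NMR:
    - NMR
    - data_block
min_factor_rows: 1
section_rules:
  PROJECT:
    required_keys: [PROJECT_TITLE, FIRST_NAME, LAST_NAME, INSTITUTE, EMAIL]
  STUDY:
    required_keys: [STUDY_TITLE, INSTITUTE, FIRST_NAME, LAST_NAME, EMAIL]
  SUBJECT:
    required_keys: [SUBJECT_TYPE, SUBJECT_SPECIES]
  COLLECTION:
    required_keys: [COLLECTION_SUMMARY]
  TREATMENT:
    required_keys: [TREATMENT_SUMMARY]
  SAMPLEPREP:
    required_keys: [SAMPLEPREP_SUMMARY]
  ANALYSIS:
    required_keys: [ANALYSIS_TYPE]
  CHROMATOGRAPHY:
    required_keys:
      - CHROMATOGRAPHY_TYPE
      - INSTRUMENT_NAME
      - COLUMN_NAME
      - FLOW_RATE
      - COLUMN_TEMPERATURE
      - SOLVENT_A
      - SOLVENT_B
  MS:
    required_keys: [INSTRUMENT_NAME, INSTRUMENT_TYPE, MS_TYPE, ION_MODE]
  NMR:
    required_keys: [INSTRUMENT_NAME, INSTRUMENT_TYPE, NMR_EXPERIMENT_TYPE]
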