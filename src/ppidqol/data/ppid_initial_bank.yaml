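# Metadata stub for the initial interview-derived item bank. The full
# wordings of the five items removed before the survey launch were never
# published; only counts and the reason for removal are recorded here.
schema_version: 1
name: ppid-initial-42
kind: stub
n_items: 42
n_removed_pre_survey: 5
removal_reason: "similarity with other questions (identified during piloting)"
survey_bank: ppid-survey-37
domains: [demeanour, appearance, condition, health, appetite, ingestion, management]
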