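# Default musculoskeletal-infection cyclical continuum model.
# Code/medication prefix lists are ILLUSTRATIVE starting points, not a
# validated extraction code set; replace them per site.
spec_version: 1
name: msk_infection_default
index_element: diabetes_mellitus
infection_elements:
- osteomyelitis
- septic_arthritis
- infectious_myositis
phases:
- label: primary risk factors
  elements:
  - id: diabetes_mellitus
    label: Diabetes mellitus
    codes:
    - system: ICD9
      prefixes:
      - '250'
    - system: ICD10
      prefixes:
      - E08
      - E09
      - E10
      - E11
      - E13
    labs:
    - analyte: hba1c
      aggregation: max
      comparator: ge
      threshold: 6.5
      units: '%'
    medications:
    - drug_class_prefixes:
      - antidiabetic
      systemic_only: true
  - id: peripheral_vascular_disease
    label: Peripheral vascular disease
    codes:
    - system: ICD9
      prefixes:
      - '443'
      - '4402'
    - system: ICD10
      prefixes:
      - I73
      - I702
- label: secondary risk factors
  elements:
  - id: osteomyelitis
    label: Osteomyelitis
    codes:
    - system: ICD9
      prefixes:
      - '730'
    - system: ICD10
      prefixes:
      - M86
  - id: multiple_infections
    label: Multiple infections
    composite:
      members:
      - osteomyelitis
      - septic_arthritis
      - infectious_myositis
      min_count: 2
- label: infection-related outcomes
  elements:
  - id: sepsis
    label: Sepsis
    codes:
    - system: ICD9
      prefixes:
      - 038
      - '99591'
      - '99592'
    - system: ICD10
      prefixes:
      - A40
      - A41
      - R652
  - id: antibiotics
    label: Antibiotics
    medications:
    - drug_class_prefixes:
      - antimicrobial
      systemic_only: true
- label: surgical interventions
  elements:
  - id: surgical_procedure
    label: Surgical procedure
    procedures:
    - prefixes: []
      amputation_only: false
    window:
      anchor: index_infection_date
      start_offset_days: 0
      end_offset_days: 90
  - id: amputation
    label: Amputation
    procedures:
    - prefixes: []
      amputation_only: true
    window:
      anchor: index_infection_date
      start_offset_days: 0
      end_offset_days: 90
auxiliary_elements:
- id: septic_arthritis
  label: Septic arthritis
  codes:
  - system: ICD9
    prefixes:
    - '7110'
  - system: ICD10
    prefixes:
    - M00
- id: infectious_myositis
  label: Infectious myositis
  codes:
  - system: ICD9
    prefixes:
    - '7280'
  - system: ICD10
    prefixes:
    - M600
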