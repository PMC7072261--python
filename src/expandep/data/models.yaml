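# Bundled electrode variants.  Each entry pairs the mechanical spec with
# the planning defaults used for that variant: voltage rounding
# granularity, pulse budget per treatment, target field and regime.
# User files with the same schema are accepted wherever a model name is.

5n-0deg:
  description: >
    Five needles (four peripheral plus one central), zero divergence:
    needles stay parallel, gaps are independent of deployment.  Long
    shaft for laparoscopic access.  Voltages planned per volt against the
    1000 V/cm reversible-electroporation target.
  spec:
    n_needles: 5
    divergence_deg: 0.0
    shaft_diameter_mm: 5.0
    shaft_length_cm: 50.0
    max_deployment_mm: 40.0
    active_length_mm: 20.0
    needle_diameter_mm: 0.45
    head_offset_mm: 3.0
    base_spacing_mm: 3.26
  voltage_granularity_V: 1
  default_pulse_count: 80
  default_target_field_V_per_cm: 1000.0
  default_regime: reversible

5n-20deg:
  description: >
    Five needles with 20 degree peripheral divergence; treatment is
    segmented over successive deployments (S2 = 20 mm, S3 = 30 mm).
    Default planning targets the 1500 V/cm irreversible threshold with
    100 V rounding.
  spec:
    n_needles: 5
    divergence_deg: 20.0
    shaft_diameter_mm: 5.0
    shaft_length_cm: 20.0
    max_deployment_mm: 40.0
    active_length_mm: 20.0
    needle_diameter_mm: 0.45
    head_offset_mm: 3.0
    base_spacing_mm: 3.26
  voltage_granularity_V: 100
  default_pulse_count: 120
  default_target_field_V_per_cm: 1500.0
  default_regime: irreversible

4n-10deg:
  description: >
    Four peripheral needles (no central needle) with 10 degree
    divergence; deployments S2/S3/max = 20/30/40 mm.  Default planning
    targets 1500 V/cm with 100 V rounding.
  spec:
    n_needles: 4
    divergence_deg: 10.0
    shaft_diameter_mm: 5.0
    shaft_length_cm: 20.0
    max_deployment_mm: 40.0
    active_length_mm: 20.0
    needle_diameter_mm: 0.45
    head_offset_mm: 3.0
    base_spacing_mm: 3.26
  voltage_granularity_V: 100
  default_pulse_count: 80
  default_target_field_V_per_cm: 1500.0
  default_regime: irreversible

5n-20deg-printed:
  description: >
    Documented preset, not a default: the 20-degree variant planned
    against ~900 V/cm.  The historically reported voltages for this
    variant (1200/900 V at S2, 1700/1100 V at S3) correspond to an
    effective target field near 900 V/cm rather than the stated
    >=1500 V/cm; this preset approximately reproduces them (3 of 4 under
    nearest-100 V rounding) and exists for auditability only.
  spec:
    n_needles: 5
    divergence_deg: 20.0
    shaft_diameter_mm: 5.0
    shaft_length_cm: 20.0
    max_deployment_mm: 40.0
    active_length_mm: 20.0
    needle_diameter_mm: 0.45
    head_offset_mm: 3.0
    base_spacing_mm: 3.26
  voltage_granularity_V: 100
  default_pulse_count: 120
  default_target_field_V_per_cm: 900.0
  default_regime: irreversible
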