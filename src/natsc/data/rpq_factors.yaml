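# Three-factor structure of the 16-item Rivermead post-concussion symptoms
# questionnaire (Smith-Seemiller factor model).  Item order is the standard
# administration order.  Light sensitivity and double vision are assigned to
# the somatic factor, the conventional placement.  Edit to re-map factors;
# every item must appear in exactly one factor.
items:
  - headache
  - dizziness
  - nausea_vomiting
  - noise_sensitivity
  - sleep_disturbance
  - fatigue
  - irritability
  - depression
  - frustration
  - forgetfulness
  - poor_concentration
  - taking_longer_to_think
  - blurred_vision
  - light_sensitivity
  - double_vision
  - restlessness
factors:
  somatic:
    - headache
    - dizziness
    - nausea_vomiting
    - noise_sensitivity
    - sleep_disturbance
    - fatigue
    - blurred_vision
    - light_sensitivity
    - double_vision
  emotional:
    - irritability
    - depression
    - frustration
    - restlessness
  cognitive:
    - forgetfulness
    - poor_concentration
    - taking_longer_to_think
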