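# SYNTHETIC placeholder normative means/SDs for the six BTACT subtests.
# The authoritative population norms (MIDUS II cognitive study, stratified
# by age/education/sex) are not redistributable here; these round-number
# stand-ins preserve the scoring arithmetic only and are NOT valid for
# interpreting real participants.  Replace with licensed norms for real use.
synthetic: true
subtests:
  immediate_word_recall: {mean: 9.0, sd: 2.5}
  delayed_word_recall: {mean: 7.5, sd: 3.0}
  backward_digit_span: {mean: 5.0, sd: 1.5}
  category_fluency: {mean: 20.0, sd: 6.0}
  number_series: {mean: 2.8, sd: 1.6}
  backward_counting: {mean: 38.0, sd: 11.0}
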