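# Categorical event tallies of the reference in vivo cohort: numerator /
# denominator counts of pulse-associated phagosome behaviours, with the
# printing precision (decimals) of each percentage.  Used as a regression
# fixture for tally_statistics.
re_opening_during_pulse:
  numerator: 27
  denominator: 138
  decimals: 1
full_release_during_pulse:
  numerator: 7
  denominator: 138
  decimals: 1
recaptured_same_neutrophil:
  numerator: 29
  denominator: 31
  decimals: 0
tubule_neck_during_pulse:
  numerator: 3
  denominator: 31
  decimals: 1
released_to_other_phagocyte:
  numerator: 1
  denominator: 31
  decimals: 0
shuttled_to_other_neutrophil:
  numerator: 1
  denominator: 31
  decimals: 0
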