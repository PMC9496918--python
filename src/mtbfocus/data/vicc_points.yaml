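# Criteria-and-points configuration for somatic-variant pathogenicity
# classification (VICC-SOP style). These point values and category
# thresholds are a documented DEFAULT; review them against the published
# SOP before clinical use — the package treats them as configuration, not
# as a re-derivation of the catalogue.
points:
  OVS1: 8    # null variant in a bona fide tumor suppressor
  OS1: 4     # same amino-acid change as an established oncogenic variant
  OS2: 4     # well-established functional studies support oncogenicity
  OS3: 4     # located in a well-characterized mutational hotspot
  OM1: 2     # critical functional domain
  OM2: 2     # protein-length change in tumor suppressor / oncogene context
  OM3: 2     # moderately recurrent hotspot
  OM4: 2     # missense where oncogenic missense variants are common
  OP1: 1     # computational evidence supports deleterious effect
  OP2: 1     # somatic in multiple tumors of the relevant type
  OP3: 1     # located in a hotspot with low recurrence
  OP4: 1     # absent from population databases
  SBVS1: -8  # high population frequency
  SBS1: -4   # frequency greater than expected for oncogenicity
  SBS2: -4   # well-established functional studies show no oncogenic effect
  SBP1: -1   # computational evidence suggests no impact
  SBP2: -1   # silent variant with no predicted splice effect
# category = highest-threshold category whose threshold <= total score
categories:
  oncogenic: 10
  likely_oncogenic: 6
  VUS: 0
  likely_benign: -6
  benign: -999
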