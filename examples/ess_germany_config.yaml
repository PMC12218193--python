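# Example configuration for a European Social Survey (German subset) style
# analysis of climate-change opinions. Users export the ESS data to delimited
# text first; column names below follow the ESS codebook. The package itself
# is survey-agnostic — this file is what makes a run ESS-specific.
input:
  format: survey
  waves:
    "2016": ess_de_wave8.csv
    "2021": ess_de_wave10.csv
    "2023": ess_de_wave11.csv

columns:
  items: [wrclmch, ccnthum]   # worry about climate change; natural vs human cause
  weight: anweight            # analysis weight recommended by the ESS
  party: prtclede             # party felt closest to (wave-specific variable name)
  closeness: prtdgcl          # how close to that party
  wave: essround

likert:
  k: 5
  missing: [6, 7, 8, 9, 66, 77, 88, 99]

filters:
  # "climate is not changing" is a substantive answer that removes the
  # respondent from the two-item opinion space
  disqualify: {item: ccnthum, codes: [55]}
  party: prtclede
  allowed_parties: [1, 2, 3, 4, 5, 6]   # CDU/CSU, SPD, Greens, Left, FDP, AfD
  refusal_codes: [77, 88, 99]

party_map:
  1: "CDU/CSU"
  2: "SPD"
  3: "Greens"
  4: "Left"
  5: "FDP"
  6: "AfD"

closeness_rule:
  column: prtdgcl
  not_close_codes: [4]        # "not at all close" -> nonpartisan ("None")

analysis:
  baseline: "2016"
  compare: ["2021", "2023"]
  mode: instantaneous         # fixed | instantaneous | custom
  ridge_epsilon: 1.0e-6
  min_group_size: 3
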