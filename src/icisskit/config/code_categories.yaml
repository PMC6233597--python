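# Grouping of external-cause codes into 9 mechanism-of-injury categories and
# of principal injury diagnoses into 13 nature-of-injury categories.
# Ranges compare the 3-character category lexicographically (inclusive).
# The S-block body-region x injury-type matrix (third character 0-6) is applied
# in code for S-codes not captured by an explicit rule here.
injury_principal_range: [S00, T89]

mechanism:
  - name: "Land transport incidents"
    ranges: ["V00-V89"]
  - name: "Falls"
    ranges: ["W00-W19"]
  - name: "Inanimate mechanical forces"
    ranges: ["W20-W49"]
  - name: "Drowning and submersion and other threats to breathing"
    ranges: ["W65-W84"]
  - name: "Smoke, fire and flames, heat and hot substances"
    ranges: ["X00-X19"]
  - name: "Poisoning"
    ranges: ["X40-X49"]
  - name: "Intentional self-harm"
    ranges: ["X60-X84"]
  - name: "Assault"
    ranges: ["X85-Y09"]
  - name: "Other and unspecified injury mechanism"
    fallback: true

nature:
  - name: "Injury to internal organs"
    prefixes: [S06, S26, S27, S36, S37]
  - name: "Foreign body entering through natural orifice"
    ranges: ["T15-T19"]
  - name: "Burns"
    ranges: ["T20-T32"]
  - name: "Poisoning by drugs, medicaments and biological substances"
    ranges: ["T36-T50"]
  - name: "Toxic effects of substances chiefly nonmedicinal as to source"
    ranges: ["T51-T65"]
  - name: "Superficial injuries"
  - name: "Open wound"
  - name: "Fracture"
  - name: "Dislocations, sprains & strains"
  - name: "Injury to nerves and spinal cord"
  - name: "Injury to blood vessels"
  - name: "Injury to muscle, fascia and tendon"
  - name: "Other and unspecified injuries"
    fallback: true
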