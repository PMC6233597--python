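# Charlson comorbidity conditions with the Quan et al. ICD-10 coding algorithm
# (17 conditions, original Charlson weights 1-6).  Patterns are matched as
# strict prefixes on normalised codes (dots stripped, upper-case); ranges
# compare the 3-character category inclusively.  Fully replaceable: pass an
# alternative file of the same shape to use a different coding algorithm.
conditions:
  - name: myocardial_infarction
    weight: 1
    prefixes: [I21, I22, I252]
  - name: congestive_heart_failure
    weight: 1
    prefixes: [I099, I110, I130, I132, I255, I420, I425, I426, I427, I428, I429, I43, I50, P290]
  - name: peripheral_vascular_disease
    weight: 1
    prefixes: [I70, I71, I731, I738, I739, I771, I790, I792, K551, K558, K559, Z958, Z959]
  - name: cerebrovascular_disease
    weight: 1
    prefixes: [G45, G46, H340]
    ranges: ["I60-I69"]
  - name: dementia
    weight: 1
    prefixes: [F051, G30, G311]
    ranges: ["F00-F03"]
  - name: chronic_pulmonary_disease
    weight: 1
    prefixes: [I278, I279, J684, J701, J703]
    ranges: ["J40-J47", "J60-J67"]
  - name: rheumatic_disease
    weight: 1
    prefixes: [M05, M06, M315, M351, M353, M360]
    ranges: ["M32-M34"]
  - name: peptic_ulcer_disease
    weight: 1
    ranges: ["K25-K28"]
  - name: mild_liver_disease
    weight: 1
    prefixes: [B18, K700, K701, K702, K703, K709, K713, K714, K715, K717, K73, K74, K760, K762, K763, K764, K768, K769, Z944]
  - name: diabetes_without_complication
    weight: 1
    prefixes: [E100, E101, E106, E108, E109, E110, E111, E116, E118, E119, E120, E121, E126, E128, E129, E130, E131, E136, E138, E139, E140, E141, E146, E148, E149]
  - name: diabetes_with_complication
    weight: 2
    prefixes: [E102, E103, E104, E105, E107, E112, E113, E114, E115, E117, E122, E123, E124, E125, E127, E132, E133, E134, E135, E137, E142, E143, E144, E145, E147]
  - name: hemiplegia_paraplegia
    weight: 2
    prefixes: [G041, G114, G801, G802, G81, G82, G830, G831, G832, G833, G834, G839]
  - name: renal_disease
    weight: 2
    prefixes: [I120, I131, N032, N033, N034, N035, N036, N037, N052, N053, N054, N055, N056, N057, N18, N19, N250, Z490, Z491, Z492, Z940, Z992]
  - name: any_malignancy
    weight: 2
    ranges: ["C00-C26", "C30-C34", "C37-C41", "C43-C43", "C45-C58", "C60-C76", "C81-C85", "C88-C88", "C90-C97"]
  - name: moderate_severe_liver_disease
    weight: 3
    prefixes: [I850, I859, I864, I982, K704, K711, K721, K729, K765, K766, K767]
  - name: metastatic_solid_tumour
    weight: 6
    ranges: ["C77-C80"]
  - name: aids_hiv
    weight: 6
    ranges: ["B20-B24"]
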