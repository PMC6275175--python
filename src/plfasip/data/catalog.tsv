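# Default PLFA biomarker catalog: biomarker -> functional group, with the
# carbon count of the underivatized fatty acid (used by the FAME correction).
# 13 group-assigned biomarkers; the remaining 11 are common general biomarkers
# that count toward total biomass only.
biomarker	group	n_carbons
18:2ω6	fungi	18
16:1ω7	gram_negative	16
cy17:0	gram_negative	17
18:1ω7	gram_negative	18
a15:0	gram_positive	15
a17:0	gram_positive	17
i15:0	gram_positive	15
i16:0	gram_positive	16
i17:0	gram_positive	17
10Me16:0	actinomycetes	17
10Me17:0	actinomycetes	18
10Me18:0	actinomycetes	19
20:4	microfauna	20
14:0	unassigned	14
15:0	unassigned	15
16:0	unassigned	16
17:0	unassigned	17
18:0	unassigned	18
16:1ω5	unassigned	16
16:1ω9	unassigned	16
18:1ω9	unassigned	18
18:1ω5	unassigned	18
cy19:0	unassigned	19
20:0	unassigned	20
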