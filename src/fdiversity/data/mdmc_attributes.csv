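attribute,narrative_distinct_terms,narrative_noc_diversity,structured_noc_diversity_printed
Smoking,30,29,3
Allergy,13,12,2
Ischemic heart disease,13,12,2
Dyspnoea,29,28,2
Chest pain,17,16,2
Palpitations,8,7,1
Swelling,26,25,1
Diabetes mellitus,15,14,1
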