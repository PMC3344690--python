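attribute,category,count_collection_a,count_collection_b
Smoking,smoker,15,203
Smoking,occasional smoker,0,19
Smoking,ex-smoker,19,128
Smoking,nonsmoker,37,730
Smoking,__missing__,39,39
Allergy,yes,27,378
Allergy,no,63,681
Allergy,do not know,0,6
Allergy,__missing__,20,54
Ischemic heart disease,yes,56,44
Ischemic heart disease,no,11,992
Ischemic heart disease,I do not know,0,9
Ischemic heart disease,__missing__,43,74
Dyspnoea,yes,28,113
Dyspnoea,no,51,934
Dyspnoea,__missing__,31,72
Chest pain,yes,10,87
Chest pain,no,28,962
Chest pain,__missing__,72,70
Palpitations,yes,6,150
Palpitations,no,11,904
Palpitations,__missing__,93,65
Swelling,yes,13,56
Swelling,no,82,994
Swelling,__missing__,15,69
Diabetes mellitus,yes,51,48
Diabetes mellitus,no,18,1025
Diabetes mellitus,__missing__,41,46
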