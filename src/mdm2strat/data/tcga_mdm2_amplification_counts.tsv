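tumor_type	amplified	total
Liposarcoma	9	14
Glioblastoma Multiforme	41	562
Bladder Urothelial Carcinoma	4	152
Stomach Adenocarcinoma	4	273
Lung Adenocarcinoma	4	437
Skin Cutaneous Melanoma	2	273
Brain Lower Grade Glioma	1	220
Breast Invasive Carcinoma	3	926
Ovarian Serous Cystadenocarcinoma	1	576
Uterine Corpus Endometrial Carcinoma	0	493
Lung Squamous Cell Carcinoma	0	387
Head and Neck Squamous Cell Carcinoma	0	337
Kidney Renal Papillary Cell Carcinoma	0	117
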