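tumor_type	annual_incidence
Liposarcoma	5000
Glioblastoma Multiforme	11130
Bladder Urothelial Carcinoma	74690
Stomach Adenocarcinoma	22220
Lung Adenocarcinoma	66700
Skin Cutaneous Melanoma	76100
Brain Lower Grade Glioma	3000
Breast Invasive Carcinoma	235030
Ovarian Serous Cystadenocarcinoma	13190
Uterine Corpus Endometrial Carcinoma	52630
Lung Squamous Cell Carcinoma	57170
Head and Neck Squamous Cell Carcinoma	42440
Kidney Renal Papillary Cell Carcinoma	6400
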