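pt,n_serious,n_nonserious,printed_test,printed_statistic
Anaemia,26,26,pearson,10.633
Febrile neutropenia,26,19,pearson,33.710
Thrombocytopenia,26,27,pearson,9.861
Haematotoxicity,15,1,pearson,31.787
Leukopenia,12,5,pearson,13.777
Neutropenia,37,65,pearson,2.270
Pancytopenia,31,23,pearson,3.706
Cytopenia,14,17,pearson,3.630
Myelosuppression,6,9,pearson,0.773
Blood disorder,3,19,pearson,2.751
Intestinal obstruction,0,16,fisher,
Disease progression,202,662,pearson,35.809
Death,109,0,pearson,277.160
Pyrexia,40,9,pearson,65.371
General physical health deterioration,17,13,pearson,10.668
Mucosal inflammation,14,3,pearson,22.841
Ill-defined disorder,7,28,pearson,1.607
Oedema,3,7,fisher,
Cytokine release syndrome,17,3,pearson,29.697
Immunosuppression,13,0,fisher,
COVID-19,79,79,pearson,34.687
Sepsis,32,15,pearson,34.220
Septic shock,28,2,pearson,59.353
Infection,17,19,pearson,5.430
Bacterial infection,14,6,pearson,15.775
Fungal infection,12,8,pearson,8.921
Urosepsis,11,9,pearson,6.221
Candida infection,11,1,fisher,
Bacteraemia,11,0,fisher,
Tooth abscess,11,0,fisher,
Infected skin ulcer,10,0,fisher,
Cytomegalovirus infection,9,8,pearson,4.454
COVID-19 pneumonia,7,3,fisher,
Cytomegalovirus infection reactivation,2,37,pearson,11.546
Neutropenic sepsis,0,15,fisher,
Neutropenic infection,0,14,fisher,
Candida pneumonia,4,6,fisher,
Varicella zoster virus infection,2,8,fisher,
C-reactive protein increased,15,14,pearson,6.877
Inflammatory marker increased,11,0,fisher,
Haemoglobin decreased,2,22,pearson,5.320
Blood bilirubin increased,0,22,pearson,9.416
Blood lactate dehydrogenase increased,48,124,pearson,0.291
Aspartate aminotransferase increased,5,17,pearson,0.517
Alanine aminotransferase increased,5,14,pearson,0.104
Glomerular filtration rate decreased,1,12,fisher,
Hypercalcaemia,11,10,pearson,5.254
Neuropathy peripheral,14,13,pearson,6.468
Confusional state,13,6,pearson,13.827
Epilepsy,11,0,fisher,
Immune effector cell-associated neurotoxicity syndrome,11,0,fisher,
Polyneuropathy,0,12,fisher,
Disturbance in attention,5,5,fisher,
Neurotoxicity,2,15,pearson,2.643
Renal failure,20,12,pearson,16.852
Respiratory failure,6,9,fisher,
Deep vein thrombosis,1,19,pearson,5.911
Haemorrhage,9,5,fisher,
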