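pt	soc
Neutropenia	Blood and lymphatic system disorders
Pancytopenia	Blood and lymphatic system disorders
Thrombocytopenia	Blood and lymphatic system disorders
Anaemia	Blood and lymphatic system disorders
Febrile neutropenia	Blood and lymphatic system disorders
Cytopenia	Blood and lymphatic system disorders
Blood disorder	Blood and lymphatic system disorders
Leukopenia	Blood and lymphatic system disorders
Haematotoxicity	Blood and lymphatic system disorders
Myelosuppression	Blood and lymphatic system disorders
Intestinal obstruction	Gastrointestinal disorders
Disease progression	General disorders and administration site conditions
Death	General disorders and administration site conditions
Pyrexia	General disorders and administration site conditions
Ill-defined disorder	General disorders and administration site conditions
General physical health deterioration	General disorders and administration site conditions
Mucosal inflammation	General disorders and administration site conditions
Oedema	General disorders and administration site conditions
Cytokine release syndrome	Immune system disorders
Immunosuppression	Immune system disorders
COVID-19	Infections and infestations
Sepsis	Infections and infestations
Cytomegalovirus infection reactivation	Infections and infestations
Infection	Infections and infestations
Septic shock	Infections and infestations
Urosepsis	Infections and infestations
Bacterial infection	Infections and infestations
Fungal infection	Infections and infestations
Cytomegalovirus infection	Infections and infestations
Neutropenic sepsis	Infections and infestations
Neutropenic infection	Infections and infestations
Candida infection	Infections and infestations
Bacteraemia	Infections and infestations
Tooth abscess	Infections and infestations
COVID-19 pneumonia	Infections and infestations
Candida pneumonia	Infections and infestations
Infected skin ulcer	Infections and infestations
Varicella zoster virus infection	Infections and infestations
Blood lactate dehydrogenase increased	Investigations
C-reactive protein increased	Investigations
Haemoglobin decreased	Investigations
Aspartate aminotransferase increased	Investigations
Blood bilirubin increased	Investigations
Alanine aminotransferase increased	Investigations
Glomerular filtration rate decreased	Investigations
Inflammatory marker increased	Investigations
Hypercalcaemia	Metabolism and nutrition disorders
Neuropathy peripheral	Nervous system disorders
Confusional state	Nervous system disorders
Neurotoxicity	Nervous system disorders
Polyneuropathy	Nervous system disorders
Immune effector cell-associated neurotoxicity syndrome	Nervous system disorders
Epilepsy	Nervous system disorders
Disturbance in attention	Nervous system disorders
Renal failure	Renal and urinary disorders
Respiratory failure	Respiratory, thoracic and mediastinal disorders
Deep vein thrombosis	Vascular disorders
Haemorrhage	Vascular disorders
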