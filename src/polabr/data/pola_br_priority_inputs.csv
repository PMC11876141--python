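soc,pt,n,ror025,deaths,medical_event,evidence
Blood and lymphatic system disorders,Neutropenia,102,7.19,20,IME,++
Blood and lymphatic system disorders,Pancytopenia,54,11.12,17,DME,++
Blood and lymphatic system disorders,Thrombocytopenia,53,4.90,10,IME,++
Blood and lymphatic system disorders,Anaemia,52,2.79,14,NA,++
Blood and lymphatic system disorders,Febrile neutropenia,45,6.16,12,DME,++
Blood and lymphatic system disorders,Cytopenia,31,16.95,2,IME,+
Blood and lymphatic system disorders,Blood disorder,22,23.09,3,NA,++
Blood and lymphatic system disorders,Leukopenia,17,2.68,3,IME,+
Blood and lymphatic system disorders,Haematotoxicity,16,13.23,0,NA,++
Blood and lymphatic system disorders,Myelosuppression,15,3.15,0,IME,++
Gastrointestinal disorders,Intestinal obstruction,16,3.06,0,IME,+
General disorders and administration site conditions,Disease progression,864,193.80,120,NA,-
General disorders and administration site conditions,Death,109,1.51,109,IME,-
General disorders and administration site conditions,Pyrexia,49,1.29,8,NA,++
General disorders and administration site conditions,Ill-defined disorder,35,3.67,7,NA,-
General disorders and administration site conditions,General physical health deterioration,30,2.20,8,NA,+
General disorders and administration site conditions,Mucosal inflammation,17,5.40,0,NA,+
General disorders and administration site conditions,Oedema,10,1.46,3,NA,++
Immune system disorders,Cytokine release syndrome,20,6.94,0,IME,+
Immune system disorders,Immunosuppression,13,9.23,1,IME,+
Infections and infestations,COVID-19,158,4.59,47,NA,+
Infections and infestations,Sepsis,47,4.26,16,IME,++
Infections and infestations,Cytomegalovirus infection reactivation,39,59.04,2,IME,+
Infections and infestations,Infection,36,2.00,12,NA,++
Infections and infestations,Septic shock,30,6.56,15,IME,++
Infections and infestations,Urosepsis,20,16.94,11,IME,+
Infections and infestations,Bacterial infection,20,8.26,14,NA,+
Infections and infestations,Fungal infection,20,4.69,2,NA,+
Infections and infestations,Cytomegalovirus infection,17,7.47,2,IME,+
Infections and infestations,Neutropenic sepsis,15,15.56,0,DME,++
Infections and infestations,Neutropenic infection,14,150.77,0,DME,++
Infections and infestations,Candida infection,12,4.01,8,NA,+
Infections and infestations,Bacteraemia,11,6.26,11,IME,+
Infections and infestations,Tooth abscess,11,6.66,0,IME,+
Infections and infestations,COVID-19 pneumonia,10,2.42,7,IME,++
Infections and infestations,Candida pneumonia,10,223.88,0,IME,+
Infections and infestations,Infected skin ulcer,10,36.23,0,NA,+
Infections and infestations,Varicella zoster virus infection,10,24.79,1,NA,+
Investigations,Blood lactate dehydrogenase increased,172,165.00,36,NA,+
Investigations,C-reactive protein increased,29,4.92,8,NA,+
Investigations,Haemoglobin decreased,24,1.98,0,NA,++
Investigations,Aspartate aminotransferase increased,22,4.15,5,NA,++
Investigations,Blood bilirubin increased,22,8.81,0,NA,-
Investigations,Alanine aminotransferase increased,19,2.84,5,NA,++
Investigations,Glomerular filtration rate decreased,13,6.61,1,NA,+
Investigations,Inflammatory marker increased,11,10.75,0,NA,+
Metabolism and nutrition disorders,Hypercalcaemia,21,13.38,5,NA,+
Nervous system disorders,Neuropathy peripheral,27,2.21,7,IME,++
Nervous system disorders,Confusional state,19,1.07,8,NA,+
Nervous system disorders,Neurotoxicity,17,6.69,0,IME,++
Nervous system disorders,Polyneuropathy,12,6.11,0,IME,+
Nervous system disorders,Immune effector cell-associated neurotoxicity syndrome,11,14.03,1,IME,+
Nervous system disorders,Epilepsy,11,2.78,0,IME,+
Nervous system disorders,Disturbance in attention,10,1.49,5,NA,+
Renal and urinary disorders,Renal failure,32,1.62,12,DME,+
"Respiratory, thoracic and mediastinal disorders",Respiratory failure,15,1.90,2,IME,+
Vascular disorders,Deep vein thrombosis,20,4.07,1,IME,+
Vascular disorders,Haemorrhage,14,1.02,5,IME,++
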