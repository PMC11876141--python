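Neutropenia
Thrombocytopenia
Cytopenia
Leukopenia
Myelosuppression
Intestinal obstruction
Death
Cytokine release syndrome
Immunosuppression
Sepsis
Cytomegalovirus infection reactivation
Septic shock
Urosepsis
Cytomegalovirus infection
Bacteraemia
Tooth abscess
COVID-19 pneumonia
Candida pneumonia
Neuropathy peripheral
Neurotoxicity
Polyneuropathy
Immune effector cell-associated neurotoxicity syndrome
Epilepsy
Respiratory failure
Deep vein thrombosis
Haemorrhage
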