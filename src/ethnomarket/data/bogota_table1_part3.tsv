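family	scientific_name	vernacular	uses	markets
Verbenaceae	Aloysia citriodora Paláu	Cidrón	Blood and circulatory system (Circulatory stimulant, Heart diseases); Dental health (Toothache); Digestive system (Digestive problems, Flatulence, Gastrointestinal disorders, Indigestion, Stomach problems); Infections and infestations (Rabies); Nervous system and mental health (Depression, Nerves, Sedative, Stress, Tranquilizer); Non-specific symptoms and general illnesses (Seizures, Spasms); Respitarory system (Expectorant)	Plaza Central de Corabastos; Plaza de El Carmen; Plaza de Las Ferias; Plaza de Mercado de Armenia (Quindío); Plaza de Mercado de Girardot (Cundinamarca); Plaza de Mercado Trinidad-Galán; Plaza de Paloquemao; Plaza de San Benito; Plaza del 20 de Julio; Plaza del 7 de Agosto; Plaza del Restrepo; Plaza Santander
Verbenaceae	Bouchea prismatica (L.) Kuntze	Arrocillo	Digestive system (Rectal problems); Infections and infestations (Malaria, Typhus); Non-specific symptoms and general illnesses (Analgesic); Skin and subcutaneous tissue (Skin Tonic)	Plaza Central de Corabastos
Verbenaceae	Lantana camara L.	Sanguinaria / Venturosa / Sanguinaria	Blood and circulatory system (Blood cleansing, High blood pressure, Varicose veins); Digestive system (Indigestion, Liver problems, Stomach problems); Non-specific symptoms and general illnesses (Analgesic, Fever, Promotes sweating, Spasms); Pregnancy, childbirth and child-bed (Breast care); Reproductive system and sexual health (Emenagogue); Respitarory system (Expectorant, Flu); Urinary system (Diuretic)	Plaza Boyacá; Plaza del 20 de Julio; Plaza del Restrepo; Plaza Samper Mendoza
Verbenaceae	Lantana canescens Kunth	Zorrillo	Non-specific symptoms and general illnesses (Fever); Reproductive system and sexual health (Emenagogue, Uterine diseases); Respitarory system (Bronchitis)	Plaza de Mercado de Armenia (Quindío)
Verbenaceae	Lantana trifolia L.	Venturosa	Muscular-skelettal system (Rheumatism); Non-specific symptoms and general illnesses (Promotes sweating); Reproductive system and sexual health (Emenagogue)	Plaza del 12 de Octubre
Verbenaceae	Lippia alba (Mill.) N.E. Br. ex Britton & P. Wilson	Curalotodo / Pronto alivio / Prontoalivio	Digestive system (Colic, Digestive problems, Flatulence, Indigestion, Stomach problems); Endocrine system (Diabetes); Muscular-skelettal system (Arthritis, Bone pain, Rheumatism); Nervous system and mental health (Nerves, Sedative, Tranquilizer); Non-specific symptoms and general illnesses (Analgesic, Fever, Headache, Promotes sweating, Spasms, Stomach ache); Reproductive system and sexual health (Emenagogue, Menstrual colic); Respitarory system (Asthma, Bronchial diseases, Cough, Flu, Sinusitis)	Plaza de El Carmen; Plaza de Fontibón; Plaza de Kennedy; Plaza de La Perseverancia; Plaza de Las Cruces; Plaza de Mercado Trinidad-Galán; Plaza del 12 de Octubre; Plaza del Lucero; Plaza Santander
Verbenaceae	Lippia hirsuta L.f.	Bunquín	Infections and infestations (Tuberculosis); Non-specific symptoms and general illnesses (Spasms); Reproductive system and sexual health (Emenagogue); Respitarory system (Asthma, Bronchitis, Expectorant, Lung diseases)	Plaza Central de Corabastos
Verbenaceae	Verbena officinalis L.	Verbena	Blood and circulatory system (High blood pressure); Digestive system (Diarrhea, Gallbladder, Stomach ache); Infections and infestations (Typhus); Non-specific symptoms and general illnesses (Analgesic, Headache, Tumors); Skin and subcutaneous tissue (Healing wounds)	Plaza de San Carlos; Plaza del Restrepo; Plaza Samper Mendoza
Violaceae	Viola odorata L.	Violeta	Non-specific symptoms and general illnesses (Fever); Respitarory system (Cough)	Plaza de Las Cruces
Vitaceae	Cissus verticillata (L.) Nicolson & C.E. Jarvis	Bejuco de Agua	Cultural illnesses (To make children walk (1-3 years)); Digestive system (Constipation, Digestive problems); Infections and infestations (Venereal diseases); Muscular-skelettal system (Muscular pain, Rheumatism); Non-specific symptoms and general illnesses (Analgesic, Inflammation, Promotes sweating); Pregnancy, childbirth and child-bed (Breast care); Respitarory system (Flu, Respiratory tract); Skin and subcutaneous tissue (Healing); Urinary system (Diuretic, Hemorrhoids)	Plaza de Mercado de Armenia (Quindío); Plaza Samper Mendoza
Winteraceae	Drimys granadensis L. f.	Canelón	Nervous system and mental health (Stimulant); Skin and subcutaneous tissue (Skin Tonic);Human food (Beberage)*	Plaza de Mercado Trinidad-Galán; Plaza de San Carlos
Winteraceae	Drimys winteri J.R. Forst. & G. Forst.	Canelo	Nervous system and mental health (Stimulant); Others (Tonic)	Plaza del 7 de Agosto
Xanthorrhoeaceae	Aloe vera (L.) Burm. f.	Sábila	Digestive system (Constipation); Infections and infestations (Leprosy); Reproductive system and sexual health (Dysmenorrhea, Emenagogue); Respitarory system (Bronchial diseases, Bronchitis, Cough, Expectorant, Pneumonia); Skin and subcutaneous tissue (Healing, Healing wounds, Skin diseases, Sweating); Toxic (Insecticide)*	Plaza Central de Corabastos; Plaza de El Carmen; Plaza de Kennedy; Plaza de Las Ferias; Plaza de San Benito; Plaza del 7 de Agosto
Zingiberaceae	Curcuma longa L.	Azafrán de raíz / Cúrcuma	Blood and circulatory system (Circulatory stimulant, Thrombosis); Digestive system (Indigestion, Liver cleaning); Endocrine system (Diabetes); Metabolism and nutrition (High cholesterol, Obesity, Strengthen inumosystem); Muscular-skelettal system (Arthritis); Non-specific symptoms and general illnesses (Cancer); Skin and subcutaneous tissue (Healing wounds); Urinary system (Kidney infection); Human food (Condiment)*	Plaza del Restrepo
Zingiberaceae	Elettaria cardamomum (L.) Maton	Cardamomo	Digestive system (Digestive problems); Nervous system and mental health (Stimulant); Non-specific symptoms and general illnesses (Lack of appetite); Respitarory system (Expectorant)	Plaza de Paloquemao; Plaza del 12 de Octubre
Zygophyllaceae	Bulnesia arborea (Jacq.) Engl.	Guayacán	Muscular-skelettal system (Rheumatism)	Plaza del Quirigua
Zygophyllaceae	Kallstroemia maxima (L.) Hook. & Arn.	Abrojo de patio / Verdolaga / Abrojo	Digestive system (Colon, Indigestion); Infections and infestations (Abscesses, Vermifuge); Others (Ceas smoke); Respitarory system (Bronchitis, Cough); Skin and subcutaneous tissue (Astringent, Pustules); Urinary system (Diuretic)	Plaza Boyacá; Plaza de El Carmen; Plaza de Las Cruces; Plaza de Mercado de Girardot (Cundinamarca); Plaza de Mercado Trinidad-Galán; Plaza de Paloquemao; Plaza del 20 de Julio; Plaza del 7 de Agosto; Plaza del Quirigua; Plaza Santander
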