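# Normalization rules for the Bogotá market-survey transcription.
#
# Category labels are kept verbatim in the transcription (including the
# source's typos); aliases resolve them to the canonical vocabulary of 19
# medicinal illness categories plus 4 non-medicinal ones.  The one-off labels
# "Sinusitis", "Astringent" and "Scabies" are filed by the semantics of the
# ailments they carry.  "Cultural" is treated as the emic medicinal category
# "Cultural illnesses" (see docs/methods.md for the rationale).
aliases:
  categories:
    "Respitarory system": "Respiratory system"
    "Muscular-skelettal system": "Muscular-skeletal system"
    "Skin and sub-cutaneous tissue": "Skin and subcutaneous tissue"
    "Food": "Human food"
    "Cultural": "Cultural illnesses"
    "Sinusitis": "Urinary system"
    "Astringent": "Skin and subcutaneous tissue"
    "Scabies": "Infections and infestations"
  families: {}
  # Two Market-column tokens in the source are species names, not markets;
  # mapping them to null drops them (logged) so the registry has 24 markets.
  markets:
    "Jacaranda caucana Pittier": null
    "Melissa officinalis L.": null

nonmedicinal_categories:
  - "Human food"
  - "Animal food"
  - "Toxic"
  - "Cosmetic"

category_registry:
  "Anti-venom": true
  "Blood and circulatory system": true
  "Cultural illnesses": true
  "Dental health": true
  "Digestive system": true
  "Endocrine system": true
  "Infections and infestations": true
  "Metabolism and nutrition": true
  "Muscular-skeletal system": true
  "Nervous system and mental health": true
  "Non-specific symptoms and general illnesses": true
  "Others": true
  "Pregnancy, childbirth and child-bed": true
  "Reproductive system and sexual health": true
  "Respiratory system": true
  "Sensory system": true
  "Skin and subcutaneous tissue": true
  "Urinary system": true
  "Veterinary": true
  "Human food": false
  "Animal food": false
  "Toxic": false
  "Cosmetic": false

family_merge:
  "Leguminosae-Caesalpinioideae": "Fabaceae"
  "Leguminosae-Mimosoideae": "Fabaceae"
  "Leguminosae-Papilionoideae": "Fabaceae"
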