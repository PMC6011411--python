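scientific_name	lic	introduced
Sambucus nigra L.	6.5	1
Matricaria chamomilla L.	6.3	1
Ocimum basilicum L.	5.7	1
Lippia alba (Mill.) N.E. Br. ex Britton & P. Wilson	5.2	0
Calendula officinalis L.	5.1	0
Ruta graveolens L.	5.0	1
Aloysia citriodora Paláu	4.9	0
Foeniculum vulgare Mill.	4.4	1
Trichanthera gigantea (Bonpl.) Nees	4.2	0
Juglans neotropica Diels	4.2	0
Persea americana Mill.	4.0	0
Allium sativum L.	4.0	1
Uncaria tomentosa (Willd.) DC.	3.9	0
Valeriana officinalis L.	3.5	1
Ambrosia peruviana Willd.	3.5	0
Equisetum bogotense Kunth	3.5	0
Columnea kalbreyeriana Mast.	3.4	0
Cymbopogon citratus (DC.) Stapf.	3.3	1
Petiveria alliacea L.	3.2	0
Lantana camara L.	3.2	0
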