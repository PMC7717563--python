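Anthrax	Anthrax
Avian influenza	Avian influenza
Bird flu	Avian influenza
Chikungunya	Chikungunya
Cholera	Cholera
COVID-19	COVID-19
Crimean-Congo haemorrhagic fever	Crimean-Congo haemorrhagic fever
Dengue	Dengue
Dengue fever	Dengue
Diphtheria	Diphtheria
Ebola	Ebola virus disease
Ebola virus disease	Ebola virus disease
Hepatitis E	Hepatitis E
Lassa fever	Lassa fever
Leptospirosis	Leptospirosis
Malaria	Malaria
Marburg virus disease	Marburg virus disease
Measles	Measles
Meningitis	Meningitis
MERS	Middle East respiratory syndrome
Middle East respiratory syndrome	Middle East respiratory syndrome
Monkeypox	Mpox
Mpox	Mpox
Nipah virus infection	Nipah virus infection
Nipah	Nipah virus infection
Plague	Plague
Poliomyelitis	Poliomyelitis
Polio	Poliomyelitis
Rabies	Rabies
Rift Valley fever	Rift Valley fever
Typhoid fever	Typhoid fever
Yellow fever	Yellow fever
Zika	Zika virus disease
Zika virus disease	Zika virus disease
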