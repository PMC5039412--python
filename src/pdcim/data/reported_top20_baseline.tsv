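rank	drug	disease	score	curated_mark
1	Gonadorelin	Endometriosis, Susceptibility To, 1	0.997	inferred
2	Escitalopram	Alcohol Dependence	0.997	inferred
3	Escitalopram	Encephalopathy With Intracranial Calcification, Growth Hormone Deficiency	0.997	inferred
4	Gonadorelin	Pyogenic Sterile Arthritis, Pyoderma Gangrenosum, And Acne	0.997	inferred
5	Levofloxacin	Helicobacter Pylori Infection, Susceptibility To	0.997	none
6	Levonorgestrel	Acroosteolysis With Osteoporosis And Changes In Skull And Mandible	0.997	none
7	Betamethasone	Asthma, Nasal Polyps, And Aspirin Intolerance	0.997	inferred
8	Gonadorelin	Leiomyoma, Uterine; Ul	0.997	inferred
9	Escitalopram	Encephalopathy, Acute Necrotizing 1, Susceptibility To; Ane1	0.997	none
10	Gonadorelin	Polyps, Multiple And Recurrent Inflammatory Fibroid, Gastrointestinal	0.997	none
11	Gonadorelin	Prostate Cancer, Hereditary, 1; Hpc1	0.997	T
12	Escitalopram	Spastic Paraplegia, Optic Atrophy, And Dementia	0.997	inferred
13	Escitalopram	Peripheral Neuropathy, Ataxia, Focal Necrotizing Encephalopathy, And Spongy Degeneration Of Brain	0.997	none
14	Ofloxacin	Asthma, Nasal Polyps, And Aspirin Intolerance	0.997	inferred
15	Leuprolide	Hypogonadotropic Hypogonadism	0.997	inferred
16	Betamethasone	Growth Retardation, Small And Puffy Hands And Feet, And Eczema	0.997	T
17	Medroxyprogesterone	Breast Cancer	0.997	M&T
18	Betamethasone	Mismatch Repair Cancer Syndrome	0.997	none
19	Prednisolone	Asthma, Nasal Polyps, And Aspirin Intolerance	0.997	T
20	Escitalopram	Panic Disorder 1; Pand1	0.997	M&T
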