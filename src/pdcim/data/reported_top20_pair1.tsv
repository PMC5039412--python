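rank	drug	disease	score	curated_mark
1	trifluoperazine	Basal Ganglia Diseases	7.36	M
2	thorazine	Basal Ganglia Diseases	7.15	M&T
3	perphenazine	Basal Ganglia Diseases	7.01	M
4	trifluoperazine	Movement Disorders	6.92	M
5	trifluoperazine	Dyskinesia, Drug-Induced	6.81	M
6	trifluoperazine	Parkinson Disease, Secondary	6.73	M
7	Thorazine	Movement Disorders	6.71	M&T
8	Thorazine	Dyskinesia, Drug-Induced	6.62	M&T
9	prochlorperazine	Tremor	6.59	none
10	perphenazine	Movement Disorders	6.56	M&T
11	Thorazine	Parkinson Disease, Secondary	6.54	M
12	thioridazine	Basal Ganglia Diseases	6.44	M
13	perphenazine	Dyskinesia, Drug-Induced	6.43	M
14	perphenazine	Parkinson Disease, Secondary	6.36	M
15	prochlorperazine	Parkinsonian Disorders	6.34	M
16	perphenazine	Tremor	6.22	M
17	trifluoperazine	Tremor	6.22	M
18	Thorazine	Tremor	6.18	M
19	fluphenazine	Parkinsonian Disorders	6.06	inferred
20	prochlorperazine	Basal Ganglia Diseases	6.03	M
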