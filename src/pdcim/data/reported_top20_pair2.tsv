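rank	drug	disease	score	curated_mark
1	chlorpromazine	Psychotic Disorders	5.36	T
2	chlorpromazine	Schizophrenia	5.19	T
3	chlorpromazine	Psychoses, Substance-Induced	5.19	M&T
4	perphenazine	Schizophrenia	5.15	T
5	Thorazine	Bipolar Disorder	5.07	M&T
6	thiothixene	Psychotic Disorders	4.91	M&T
7	trifluoperazine	Psychotic Disorders	4.72	T
8	trifluoperazine	Psychoses, Substance-Induced	4.58	M
9	trifluoperazine	Schizophrenia	4.57	T
10	thioridazine	Psychoses, Substance-Induced	4.56	none
11	trifluoperazine	Bipolar Disorder	4.54	T
12	fluphenazine	Psychotic Disorders	4.42	T
13	fluphenazine	Schizophrenia	4.24	T
14	fluphenazine	Bipolar Disorder	4.16	T
15	fluphenazine	Psychoses, Substance-Induced	4.10	M
16	thorazine	Lewy Body Disease	4.07	inferred
17	perphenazine	Bipolar Disorder	3.89	T
18	prochlorperazine	Bipolar Disorder	3.81	none
19	perphenazine	Psychotic Disorders	3.78	T
20	chlorpromazine	Alcohol Withdrawal Delirium	3.68	none
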