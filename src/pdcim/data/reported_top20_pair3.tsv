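rank	drug	disease	score	curated_mark
1	imipramine	Bipolar Disorder	8.80	M&T
2	amitriptyline	Bipolar Disorder	8.51	T
3	imipramine	Depressive Disorder, Major	7.96	M&T
4	amitriptyline	Depressive Disorder, Major	7.86	M&T
5	desipramine	Bipolar Disorder	7.38	M&T
6	amitriptyline	Depressive Disorder	6.93	M&T
7	imipramine	Depressive Disorder	6.67	T
8	amitriptyline	Mood Disorders	6.64	M&T
9	desipramine	Depressive Disorder, Major	6.62	T
10	nortriptyline	Bipolar Disorder	6.59	M
11	imipramine	Mood Disorders	6.47	T
12	amitriptyline	Personality Disorders	6.21	T
13	nortriptyline	Depressive Disorder, Major	6.21	M&T
14	amitriptyline	Anxiety Disorders	5.88	T
15	amitriptyline	Sleep Disorders, Circadian Rhythm	5.82	none
16	amitriptyline	Dyssomnias	5.77	M&T
17	desipramine	Depressive Disorder	5.49	M&T
18	desipramine	Mood Disorders	5.37	M
19	amitriptyline	Schizophrenia	5.32	T
20	imipramine	Depression, Postpartum	5.23	none
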