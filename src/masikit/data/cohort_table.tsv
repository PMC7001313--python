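case_id	age	sex	location	vaf_percent	rel_intensity
1	6	F	Pons	40.7
2	30	F	Insular gyrus	42.4	1.13
3	53	M	Brainstem, Temporal lobe	0.8	0.23
4	14	M	Spinal Cord	38.3	1.27
5	37	M	Brainstem	73.2	1.80
6	37	F	Thalamus, Ventricle, Midbrain	40.7	1.07
7	15	F	Basal ganglia	29.6
8	29	M	Thalamus	13.1	0.52
9	31	F	Thalamus	42.8
10	14	M	Spinal Cord	68.0	1.98
11	9	F	Brainstem	22.7	0.81
12	31	F	Brainstem, Thalamus, Cerebellum	79.9	1.50
13	14	M	Thalamus	49.6
14	24	M	Corpus callosum	43.0
15	21	M	Corpus callosum	65.9	1.09
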