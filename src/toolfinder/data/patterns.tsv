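pattern_id	label	slots	connectors
1	Drug for Disease	Drug|Disease	for
2	Edam Data/Format and Edam Operation	EDAM Data/Format|EDAM Operation	and
3	Patient took Drug for Disease	Patient|Drug|Disease	took|for
4	Finding with Organism Function	Finding|Organism Function	with
5	Drug for Disease in Body Part	Drug|Disease|Body Part	for|in
6	Finding in/with Medical Procedure	Finding|Medical Procedure	in/with
7	Drug for Symptom	Drug|Symptom	for
8	Edam Data in Body Part	EDAM Data/Format|Body Part	in
9	Patient has Disease in Body Part	Patient|Disease|Body Part	has|in
10	Patient took Drug for Disease in Body Part	Patient|Drug|Disease|Body Part	took|for|in
11	Patient took Drug for Body Part	Patient|Drug|Body Part	took|for
12	Patient has been in Medical Procedure	Patient|Medical Procedure	has been in
13	Patient has Disease	Patient|Disease	has
14	Patient has Organism Function	Patient|Organism Function	has
15	Disease in Body Part	Disease|Body Part	in
16	Drug for Edam Data in Body Part	Drug|EDAM Data/Format|Body Part	for|in
17	Patient's Finding	Patient|Finding	's
18	Drug & Drug for Disease	Drug|Drug|Disease	&|for
19	Patient took Vitamin	Patient|Vitamin	took
20	Symptom of Medical Procedure	Symptom|Medical Procedure	of
21	Patient has Symptom	Patient|Symptom	has
22	Drug for Edam Data	Drug|EDAM Data/Format	for
23	Patient ate Food	Patient|Food	ate
24	Edam Data/Format and Edam Operation and Edam Data/Format	EDAM Data/Format|EDAM Operation|EDAM Data/Format	and|and
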