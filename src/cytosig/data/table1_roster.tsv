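patient	age_years	mode_of_diagnosis	phenotype	allele_1	allele_2
1	<5	Genetic	Typical	c.304 C > T	c.1405A > G
2	<5	Genetic	Typical	c.406 - 2A > G	c.1336G > A
3	<5	Genetic	Typical	c.1017_1020delACGG	c.877 G > A
4	5-10	Genetic	Typical	c.984 + 1G > A	c.406 - 2A > G
5	5-10	Genetic	Typical	c.406 - 2A > G	c.964C > T
6	5-10	Genetic	Typical	c.694A > C	c.785T > C
7	11-15	Genetic	Typical	c.406 - 2A > G	c.406 - 2A > G
8	11-15	Genetic	Mild	c.406 - 2A > G	c.406 - 2A > G
9	11-15	Genetic	Typical	c.406 - 2A > G	c.406 - 2A > G
10	11-15	Genetic	Typical	c.406 - 2A > G	c.406 - 2A > G
11	11-15	Genetic and Corneal bx	Typical	c.406 - 2A > G	Not Identified
12	16-20	Genetic	Typical	c.236_237ins93	c.694A>C
13	16-20	Genetic	Typical	c.406 - 2A > G	c.406 - 2A > G
14	16-20	Genetic	Mild	c.236_237ins93	c.1207C > T
15	25-30	Clinical and Gastrin	Typical	Unknown	Unknown
16	25-30	Genetic	Typical	c.406 - 2A > G	c.406 - 2A > G
17	25-30	Genetic	Typical	c406 - 2A > G	c406 - 2A > G
18	25-30	Genetic	Mild	c.920delT	c.1615delG
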