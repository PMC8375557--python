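snp_name	ref_id	snp_position	ref_base	alt_base	female	male
1	ref32333	24	A	G	A/G	A/A
2	ref32333	26	T	A	T/A	T/T
3	ref68728	2	C	T	C/T	C/C
4	ref53064	3	C	T	C/T	C/C
5	ref107153	1	G	A	G/A	G/G
6	ref42855	9	A	C	C/C	A/A
7	ref125173	6	T	A	T/T	T/A
8	ref161496	8	G	T	G/G	G/T
9	ref86238	22	T	C	T/C	T/T
10	ref59409	3	T	C	T/C	T/T
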