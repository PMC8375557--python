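name	sex	raw_reads	raw_bases	clean_reads	tags	depth
F1	F	7416917	7211370	6997835	119303	39.37
F2	F	7416917	7211370	6977732	131127	36.83
F3	F	7416917	7211370	6964296	115465	40.94
F4	F	7416917	7211370	6962948	116298	40.65
F5	F	7416917	7211370	6973281	121724	37.85
F6	F	7915473	7696999	7465187	119963	41.41
F7	F	7915473	7696999	7475314	131311	38.88
F8	F	7915473	7696999	7432458	116989	42.4
F9	F	7915473	7696999	7440918	118280	42.67
F10	F	7915473	7696999	7435674	123705	40.27
M1	M	5672850	5486113	5343733	116336	31.43
M2	M	5672850	5486113	5341739	126894	29.32
M3	M	5672850	5486113	5318442	111114	33
M4	M	5672850	5486113	5307239	111615	33.18
M5	M	5672850	5486113	5282468	115196	30.92
M6	M	6531661	6290517	6072984	118336	34.98
M7	M	6531661	6290517	6095777	127515	33.51
M8	M	6531661	6290517	6105512	111501	37.54
M9	M	6531661	6290517	6077488	112770	36.65
M10	M	6531661	6290517	6045703	119547	34.15
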