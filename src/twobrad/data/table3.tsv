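tag_name	ref_id	sequence
Female-tag 1	ref7866-1	AACTCTGGAACCTTCCCTCCATCTTCC
Female-tag 2	ref62548-1	CCAAAAGCTACTTCATCTCCTGCAAGG
Female-tag 3	ref72559-1	CCTTACATTACGCTTTCTCCGACTGGC
Female-tag 4	ref75945-1	CGGCGGAAGACCGGAGCTCCATGTCAT
Female-tag 5	ref78854-1	CTAGATCTAACCTAGTCTCCTATGTTT
Female-tag 6	ref80771-1	CTCCACAGTACTTGTACTCCTTGACTC
Female-tag 7	ref102102-1	GCCTGGAGCACTGAATCTCCGTGCAAA
Female-tag 8	ref106304-1	GGACCTTTCACCTCTTCTCCTGTATGA
Female-tag 9	ref110721-1	GGTAGGAGCACTTTACCTCCCTCCTAA
Female-tag 10	ref129620-1	TATAGTTTTACCTTTTCTCCTTGTTCT
Female-tag 11	ref155669-1	TGTTTGCTCACTGGAGCTCCTTATGGA
Female-tag 12	ref159947-1	TTCAGAAAAACACTAGCTCCCTAAGAC
Female-tag 13	ref161941-1	TTCTAGAAAACTCTCACTCCACGAAAA
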