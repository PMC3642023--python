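chrom	start	end	type	sample	n_snps	start_snp	end_snp	expected_length
chr1	193577075	193861997	del	10	44	rs1359381	rs12745696	284923
chr1	193577075	193861997	del	4	44	rs1359381	rs12745696	284923
chr1	193577075	193861997	del	2	44	rs1359381	rs12745696	284923
chr13	26048387	26099109	dup	7	10	rs2133814	rs7986966	50723
chr13	26048387	26099109	dup	10	10	rs2133814	rs7986966	50723
chr13	26048387	26099109	dup	6	10	rs2133814	rs7986966	50723
chr13	26048387	26099109	dup	8	10	rs2133814	rs7986966	50723
chr13	26048387	26099109	dup	1	10	rs2133814	rs7986966	50723
chr2	41082092	41099005	del	6	11	rs12474136	rs2373974	16914
chr2	41082092	41099005	del	8	11	rs12474136	rs2373974	16914
chr2	41082092	41099005	del	3	11	rs12474136	rs2373974	16914
chr2	41082092	41099005	del	2	11	rs12474136	rs2373974	16914
chr8	3753745	3763223	del	5	14	rs2930372	rs1464619	9479
chr8	3753745	3763223	del	7	14	rs2930372	rs1464619	9479
chr8	3753745	3763223	del	4	14	rs2930372	rs1464619	9479
chr8	3753745	3763223	del	6	14	rs2930372	rs1464619	9479
chr8	3753745	3763223	del	8	14	rs2930372	rs1464619	9479
chr8	3753745	3763223	del	3	14	rs2930372	rs1464619	9479
chr8	3753745	3763223	del	1	14	rs2930372	rs1464619	9479
chrX	22775615	22833684	del	5	14	rs7889437	rs5970944	58070
chrX	22775615	22833684	del	7	14	rs7889437	rs5970944	58070
chrX	22775615	22833684	del	4	14	rs7889437	rs5970944	58070
chrX	22775615	22833684	del	3	14	rs7889437	rs5970944	58070
chrX	22775615	22833684	del	2	14	rs7889437	rs5970944	58070
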