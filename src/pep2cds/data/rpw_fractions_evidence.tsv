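fraction_id	technique	sequences
# Peptide sequences determined from the antibacterial hemolymph fractions of
# Rhynchophorus ferrugineus (Edman N-terminal reads, X = undetermined cycle;
# MS = internal tryptic peptides). Printed in the numbered, space-blocked style.
1.1	N-terminal	1.ETKQLNWQPK DDNQP
2.1	N-terminal	1.ATXDLLSFEV KGFKLNDSA
3.1	N-terminal	1.LTIEESKEKF KKAHEKXNAD VSTKL
3.2	MS	1.DTPEQTSIDL DACLRK2.HMLCMMQGIG AVTSDGHISQ DGVK
3.3	N-terminal	1.ATXDLLSFEA FGIKLNDSA
# 3.4: impossible for identification (blocked N-terminus, MS failed) - no record
4.1	MS	1.VSHILKDCAV AK2.HVVSDESKVS HILK3.DTPEQTSIDL DACLRK4.DCAVAKDTPE QTSIDLDACL R5.HMLCMMQGIG AVTSDGHISQ DGVK
4.2	N-terminal	1.GWLKKQLKSV EKGVRRVRD
4.3	N-terminal	1.DHVQVRYDNV HKNXQKDPAL YVDDA
4.4	N-terminal	1.DHVQVRYDNV HKNXQKDPAL
4.5	N-terminal	1.LEPNAAAARE SQEKLKQAHQ
4.6	N-terminal	1.LEPNAAAARE SQEKLKQAHQ
4.7	MS	1.DTPEQTSIDL DACLRK2.DCAVAKDTPE QTSIDLDACL R3.HMLCMMQGIG AVTSDGHISQ DGVK4.IDEEVFQKLD QNEPVDLPPN FGK
4.8	N-terminal	1.DHVQVRYDNV HKNXQKDPAL YVDDA
4.9	N-terminal	1.DHVQVRYDNV HKNXQKDPAL YV
5.1	N-terminal	1.ATTKSSWNSV HQAXQAKPGV FVDD
5.2	N-terminal	1.ATTKSSWNSV HQAXQAKPGV FVDDA
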