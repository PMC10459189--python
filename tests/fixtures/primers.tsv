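name	sequence
GmLox1-snp-F	AGCTTTGGTTGATTTTCTCACAGGT
GmLox1-snp-R	CGGGGATTCCCATGCTTCCG
GmLox1-del-F	CGAGGTAAACATGCGAAGCG
GmLox1-del-R	GCAGCCCATATCTCCAGTCC
GmLox2-snp-F	TGCCACATCCTGCTGGGGA
GmLox2-snp-R	CCGCTGAAGACATCTCAACGGAA
GmLox3-del-F	TACCACCAGGGGCTGTGCTT
GmLox3-del-R	GAAGACACACAAGGAGGACACGC
GmLox1-qPCR-F	ATTGGTTAAATACTCATGCGGC
GmLox1-qPCR-R	CCGAAGACATCTCCACAGAATA
GmLox2-qPCR-F	TCCTGAACAGAGGAGGAGGG
GmLox2-qPCR-R	GTGCCTATGAGTCCCCCAAC
GmLox3-qPCR-F	GCTTGGGGGTCTTCTCCATAG
GmLox3-qPCR-R	GCTGGAGAGACACGGATCG
GmCYP2-qPCR-F	CAAAAACCCTGTCACGCAGT
GmCYP2-qPCR-R	CACTTTCTCTCAAGGGCACCA
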