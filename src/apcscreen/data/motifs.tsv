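# name	iupac
AP-1	TGASTCA
TCF7L2	WWCAAAG
SP1	KGGGCGGRRY
USF1/2	CACGTG
NRF1	GCGCRYGCGC
EGR-1	GCGKGGGCG
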