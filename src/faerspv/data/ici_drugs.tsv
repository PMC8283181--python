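generic	brands	target_class
nivolumab	opdivo	PD-1
pembrolizumab	keytruda	PD-1
cemiplimab	libtayo	PD-1
atezolizumab	tecentriq	PD-L1
avelumab	bavencio	PD-L1
durvalumab	imfinzi	PD-L1
ipilimumab	yervoy	CTLA-4
tremelimumab		CTLA-4
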