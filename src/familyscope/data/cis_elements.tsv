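name	consensus	source
DPBFCOREDCDC3	ACACNNG	PLACE S000292
ABRELATERD1	ACGTG	PLACE S000414
ERELEE4	AWTTCAAA	PLACE S000037
PREATPRODH	ACTCAT	PLACE S000450
DRECRTCOREAT	RCCGAC	PLACE S000418
WBOXNTERF3	TGACY	PLACE S000457
WBOXATNPR1	TTGAC	PLACE S000390
MYBCORE	CNGTTR	PLACE S000176
GT1CONSENSUS	GRWAAW	PLACE S000198
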