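population	n	p50	p90	p95	p99
AA	889	-0.39	0.67	0.82	2.32
EA	1433	-0.39	0.24	0.82	3.24
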