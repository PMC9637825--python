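subject	condition	learner	intensity	unpleasantness
S1	ACCD	0	5	7
S2	ACCD	0	5	5
S3	ACCD	1	6	6
S4	ACCD	1	5	6
S5	ACCD	1	7	7
S6	ACCD	1	5	5
S7	ACCD	1	5	5
S8	ACCD	0	4.5	7.5
S9	ACCD	0	7.5	7.5
S10	ACCD	1	7	6
S1	ACCU	1	7	10
S2	ACCU	1	5	5
S3	ACCU	0	5	6
S4	ACCU	1	4	4
S5	ACCU	0	6	6
S6	ACCU	1	6	7
S7	ACCU	0	6	5
S8	ACCU	0	2.5	5.5
S9	ACCU	1	5	5
S10	ACCU	0	5	6
S1	INSD	0	5	5
S2	INSD	1	4	4
S3	INSD	1	5	6
S4	INSD	1	5	5
S5	INSD	1	6	6
S6	INSD	1	4	6
S7	INSD	0	5	4
S8	INSD	1	4.5	7.5
S9	INSD	1	7	7
S10	INSD	1	5	4
S1	INSU	1	6	8
S2	INSU	1	5	5
S3	INSU	0	5	6
S4	INSU	1	5	6
S5	INSU	0	6	6
S6	INSU	1	4	5
S7	INSU	1	5	4
S8	INSU	0	3.5	6.5
S9	INSU	0	5	5
S10	INSU	0	9	9
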