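sequence_id	TRUTH
sp1_1	SP_1
sp1_2	SP_1
sp1_3	SP_1
sp1_4	SP_1
sp1_5	SP_1
sp1_6	SP_1
sp1_7	SP_1
sp1_8	SP_1
sp2_1	SP_2
sp2_2	SP_2
sp2_3	SP_2
sp2_4	SP_2
sp2_5	SP_2
sp2_6	SP_2
sp2_7	SP_2
sp2_8	SP_2
sp3_1	SP_3
sp3_2	SP_3
sp3_3	SP_3
sp3_4	SP_3
sp3_5	SP_3
sp3_6	SP_3
sp3_7	SP_3
sp3_8	SP_3
sp4_1	SP_4
sp4_2	SP_4
sp4_3	SP_4
sp4_4	SP_4
sp4_5	SP_4
sp4_6	SP_4
sp4_7	SP_4
sp4_8	SP_4
sp5_1	SP_5
sp5_2	SP_5
sp5_3	SP_5
sp5_4	SP_5
sp5_5	SP_5
sp5_6	SP_5
sp5_7	SP_5
sp5_8	SP_5
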