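segment,mean_transverse_mm,sd_transverse_mm,mean_ap_mm,sd_ap_mm,n_subjects
C1,11.3,1.7,8.3,1.6,26
C2,11.5,1.9,8.2,1.6,181
C3,12,2.3,8,1.6,318
C4,12.8,2.4,7.7,1.7,362
C5,13.3,2.2,7.4,1.6,234
C6,13.1,1.9,7,1.6,438
C7,12.5,1.9,6.9,1.6,488
C8,11.3,2.2,6.8,1.6,336
T1,10.7,2.3,6.9,1.6,316
T2,10,2.3,6.9,1.7,27
T3,9.6,2,6.8,1.8,131
T4,9.5,1.9,6.6,1.9,131
T5,9.2,2.4,6.4,1.9,65
T6,8.7,3,6.4,1.9,65
T7,8.4,2.7,6.3,2,167
T8,8.3,2.1,6.3,2,77
T9,8.6,1.7,6.5,2,65
T10,8.6,1.8,6.5,2,65
T11,8.3,2.1,6.4,1.9,65
T12,8.2,2.1,6.4,1.8,27
L1,8.6,1.9,6.7,1.7,65
L2,9.1,1.6,7.2,1.6,27
L3,9.4,1.5,7.5,1.6,77
L4,9.3,1.5,7.5,1.6,27
L5,8.8,1.7,7.1,1.8,27
S1,8.4,1.9,6.8,2,129
S2,7.1,2.5,5.8,2.4,65
S3,6.3,2.8,5.2,2.7,27
S4,5.5,3.2,4.6,2.9,15
S5,4.7,3.5,3.9,3.2,15
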