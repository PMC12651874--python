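subject_id,group,sex,age,bmi
C01,pd_control,F,59,24.8
C02,pd_control,M,70,25.5
C03,pd_control,M,76,26
C04,pd_control,M,69,26
C05,pd_control,F,79,23.4
C06,pd_control,M,56,27.5
E01,pd_tpei,M,47,23.2
E02,pd_tpei,M,60,33.5
E03,pd_tpei,M,40,18.3
E04,pd_tpei,M,47,26.8
E05,pd_tpei,F,36,18.7
E06,pd_tpei,M,75,24.9
H01,healthy,M,22,20.52
H02,healthy,F,23,23.44
H03,healthy,F,23,23.34
H04,healthy,M,24,30.12
H05,healthy,F,24,21.77
H06,healthy,M,26,23.51
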