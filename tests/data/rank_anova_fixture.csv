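tag_id,sex,phenotype,value
T001,F,high,10.1
T002,F,high,14.01
T003,F,high,14.49
T004,F,high,11.79
T005,F,high,12.04
T006,F,high,9.78
T007,F,high,8.71
T008,F,low,3.75
T009,F,low,3.5
T010,F,low,8.32
T011,F,low,5.86
T012,F,low,6.32
T013,F,low,4.4
T014,F,low,3.28
T015,M,high,13.0
T016,M,high,13.9
T017,M,high,17.5
T018,M,high,16.05
T019,M,high,14.86
T020,M,high,15.4
T021,M,high,12.43
T022,M,low,14.08
T023,M,low,7.96
T024,M,low,11.11
T025,M,low,16.34
T026,M,low,4.62
T027,M,low,7.48
T028,M,low,9.19
T029,M,low,11.29
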