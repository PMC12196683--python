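patient_id,session,age,sex,stroke_type,onset_days,fma_ue,paretic_side
S001,single,80,M,CI,11,58,R
S002,single,32,F,CI,11,50,R
S003,single,71,M,ICH,13,64,R
S004,single,52,F,CI,8,63,L
S005,single,82,M,CI,9,27,L
S006,single,81,M,ICH,5,16,R
S007,single,77,M,CI,9,60,R
S008,single,79,F,ICH,7,28,R
S009,single,65,M,ICH,5,55,R
S010,single,67,F,ICH,12,37,L
S011,single,66,M,CI,13,15,L
S012,single,64,F,ICH,33,35,L
S013,single,63,M,CI,13,59,R
S014,single,50,M,CI,19,22,R
S015,single,72,F,CI,16,52,R
S016,single,57,M,ICH,12,42,L
S017,single,57,M,ICH,18,8,L
S018,single,64,M,CI,9,60,R
S019,single,74,F,CI,12,9,L
S020,A,75,M,CI,24,10,L
S020,B,75,M,CI,45,10,L
S021,A,74,M,ICH,26,10,L
S021,B,74,M,ICH,34,13,L
S022,A,57,M,ICH,25,15,R
S022,B,57,M,ICH,34,24,R
S023,A,70,M,ICH,23,55,L
S023,B,70,M,ICH,31,56,L
S024,A,80,M,CI,34,47,L
S024,B,80,M,CI,47,54,L
S025,A,51,M,ICH,31,16,L
S025,B,51,M,ICH,50,17,L
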