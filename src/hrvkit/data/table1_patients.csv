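subject_id,sex,age,opioids,beta_blockers,vas_back_off,vas_back_on,vas_leg_off,vas_leg_on
A1,M,57,No,No,8.5,5.2,9.3,3.7
A2,F,65,Yes,Yes,10.0,10.0,4.3,9.3
A3,M,49,No,Yes,4.1,1.4,4.9,3.6
A4,F,72,Yes,Yes,7.8,5.1,7.8,5.4
A5,F,37,Yes,No,7.1,5.9,8.9,8.5
A6,M,57,No,No,4.3,1.4,4.3,1.5
A7,F,44,Yes,No,0.4,0.1,5.7,1.1
A8,F,53,No,No,3.8,3.3,6.4,1.4
A9,F,54,Yes,Yes,0.0,0.0,0.0,0.0
A10,F,60,No,No,6.1,4.1,6.8,3.3
A11,F,51,No,No,6.3,5.6,7.0,7.1
A12,F,54,Yes,No,9.7,1.3,9.8,5.9
A13,F,48,Yes,No,3.7,0.1,5.1,5.4
A14,F,57,No,Yes,6.7,6.9,4.6,4.9
A15,F,52,No,No,9.8,7.1,3.6,2.7
A16,M,46,Yes,Yes,6.9,7.5,6.8,3.3
A17,M,55,Yes,No,7.0,6.3,5.4,5.6
A18,F,59,No,No,4.3,0.2,3.5,0.1
A19,F,57,No,Yes,7.6,3.3,8.6,6.5
A20,M,58,Yes,No,5.8,5.2,9.4,7.1
A21,F,68,Yes,No,4.8,4.6,2.3,4.9
A22,F,59,Yes,Yes,5.3,1.5,4.2,0.4
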