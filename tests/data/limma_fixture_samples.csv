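sample_id,animal,time_h,batch
r1_t0,1,0.0,1
r1_t1,1,1.0,1
r1_t2,1,2.0,1
r1_t3,1,3.0,1
r1_t6,1,6.0,1
r1_t24,1,24.0,1
r2_t0,2,0.0,1
r2_t1,2,1.0,1
r2_t2,2,2.0,1
r2_t3,2,3.0,1
r2_t6,2,6.0,1
r2_t24,2,24.0,1
r3_t0,3,0.0,1
r3_t1,3,1.0,1
r3_t2,3,2.0,1
r3_t3,3,3.0,1
r3_t24,3,24.0,1
r4_t0,4,0.0,1
r4_t1,4,1.0,1
r4_t2,4,2.0,1
r4_t3,4,3.0,1
r4_t6,4,6.0,1
r4_t24,4,24.0,1
r5_t0,5,0.0,1
r5_t1,5,1.0,1
r5_t2,5,2.0,1
r5_t3,5,3.0,1
r5_t6,5,6.0,1
r5_t24,5,24.0,1
r6_t0,6,0.0,1
r6_t1,6,1.0,1
r6_t2,6,2.0,1
r6_t3,6,3.0,1
r6_t6,6,6.0,1
r6_t24,6,24.0,1
r7_t0,7,0.0,1
r7_t1,7,1.0,1
r7_t2,7,2.0,1
r7_t3,7,3.0,1
r7_t6,7,6.0,1
r7_t24,7,24.0,1
r8_t0,8,0.0,1
r8_t1,8,1.0,1
r8_t2,8,2.0,1
r8_t3,8,3.0,1
r8_t6,8,6.0,1
r8_t24,8,24.0,1
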