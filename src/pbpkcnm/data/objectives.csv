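patient_id,urine_CPT-11,urine_SN-38,urine_SN-38G,urine_NPC,urine_APC,feces_CPT-11,feces_SN-38+SN-38G,feces_NPC,feces_APC,cmax_CPT-11,cmax_SN-38,cmax_SN-38G,cmax_APC
1,23.2,0.4,3.1,0.1,2.3,45.3,11.9,1.9,11.6,1.53,0.04,0.09,0.19
2,25.5,0.5,3.4,0.2,2.5,43.5,11.4,1.8,11.2,1.53,0.04,0.09,0.19
3,35.5,0.7,4.8,0.2,3.5,35.4,9.3,1.5,9.1,1.53,0.04,0.09,0.19
4,26.3,0.5,3.6,0.2,2.6,42.7,11.2,1.8,11.0,1.53,0.04,0.09,0.19
5,17.8,0.3,2.4,0.1,1.8,49.6,13.1,2.1,12.7,1.53,0.04,0.09,0.19
6,28.1,0.5,3.8,0.2,2.8,41.4,10.9,1.7,10.6,1.53,0.04,0.09,0.19
7,30.0,0.6,4.0,0.2,3.0,39.9,10.5,1.7,10.2,1.53,0.04,0.09,0.19
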