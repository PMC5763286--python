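patient_id,sex,age,height_cm,weight_kg,bmi,dose_ug_per_kg,infusion_min,v_venous_blood,v_artery_blood,v_lung,v_heart,v_brain,v_muscle,v_adipose,v_skin,v_bone,v_kidney,v_spleen,v_pancreas,v_stomach,v_small_intestine,v_large_intestine,v_liver,q_lung,q_heart,q_brain,q_muscle,q_adipose,q_skin,q_bone,q_kidney,q_spleen,q_pancreas,q_stomach,q_small_intestine,q_large_intestine,q_liver_total,q_liver_artery
1,male,73,171.6,109.1,37.1,1000,90,12.8,8.1,11.6,3.8,13.8,290.8,469.0,41.7,106.3,3.9,2.2,1.7,1.5,6.5,3.7,21.2,54.9,2.3,7.0,9.9,2.9,2.9,2.9,11.9,1.8,0.6,0.6,5.8,2.3,14.9,3.8
2,male,67,169.4,89.1,31.0,1500,90,15.6,9.8,14.1,4.5,16.9,352.7,360.6,46.0,128.9,4.8,2.7,2.1,1.8,7.9,4.5,25.7,66.6,2.8,8.5,12.1,3.5,3.5,3.5,14.5,2.1,0.7,0.7,7.1,2.8,18.1,4.6
3,male,51,182.3,78.6,23.7,1700,90,18.7,11.7,16.9,5.4,19.2,422.4,240.0,50.3,154.4,5.7,3.2,2.5,2.2,9.5,5.4,30.8,79.8,3.4,10.2,14.4,4.2,4.2,4.2,17.3,2.5,0.8,0.8,8.5,3.4,21.7,5.5
4,male,70,182.5,98.2,29.5,1100,90,14.9,9.4,13.5,4.4,15.4,338.4,391.2,40.3,123.7,4.6,2.5,2.0,1.8,7.6,4.3,24.7,63.9,2.7,8.2,11.6,3.4,3.4,3.4,13.9,2.0,0.7,0.7,6.8,2.7,17.3,4.4
5,female,74,170.6,88.0,30.2,1400,90,12.3,7.7,11.9,3.9,15.4,238.4,516.4,38.1,107.3,4.7,2.6,2.0,1.9,8.2,4.9,22.4,64.7,3.5,8.3,7.8,5.9,3.5,3.5,13.2,2.1,0.7,0.7,7.6,3.5,18.7,4.5
6,female,52,169.4,52.7,18.4,2200,90,20.4,12.8,19.7,6.4,25.7,396.0,210.8,49.1,178.2,7.9,4.3,3.3,3.2,13.6,8.1,37.2,107.5,5.8,13.8,13.0,9.8,5.8,5.8,21.9,3.5,1.2,1.2,12.7,5.8,31.1,7.5
7,female,71,188.6,83.2,23.4,1400,90,14.0,8.8,13.5,4.4,16.3,271.9,452.6,40.7,122.3,5.4,2.9,2.3,2.2,9.3,5.6,25.5,73.8,4.0,9.5,8.9,6.7,4.0,4.0,15.0,2.4,0.8,0.8,8.7,4.0,21.4,5.1
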