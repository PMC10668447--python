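player_id,age,sex,days_since_injury,days_in_rehab,diagnosis,hemisphere,fim_motor,fim_cognition,fim_total,neglect_present,neglected_hemispace,clox,slct,alberts
9,52,Male,53,6,TBI,Bilateral,3.4,6.2,4.2,0,Right,0,1,0
10,59,Male,52,4,TBI,Left,6.5,5.8,6.3,0,,0,0,0
11,37,Male,37,7,TBI,Left,6.6,5.0,6.2,0,,0,0,0
12,83,Male,17,7,Stroke,Left,6.0,6.2,5.9,0,,0,0,0
13,65,Female,22,6,ABI,Right,5.0,5.6,5.1,0,,0,0,0
14,80,Female,15,7,Stroke,Right,1.6,4.0,2.3,0,,0,0,0
15,70,Male,23,14,ABI,Left,2.3,4.4,2.9,0,,0,0,0
16,68,Male,125,9,TBI,Bilateral,1.2,2.2,1.5,0,,0,0,0
17,47,Female,40,16,Stroke,Right,2.4,5.6,3.3,1,Left,1,1,1
18,47,Male,22,35,Stroke,Bilateral,5.3,7.0,5.8,0,,0,0,0
19,66,Male,57,53,Stroke,Right,2.0,2.8,2.2,1,Left,1,1,0
20,48,Male,27,15,Stroke,Right,3.9,6.4,4.6,0,,0,0,0
21,41,Female,42,3,Stroke,Right,1.5,5.4,2.6,1,Left,0,1,0
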