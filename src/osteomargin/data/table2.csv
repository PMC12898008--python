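id,margin_mm,operative_time_min,blood_loss_ml,msts,recurrence,metastasis,status
1,20,280,1000,21,no,no,alive
2,20,375,2000,30,no,yes,dead
3,20,180,800,25,no,no,alive
4,15,300,2400,27,no,no,alive
5,20,240,1000,30,no,no,alive
6,20,160,800,27,no,yes,dead
7,10,360,1500,26,no,no,alive
8,10,150,1200,27,no,no,alive
9,20,150,1200,28,no,no,alive
10,20,185,500,27,no,no,alive
11,20,344,2500,26,no,no,alive
12,20,180,400,28,no,no,alive
13,20,240,1400,27,no,no,alive
14,20,180,400,,no,no,alive
15,20,570,3000,28,no,no,alive
16,15,165,1200,27,no,no,alive
17,10,120,1000,27,no,no,alive
18,20,340,1000,25,no,no,alive
19,20,270,2500,26,no,no,alive
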