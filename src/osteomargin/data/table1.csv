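id,age,sex,resection_type,stage,histology,follow_up_months
1,60,male,IV,IIB,chordoma,86
2,56,male,II+III,IIB,osteosarcoma,17
3,39,female,I,IIB,peripheral nerve sheath tumor,62
4,51,female,II+III,3,giant cell tumor,62
5,66,male,III,IIB,spindle cell sarcoma,54
6,46,female,II,IIB,chondrosarcoma,50
7,45,female,I+II,3,giant cell tumor,47
8,57,female,I,3,giant cell tumor,43
9,45,female,III,IB,chondrosarcoma,35
10,40,female,III,IB,chondrosarcoma,31
11,22,female,II+III,IIB,Ewing sarcoma,31
12,49,female,I,3,chondromyxoid fibroma,28
13,39,female,III,IB,chondrosarcoma,26
14,57,male,I+II,IB,chondrosarcoma,25
15,19,male,I,IIB,Ewing sarcoma,25
16,49,male,IV,IB,chordoma,20
17,37,male,III,3,giant cell tumor,20
18,29,female,II+III,IIB,Ewing sarcoma,18
19,50,male,II,IB,chondrosarcoma,14
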