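image,expert_upper_t1,expert_upper_t2,expert_lower_t1,expert_lower_t2,expert_t1,expert_t2,novice_upper_t1,novice_upper_t2,novice_lower_t1,novice_lower_t2,novice_t1,novice_t2,mbr_upper,mbr_lower,mbr
1,T8,T8,L2,L2,-16.8,-16.9,T8,T8,L1,L1,-15.0,-15.2,T8,L5,-20.1
2,T6,T9,L1,L1,6.4,6.1,T10,T10,L1,L1,13.7,13.7,T6,T12,7.8
3,T2,T10,L1,L2,9.9,6.2,T4,T4,L2,L2,11.6,11.6,T3,L2,10.1
4,T9,T10,L4,L4,11.9,16.9,T9,T9,L4,L4,13.9,13.9,T11,L4,15.9
5,T11,T10,L4,L4,15.9,14.5,T11,T11,L4,L4,11.6,11.6,T12,L4,9.1
6,T11,T9,L4,L4,-19.2,-16.8,T10,T10,L4,L4,-15.1,-15.1,T11,L3,-15.1
7,T12,T11,L4,L4,-8.1,-12.3,T9,T9,L4,L4,-12.0,-12.0,T6,L2,-5.2
8,T12,T11,L4,L4,-9.1,-8.2,T9,T9,L4,L4,-13.5,-13.5,T12,L2,-11.0
9,T10,T10,L4,L4,-19.8,-15.6,T11,T11,L4,L4,-20.6,-20.6,T9,L3,-14.8
10,T11,T12,L4,L4,10.2,11.0,T12,T12,L4,L4,10.9,10.9,T12,L3,10.8
11,T5,,L1,,-8.4,0,T7,T7,L2,L2,-4.2,-4.2,T1,T12,-7.2
12,T5,T5,L2,L1,13.5,8.7,T4,T4,L3,L3,9.3,9.3,T1,L2,11.1
13,T10,T10,L4,L4,15.1,14.0,T10,T10,L4,L4,14.4,14.4,T9,L5,13.5
14,T9,T9,L4,L4,-15.4,-12.1,T10,T10,L4,L4,-13.8,-13.8,T2,L5,-14.2
15,,,,,0,0,T4,T4,T12,T12,-7.4,-7.4,T4,T10,-7.7
16,T9,T11,L4,L4,-14.2,-15.0,T7,T7,L4,L4,-20.2,-20.2,T7,L4,-18.9
17,T1,T4,T7,T12,5.9,8.4,T2,T2,T12,T12,13.4,13.6,T2,T12,11.3
18,T7,T6,L1,L3,14.7,8.3,T6,T6,L4,L4,7.0,7.1,T9,L1,7.6
19,T11,T9,L5,L5,-6.9,-9.6,T4,T4,L5,L5,-11.5,-11.7,T2,L5,-12.4
20,T3,T2,T8,T11,7.1,8.5,T4,T4,T6,T6,8.8,8.5,T3,T6,9.8
21,T12,T10,L5,L4,11.1,9.9,C3,C3,L2,L2,15.3,16.2,T3,L3,13.8
22,T7,T7,L4,L4,12.9,13.0,T2,T2,L4,L4,16.8,16.9,T3,L3,18.1
23,T8,T8,L3,L4,11.3,13.8,T11,T11,L5,L5,15.5,15.6,T11,L3,9.4
24,T7,T9,L4,L4,-14.1,-14.0,T5,T5,L5,L5,-21.8,-22.1,T2,L3,-13.5
25,T9,T8,L3,L3,-16.2,-14.5,T6,T6,L3,L3,-10.3,-9.9,T11,L2,-10.7
26,T8,T8,L3,L3,-8.2,-8.0,T7,T7,L2,L2,-6.4,-6.3,T2,L2,-5.6
27,T5,T5,L3,L4,-17.3,-17.3,T5,T5,L3,L3,-15.8,-15.0,T1,L3,-15.2
28,T11,T11,L4,L3,18.4,15.7,T12,T12,L4,L4,22.4,23.1,T12,L4,16.6
29,,,,,0,0,T3,T3,T10,T10,-5.2,-5.1,T2,L4,-6.6
30,T9,T9,L4,L4,-11.7,-9.9,T5,T5,L4,L4,-14.2,-14.1,T6,L4,-8.7
31,T11,T12,L4,L4,-6.9,-7.7,T3,T3,L1,L1,10.0,10.1,L1,L4,-7.4
32,T11,T10,L4,L4,-5.9,-6.0,T5,T5,L5,L5,-6.2,-7.1,T1,L3,-9.1
33,T9,T9,L4,L4,-16.7,-16.0,T8,T8,L4,L4,-14.0,-13.3,T11,L4,-12.5
34,T12,T12,L4,L4,10.3,12.1,T12,T12,L4,L4,10.0,9.7,T1,L3,9.9
35,T5,T7,L1,L2,15.7,16.4,T5,T5,L1,L1,17.0,17.9,T5,L1,13.8
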