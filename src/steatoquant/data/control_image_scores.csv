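image,algorithm,LP1_strict,LP1_gestalt,LP2_strict,LP2_gestalt,LP3_strict,LP3_gestalt
1,5.8,20,25,15,15,20,15
2,10.3,35,40,20,20,25,25
3,10.0,35,40,20,25,30,25
4,13.8,40,45,20,20,40,40
5,7.7,20,30,15,10,30,30
6,16.8,50,70,40,35,55,50
7,6.2,10,15,5,5,20,20
8,13.1,25,40,15,15,50,45
9,11.6,20,45,20,20,40,35
10,10.2,20,45,20,20,40,40
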