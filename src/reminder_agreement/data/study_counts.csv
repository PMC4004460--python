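reminder_id,a,b,c,d
1,85,20,7,293
2,11,1,2,391
3,4,4,15,382
4,110,15,32,248
5,12,34,44,315
6,1,0,3,401
7,204,12,8,181
8,140,27,7,231
9,84,127,9,185
10,35,8,72,290
11,2,29,2,372
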