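subject,condition,W,N1,N2,N3,REM
1,stim,300,210,30,0,0
1,sham,0,0,390,90,0
2,stim,0,0,0,540,0
2,sham,0,0,300,240,0
3,stim,0,0,0,540,0
3,sham,0,0,0,480,0
4,stim,0,0,120,420,0
4,sham,0,30,150,360,0
5,stim,0,0,60,480,0
5,sham,60,150,240,90,0
6,stim,0,0,60,480,0
6,sham,0,30,240,270,0
7,stim,0,0,90,450,0
7,sham,0,0,180,360,0
8,stim,0,0,120,420,0
8,sham,0,0,210,330,0
9,stim,0,0,450,90,0
9,sham,0,0,120,420,0
10,stim,0,30,330,120,0
10,sham,120,60,240,120,0
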