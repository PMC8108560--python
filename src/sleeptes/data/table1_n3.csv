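subject,condition,n3_minutes,n3_percent
1,stim,20.0,4.3
1,sham,13.5,3.0
2,stim,64.0,13.6
2,sham,56.5,11.7
3,stim,130.5,26.1
3,sham,117.5,23.4
4,stim,80.5,16.4
4,sham,57.5,11.9
5,stim,31.0,7.1
5,sham,24.5,5.5
6,stim,134.5,27.7
6,sham,121.5,24.8
7,stim,12.0,2.3
7,sham,11.5,2.2
8,stim,38.0,7.5
8,sham,41.0,8.0
9,stim,65.0,13.7
9,sham,66.5,14.1
10,stim,62.0,13.1
10,sham,53.5,10.7
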