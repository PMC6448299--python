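M,C,F,count
1,1,1,5
1,1,2,4
1,1,3,1
1,2,1,0
1,2,2,1
1,2,3,2
1,3,1,2
1,3,2,0
1,3,3,2
2,1,1,15
2,1,2,4
2,1,3,2
2,2,1,2
2,2,2,3
2,2,3,1
2,3,1,4
2,3,2,4
2,3,3,2
3,1,1,3
3,1,2,3
3,1,3,4
3,2,1,0
3,2,2,2
3,2,3,3
3,3,1,1
3,3,2,1
3,3,3,7
4,1,1,2
4,1,2,1
4,1,3,2
4,2,1,0
4,2,2,1
4,2,3,3
4,3,1,0
4,3,2,3
4,3,3,3
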