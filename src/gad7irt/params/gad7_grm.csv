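item,label,lambda,tau1,tau2,tau3
1,Feeling nervous anxiety,2.64,-0.46,2.83,4.27
2,Not able to stop worrying,3.55,0.74,4.24,6.37
3,Worrying too much,3.10,-0.20,3.20,5.07
4,Trouble relaxing,2.74,-0.78,2.30,4.25
5,Hard to sit still,1.69,1.04,2.94,4.30
6,Becoming easily annoyed,1.69,-0.36,2.44,4.06
7,Something might happen,2.32,0.93,3.53,4.86
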