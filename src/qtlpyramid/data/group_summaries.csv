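subject,n,mean,min,max,scale
HJX74,1,29.2,,,raw_percent
1QL,11,48.1,42.5,56.5,raw_percent
2QL,7,54.6,46.9,63.2,raw_percent
3QL,10,67.4,60.0,78.1,raw_percent
4QL,7,70.6,63.4,76.5,raw_percent
5QL,5,77.1,73.3,80.9,raw_percent
6QL,2,88.8,86.0,91.7,raw_percent
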