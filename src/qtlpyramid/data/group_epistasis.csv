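group,n,mean_i,min_i,max_i,significance
2QL,7,-7.8,0.9,-14.1,ns
3QL,10,-14.6,-3.9,-21.4,*
4QL,7,-25.2,-17.0,-31.2,**
5QL,5,-40.4,-32.4,-49.0,***
6QL,2,-47.7,-41.7,-53.7,***
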