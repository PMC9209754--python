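group,subgroup,n,mean_i,mean_ser
2QL,with,3,-2.1,58.6
2QL,without,4,-12.0,51.6
3QL,with,6,-11.9,71.4
3QL,without,4,-18.8,61.5
4QL,with,4,-21.4,72.5
4QL,without,3,-30.4,68.0
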