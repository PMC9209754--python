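# Synthetic reconstruction: per-locus single-QTL additive effects (percentage
# points of SER) are not published per locus; these values were solved to be
# jointly consistent with every published aggregate (grand mean 18.9, range
# 13.3-27.3, level means 16.2/20.8/26.4 with sizes 7/2/2, donor means
# 16.6 (sativa, 14.8-17.5), 17.1 (glaberrima, 13.3-21.4),
# 24.3 (glumaepatula, 20.2-27.3)). Used as simulator defaults only.
locus,additive_effect
qSER1a-gla,13.3
qSER1b-gla,16.2
qSER1b-glu,20.2
qSER2a-sat,14.8
qSER2b-sat,16.6
qSER3a-sat,17.5
qSER3b-sat,17.5
qSER3b-glu,25.5
qSER5-glu,27.3
qSER8b-gla,17.5
qSER12-gla,21.4
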