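line_id,group,qSER1a-gla,qSER1b-gla,qSER1b-glu,qSER2a-sat,qSER2b-sat,qSER3a-sat,qSER3b-sat,qSER3b-glu,qSER5-glu,qSER8b-gla,qSER12-gla
HJX74,control,-,-,-,-,-,-,-,-,-,-,-
A35,2QL,-,-,-,+,+,-,-,-,-,-,-
A88,2QL,-,-,-,-,-,+,+,-,-,-,-
2QL-1,2QL,-,+,-,-,-,-,-,-,-,-,+
2QL-2,2QL,-,+,-,-,-,-,-,-,-,+,-
2QL-3,2QL,-,-,-,-,-,-,-,-,-,+,+
2QL-4,2QL,-,-,-,-,-,+,-,-,-,+,-
2QL-5,2QL,-,-,-,-,-,+,-,-,-,-,+
3QL-1,3QL,+,+,-,-,-,-,-,-,-,-,+
3QL-2,3QL,+,+,-,-,-,-,-,-,-,+,-
3QL-3,3QL,-,+,-,-,-,-,-,-,-,+,+
3QL-4,3QL,+,-,-,-,-,-,-,-,-,+,+
3QL-5,3QL,-,+,-,-,-,+,+,-,-,-,-
3QL-6,3QL,-,-,-,-,-,+,+,-,-,+,-
3QL-7,3QL,-,-,-,-,-,+,-,+,-,+,-
3QL-8,3QL,-,-,+,-,-,+,-,-,-,+,-
3QL-9,3QL,-,-,-,-,-,+,-,-,+,+,-
3QL-10,3QL,-,-,-,+,+,+,-,-,-,-,-
4QL-1,4QL,-,+,-,+,+,-,-,-,-,-,+
4QL-2,4QL,-,+,-,+,+,-,-,-,-,+,-
4QL-3,4QL,-,-,-,+,+,-,-,-,-,+,+
4QL-4,4QL,-,+,-,-,-,+,+,-,-,-,+
4QL-5,4QL,-,-,-,-,-,+,+,-,-,+,+
4QL-6,4QL,-,+,-,-,-,+,+,-,-,+,-
4QL-7,4QL,+,-,-,-,-,+,+,-,-,-,+
5QL-1,5QL,-,+,-,-,-,+,+,-,-,+,+
5QL-2,5QL,-,-,-,+,+,+,+,-,-,-,+
5QL-3,5QL,-,-,-,-,-,+,+,+,+,+,-
5QL-4,5QL,-,+,-,-,-,+,+,-,+,+,-
5QL-5,5QL,-,-,-,+,+,+,+,-,-,+,-
6QL-1,6QL,-,-,-,+,+,+,+,-,+,+,-
6QL-2,6QL,-,+,-,+,+,+,+,-,-,+,-
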