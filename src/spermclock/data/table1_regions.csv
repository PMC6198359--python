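name,chr,start,stop
ADAMTS8,chr11,130299298,130299948
ARC,chr8,143694010,143694548
ARGHGEF10,chr8,1877888,1878324
BCL11A,chr2,60680616,60680762
C1ORF122,chr1,38272200,38273057
C7ORF50,chr7,1083209,1084163
CCDC144NL,chr17,20798895,20799770
CLIC1,chr6,31698492,31699299
DMPK,chr19,46282571,46283081
FAM86C1,chr11,71498202,71499118
FAM86JP,chr3,125634060,125634453
FOXK1,chr7,4722778,4723928
FSCN,chr7,5635134,5635954
GAPDH,chr12,6641602,6642355
GET4,chr7,914964,915832
GNB2,chr7,100274361,100275305
GPANK1,chr6,31630819,31632542
GPR45,chr2,105857809,105859084
KCNQ1,chr11,2554562,2555577
LDLRAD4,chr18,13611370,13611825
LMO3,chr12,16760040,16761003
LOC100133461,chr4,3680721,3681760
MIR22HG,chr17,1617363,1618296
MTMR8,chrX,63614857,63615496
N10,chr1,28423399,28424202
N12,chr5,3593413,3594276
N22,chr19,4579481,4580471
N23,chr14,106004434,106004608
N24,chr6,170449417,170450804
N27,chr6,30432200,30433944
N30,chr15,27959473,27960032
N8,chr11,69260136,69261045
N9,chr7,35300077,35301070
NCOR2,chr12,124990897,124991140
NONE,chr10,17347047,17347392
NSG1,chr4,4386726,4387698
PAX2,chr10,102509693,102510569
PITX1,chr5,134365728,134366535
PRSS22,chr16,2908157,2908935
PTPRN2.3,chr7,157523356,157524159
PTPRN2.4,chr7,158109339,158110153
PURA,chr5,139492535,139493491
PYY2,chr17,26553567,26554908
SECTM1,chr17,80278592,80280331
SEMA6B,chr19,4555999,4556983
SEZ6,chr17,27330794,27332647
SLC22A18AS,chr11,2909690,2909716
SOHLH1,chr9,138590204,138590996
THBS3,chr1,155176868,155177784
TNXB,chr6,32064146,32065891
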