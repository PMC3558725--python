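gene_id	snp_id
ACO1	rs1028932
ACO1	rs10435797
ACO1	rs10813816
ACO1	rs13293491
ACO1	rs10813818
ACO1	rs2026739
ACO1	rs7032871
ACO1	rs10738885
ACO1	rs16918276
ACO1	rs3780473
ACO1	rs3780474
ACO1	rs4495514
ACO1	rs13302577
ACO1	rs7866419
ACO1	rs7022554
ACO1	rs4879583
ACO1	rs10970961
ACO1	rs7033149
ACO1	rs10970972
ACO1	rs10970974
ACO1	rs7019520
ACO1	rs13292540
ACO1	rs13293491
ACO1	rs3780474
ALAD	rs8177800
ALAD	rs8177804
ALAD	rs818684
ALAD	rs2761016
ALAD	rs8177812
ALAD	rs1805313
ALAD	rs1805316
ALAS1	rs352166
ALAS1	rs352167
ALAS1	rs352169
ALAS1	rs11712164
ALAS1	rs352170
ALAS1	rs9813468
BLVRA	rs10234057
BLVRA	rs849161
BLVRA	rs699510
BLVRA	rs849162
BLVRA	rs849165
BLVRA	rs10233867
BLVRA	rs10268054
BLVRA	rs1317916
BLVRB	rs2613843
CP	rs17787768
CP	rs3816893
CP	rs772908
CP	rs16861598
CP	rs16861634
CP	rs16861590
CP	rs4974389
CP	rs701755
CP	rs7652826
CP	rs13072552
CP	rs16861577
CP	rs13075921
CP	rs9853335
CP	rs1879169
CP	rs773050
CP	rs16861579
CP	rs11924961
CPOX	rs3804622
CPOX	rs1675534
FECH	rs1788002
FECH	rs1790619
FECH	rs492274
FECH	rs317806
FECH	rs8094527
FECH	rs533952
FECH	rs12969847
FECH	rs1041951
FECH	rs7243988
FECH	rs317807
FECH	rs12454808
FECH	rs2269221
FECH	rs2269222
FECH	rs8099511
FECH	rs1736439
FECH	rs8092783
FECH	rs2272783
FECH	rs8095390
FECH	rs12968109
FECH	rs7242288
FTH1	rs5904861
FTH1	rs195154
HAMP	rs8101606
HFE	rs1800562
HFE	rs2071303
HFE	rs2858996
HFE2	rs10218795
HFE2	rs7540883
HMBS	rs1799993
HMBS	rs1784304
HMBS	rs1006195
HMBS	rs494048
HMBS	rs1144041
HMBS	rs17075
HMBS	rs549893
HMOX1	rs9306300
HMOX1	rs8140669
HMOX1	rs2071749
HMOX1	rs8140370
HMOX1	rs2285112
HMOX1	rs5995097
HMOX1	rs2269533
HMOX2	rs4786500
HMOX2	rs2160567
HMOX2	rs1362626
HMOX2	rs9302781
HMOX2	rs11076834
HMOX2	rs3789038
HMOX2	rs4786501
HMOX2	rs2270366
HMOX2	rs10500325
HMOX2	rs8063084
HMOX2	rs4785969
HMOX2	rs9929475
HMOX2	rs7192051
HMOX2	rs9936357
HMOX2	rs8048958
HMOX2	rs8055559
IL6	rs2069837
IL6	rs2066992
IL6	rs2069835
IL6	rs1548216
IL6	rs2069842
IL6	rs2069840
IL6	rs1474347
IL6R	rs11265618
IL6R	rs4845626
IL6R	rs4537545
IL6R	rs10752641
IL6R	rs4240872
IL6R	rs11265610
IL6R	rs6694817
IL6R	rs6427658
IL6R	rs4845618
IL6R	rs10159236
IL6R	rs6689393
IL6R	rs12060250
IL6R	rs4129267
IL6R	rs8192282
IL6R	rs4537545
IL6R	rs10752641
IREB2	rs13180
IREB2	rs2568491
IREB2	rs9920411
IREB2	rs924840
IREB2	rs17483929
IREB2	rs16969899
IREB2	rs2656071
IREB2	rs16969858
IREB2	rs17483721
IREB2	rs905742
IREB2	rs8043227
IREB2	rs10519198
IREB2	rs7181486
IREB2	rs2568483
IREB2	rs2656073
IREB2	rs8041628
IREB2	rs11636431
IREB2	rs2568492
SLC11A2	rs17125212
SLC11A2	rs2269683
SLC11A2	rs224572
SLC11A2	rs224573
SLC11A2	rs224568
SLC11A2	rs224589
SLC25A37	rs7826247
SLC25A37	rs2872716
SLC25A37	rs17089392
SLC25A37	rs2942194
SLC25A37	rs17089394
SLC25A37	rs7833754
SLC25A37	rs7834536
SLC25A37	rs17089335
SLC25A37	rs11778179
SLC25A37	rs2928672
SLC25A37	rs752778
SLC25A37	rs7846025
SLC25A37	rs3736032
SLC25A37	rs7834883
SLC25A37	rs7830129
SLC25A37	rs2928665
SLC25A37	rs7816824
SLC25A37	rs10503725
SLC25A37	rs17698981
SLC25A37	rs2942204
SLC25A37	rs2978471
SLC25A37	rs2978475
SLC25A37	rs17089332
SLC25A37	rs11781222
SLC25A37	rs7015818
SLC25A37	rs12548753
SLC25A37	rs7829094
SLC25A37	rs13266950
SLC25A37	rs17089358
SLC25A37	rs2004644
SLC25A37	rs4871881
SLC25A37	rs4871880
SLC25A37	rs7834536
SLC40A1	rs4667287
SLC40A1	rs2304704
SLC40A1	rs1439816
SLC40A1	rs930373
SLC40A1	rs1123110
SLC40A1	rs3792079
SLC40A1	rs11568350
SLC40A1	rs13431938
SLC40A1	rs1123109
SLC40A1	rs13404407
SMAD4	rs3764465
SMAD4	rs10502913
SMAD4	rs16952790
SMAD4	rs12457540
SMAD4	rs948588
STAT3	rs3809758
STAT3	rs2306580
STAT3	rs4796646
STAT3	rs17880900
STAT3	rs8069645
STAT3	rs3785898
STAT3	rs7215104
STAT3	rs744166
STAT3	rs4796644
STAT3	rs8078731
STAT3	rs8074524
STAT3	rs6503698
STAT3	rs1026916
STAT3	rs7211777
STAT3	rs3816769
STAT3	rs9912773
STEAP3	rs838075
STEAP3	rs708675
STEAP3	rs3769659
STEAP3	rs838074
STEAP3	rs12711924
STEAP3	rs41527945
STEAP3	rs7596511
STEAP3	rs838083
STEAP3	rs708672
STEAP3	rs838072
STEAP3	rs708670
STEAP3	rs865688
STEAP3	rs838095
STEAP3	rs12465926
STEAP3	rs11888609
STEAP3	rs838103
STEAP3	rs12990907
STEAP3	rs10182241
STEAP3	rs838090
STEAP3	rs1867856
STEAP3	rs10188946
STEAP3	rs838092
STEAP3	rs4592854
STEAP3	rs12104548
STEAP3	rs838079
STEAP3	rs6542517
STEAP3	rs838102
STEAP3	rs1867749
STEAP3	rs13401854
STEAP3	rs6720040
TF	rs4854759
TF	rs8177201
TF	rs1358022
TF	rs8177203
TF	rs8177306
TF	rs1049296
TF	rs2715627
TF	rs1799852
TF	rs7638018
TF	rs4241357
TF	rs7633232
TF	rs6778321
TF	rs1800277
TF	rs8177241
TF	rs8177232
TF	rs2715631
TF	rs8177277
TF	rs8177235
TF	rs8177220
TF	rs8177238
TF	rs8177233
TF	rs2715632
TF	rs8177272
TF	rs12493168
TF	rs2718796
TF	rs1115219
TF	rs8177253
TF	rs8177318
TF	rs8177224
TF	rs7628133
TF	rs8177248
TF	rs1525892
TF	rs8177262
TF	rs7645538
TF	rs8177191
TF	rs8177215
TF	rs3811657
TFR2	rs4521695
TFRC	rs3933
TFRC	rs3804141
TFRC	rs3804142
TFRC	rs4927866
TFRC	rs480760
TFRC	rs12330245
UROD	rs13948
UROS	rs10510149
UROS	rs1571278
UROS	rs2281956
UROS	rs10794025
UROS	rs3814624
UROS	rs11244653
UROS	rs10901450
UROS	rs2027515
UROS	rs3740179
UROS	rs10751533
UROS	rs2149019
UROS	rs12251135
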