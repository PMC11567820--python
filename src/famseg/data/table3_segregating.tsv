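variant_type	cohort	variant	gene	families_complete	n_affected_in_segregating_families	n_healthy_in_segregating_families	coseg_APOE	index_SNP	n_members_carrying_index_SNP
Frameshift variant	EFIGA	chr19:1044708:GGGGCACCTGGT:G	ABCA7	2	8	2	No	chr19:1050875:A:G	2
Stop gain	EFIGA	chr10:11742730:C:T	ECHDC3	1	3	0	No	chr10:11676714:A:G	3
Stop gain	EFIGA	chr7:37884404:G:T	NME8	1	2	1	No	chr7:37844191:T:C	0
Frameshift variant	AD-FBS	chr19:1044708:GGGGCACCTGGT:G	ABCA7	1	3	1	No	chr19:1050875:A:G	0
Frameshift variant	AD-FBS	chr7:37896956:C:CA	NME8	1	3	0	No	chr7:37844191:T:C	0
Splice acceptor variant	AD-FBS	chr16:30010237:T:C	DOC2A	1	2	0	Yes	chr16:30010081:C:T	0
Structural interaction variant	AD-FBS	chr16:70654657:C:A	IL34	2	5	2	Yes	chr16:70660097:C:A	0
Frameshift variant	AD-FBS	chr2:37289451:T:TG	PRKD3	1	2	1	No	chr2:37304796:T:C	0
Frameshift variant	AD-FBS	chr2:37289452:TACTC:T	PRKD3	1	2	1	No	chr2:37304796:T:C	0
Frameshift variant	AD-FBS	chr2:37289460:T:TTG	PRKD3	1	2	1	No	chr2:37304796:T:C	0
Stop gain	AD-FBS	chr20:427337:C:T	RBCK1	1	2	0	No	chr20:413334:A:G	2
Stop gain	AD-FBS	chr4:991652:G:A	SLC26A1/IDUA	1	2	0	Yes		0
Splice acceptor variant	AD-FBS	chr9:104804721:C:G	ABCA1	1	2	0	Yes	chr9:104903697:C:G	0
Damaging missense (CADD > 20)	EFIGA	chr19:1051965:C:T	ABCA7	1	2	4	No	chr19:1050875:A:G	1
Damaging missense (CADD > 20)	EFIGA	chr17:63479054:G:C	ACE	1	2	0	No	chr17:63471557:C:T	2
Damaging missense (CADD > 20)	EFIGA	chr15:58717601:C:T	ADAM10	1	2	2	No	chr15:58764824:T:A	4
Damaging missense (CADD > 20)	EFIGA	chr21:26838216:C:T	ADAMTS1	2	4	0	No	chr21:26775872:C:T	4
Damaging missense (CADD > 20)	EFIGA	chr12:43356572:T:C	ADAMTS20	1	5	3	No	chr12:43573874:T:G	0
Damaging missense (CADD > 20)	EFIGA	chr12:43428519:A:G	ADAMTS20	1	2	1	Yes	chr12:43573874:T:G	3
Damaging missense (CADD > 20)	EFIGA	chr7:92038422:A:G	AKAP9	1	2	0	No		0
Damaging missense (CADD > 20)	EFIGA	chr7:92040807:G:A	AKAP9	1	2	0	No		0
Damaging missense (CADD > 20)	EFIGA	chr7:92102769:G:A	AKAP9	1	2	0	No		0
Damaging missense (CADD > 20)	EFIGA	chr1:207511589:C:T	CR1	1	2	1	Yes	chr1:207577223:T:C	3
Damaging missense (CADD > 20)	EFIGA	chr1:207523952:C:T	CR1	1	5	6	No	chr1:207577223:T:C	2
Damaging missense (CADD > 20)	EFIGA	chr7:143391696:G:A	EPHA1	1	2	3	No	chr7:143413669:G:A	3
Damaging missense (CADD > 20)	EFIGA	chr7:100488976:C:T	NYAP1	1	2	2	No	chr7:100494172:T:C	4
Damaging missense (CADD > 20)	EFIGA	chr14:73170959:A:G	PSEN1	1	5	1	No		0
Damaging missense (CADD > 20)	EFIGA	chr8:27437198:G:A	PTK2B	1	2	0	No	chr8:27362470:C:T	0
Damaging missense (CADD > 20)	EFIGA	chr11:121604205:C:T	SORL1	1	3	0	Yes	chr11:121564878:T:C	0
Damaging missense (CADD > 20)	EFIGA	chr4:987896:C:G	IDUA	1	2	0	No	chr4:993555:G:T	0
Damaging missense (CADD > 20)	EFIGA	chr4:989768:G:A	SLC26A1/IDUA	1	2	0	No	chr4:993555:G:T	0
Damaging missense (CADD > 20)	EFIGA	chr4:989896:A:G	SLC26A1/IDUA	1	3	0	No	chr4:993555:G:T	0
Damaging missense (CADD > 20)	EFIGA	chr6:41033992:C:T	UNC5CL	1	3	0	No	chr6:41036354:G:A	0
Damaging missense (CADD > 20)	EFIGA	chr6:41198273:C:A	TREML2	1	4	1	No	chr6:41181270:A:G	0
Damaging missense (CADD > 20)	EFIGA	chr7:37741061:C:A	GPR141/EPDR1	1	2	0	Yes	chr7:37844191:T:C	2
Damaging missense (CADD > 20)	EFIGA	chr7:37916317:C:T	SFRP4/EPDR1	1	2	0	No	chr7:37844191:T:C	2
Damaging missense (CADD > 20)	EFIGA	chr9:104798567:T:C	ABCA1	1	3	0	Yes	chr9:104903697:C:G	3
Damaging missense (CADD > 20)	EFIGA	chr10:60070700:T:A	ANK3	1	2	1	Yes	chr10:60025170:T:G	2
Damaging missense (CADD > 20)	EFIGA	chr10:60073965:T:C	ANK3	1	3	0	No	chr10:60025170:T:G	0
Damaging missense (CADD > 20)	EFIGA	chr11:86245326:C:T	EED	1	3	0	No	chr11:86157598:T:C	3
Damaging missense (CADD > 20)	EFIGA	chr12:113293011:C:T	TPCN1	1	3	0	No	chr12:113281983:T:C	3
Damaging missense (CADD > 20)	EFIGA	chr16:31110471:C:T	BCKDK	1	2	0	No	chr16:31111250:C:T	0
Damaging missense (CADD > 20)	EFIGA	chr16:81858323:C:T	PLCG2	1	2	0	No	chr16:81908423:C:G	0
Damaging missense (CADD > 20)	EFIGA	chr17:1732823:G:A	WDR81	1	4	0	No	chr17:1728046:TGAG:T	0
Damaging missense (CADD > 20)	EFIGA	chr17:18120185:G:A	MYO15A	1	3	0	No	chr17:18156140:G:A	0
Damaging missense (CADD > 20)	EFIGA	chr17:18173824:G:A	MYO15A	1	2	0	No	chr17:18156140:G:A	0
Damaging missense (CADD > 20)	EFIGA	chr17:58307871:C:G	TSPOAP1	1	4	1	No	chr17:58332680:A:G	3
Damaging missense (CADD > 20)	EFIGA	chr17:58325608:C:T	TSPOAP1	1	4	0	Yes	chr17:58332680:A:G	0
Damaging missense (CADD > 20)	EFIGA	chr17:58327896:G:A	TSPOAP1	1	2	2	No	chr17:58332680:A:G	2
Damaging missense (CADD > 20)	EFIGA	chr19:54279530:T:A	LILRB2	1	2	0	No	chr19:54267597:C:T	1
Damaging missense (CADD > 20)	AD-FBS	chr19:1057344:G:A	ABCA7	2	5	4	No	chr19:1050875:A:G	6
Damaging missense (CADD > 20)	AD-FBS	chr21:26838049:G:A	ADAMTS1	1	4	2	No	chr21:26775872:C:T	6
Damaging missense (CADD > 20)	AD-FBS	chr7:91992989:G:C	AKAP9	1	2	0	Yes		0
Damaging missense (CADD > 20)	AD-FBS	chr7:92097077:C:A	AKAP9	1	3	2	No		0
Damaging missense (CADD > 20)	AD-FBS	chr7:143398406:G:A	EPHA1	1	3	1	No	chr7:143402040:C:A	2
Damaging missense (CADD > 20)	AD-FBS	chr7:100490675:C:T	NYAP1	1	2	6	No	chr7:100494172:T:C	1
Damaging missense (CADD > 20)	AD-FBS	chr14:73170945:C:T	PSEN1	1	2	0	No		0
Damaging missense (CADD > 20)	AD-FBS	chr15:50722170:A:T	SPPL2A	1	4	0	No	chr15:50716490:T:C	4
Damaging missense (CADD > 20)	AD-FBS	chr4:987896:C:G	IDUA	1	2	0	No	chr4:993555:G:T	0
Damaging missense (CADD > 20)	AD-FBS	chr4:989305:G:A	SLC26A1/IDUA	1	2	1	No	chr4:993555:G:T	0
Damaging missense (CADD > 20)	AD-FBS	chr4:990080:G:A	SLC26A1/IDUA	1	2	0	No	chr4:993555:G:T	0
Damaging missense (CADD > 20)	AD-FBS	chr4:990241:C:T	SLC26A1/IDUA	1	2	0	No	chr4:993555:G:T	0
Damaging missense (CADD > 20)	AD-FBS	chr7:37741003:A:T	GPR141/EPDR1	1	3	1	No	chr7:37844191:T:C	0
Damaging missense (CADD > 20)	AD-FBS	chr9:104817343:G:A	ABCA1	1	3	1	No	chr9:104903697:C:G	4
Damaging missense (CADD > 20)	AD-FBS	chr9:104819624:C:T	ABCA1	1	2	0	Yes	chr9:104903697:C:G	0
Damaging missense (CADD > 20)	AD-FBS	chr9:104884475:G:A	ABCA1	1	2	0	No	chr9:104903697:C:G	0
Damaging missense (CADD > 20)	AD-FBS	chr10:60074069:A:C	ANK3	1	3	0	Yes	chr10:60025170:T:G	3
Damaging missense (CADD > 20)	AD-FBS	chr10:60075299:G:A	ANK3	1	2	1	Yes	chr10:60025170:T:G	1
Damaging missense (CADD > 20)	AD-FBS	chr10:60186803:G:A	ANK3	1	2	0	Yes	chr10:60025170:T:G	2
Damaging missense (CADD > 20)	AD-FBS	chr11:86245267:C:T	EED	1	3	4	Yes	chr11:86157598:T:C	3
Damaging missense (CADD > 20)	AD-FBS	chr12:113288795:G:A	TPCN1	1	2	0	Yes	chr12:113281983:T:C	0
Damaging missense (CADD > 20)	AD-FBS	chr16:81923501:A:G	PLCG2	1	2	0	No	chr16:81908423:C:G	0
Damaging missense (CADD > 20)	AD-FBS	chr17:1728303:G:C	WDR81	1	2	0	Yes	chr17:1728046:TGAG:T	0
Damaging missense (CADD > 20)	AD-FBS	chr17:18119509:G:A	MYO15A	1	2	0	No	chr17:18156140:G:A	2
Damaging missense (CADD > 20)	AD-FBS	chr17:18120434:C:T	MYO15A	1	2	0	No	chr17:18156140:G:A	0
Damaging missense (CADD > 20)	AD-FBS	chr17:18133274:G:A	MYO15A	1	2	1	No	chr17:18156140:G:A	0
Damaging missense (CADD > 20)	AD-FBS	chr17:18142122:G:A	MYO15A	1	2	0	No	chr17:18156140:G:A	0
Damaging missense (CADD > 20)	AD-FBS	chr10:11463631:G:A	USP6NL	1	2	0	Yes	chr10:11676714:A:G	0
Damaging missense (CADD > 20)	AD-FBS	chr15:64126203:C:T	SNX1	1	3	1	No	chr15:64131307:G:A	1
Damaging missense (CADD > 20)	AD-FBS	chr15:64131812:C:T	SNX1	1	2	0	Yes	chr15:64131307:G:A	0
Damaging missense (CADD > 20)	AD-FBS	chr16:90060590:C:G	PRDM7	1	2	0	Yes	chr16:90103687:G:A	0
Damaging missense (CADD > 20)	AD-FBS	chr16:90062060:A:G	PRDM7	1	3	0	Yes	chr16:90103687:G:A	3
Damaging missense (CADD > 20)	AD-FBS	chr17:49217803:G:A	ABI3	1	2	0	Yes	chr17:49219935:T:C	0
Damaging missense (CADD > 20)	AD-FBS	chr5:151052238:T:C	TNIP1	1	2	0	No	chr5:151052827:C:T	0
Damaging missense (CADD > 20)	AD-FBS	chr6:114057958:G:A	HS3ST5	1	2	1	No	chr6:114291731:T:C	0
Damaging missense (CADD > 20)	AD-FBS	chr8:11847108:T:G	CTSB	1	3	4	Yes	chr8:11844613:G:C	0
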