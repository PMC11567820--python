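gene	variant	cohort	variant_type
ABCA1	chr9:104804721:C:G	AD-FBS	LoF
ABCA1	chr9:104798567:T:C	EFIGA	Missense
ABCA1	chr9:104817343:G:A	AD-FBS	Missense
ABCA1	chr9:104819624:C:T	AD-FBS	Missense
ABCA1	chr9:104884475:G:A	AD-FBS	Missense
ABCA7	chr19:1057344:G:A	AD-FBS	Missense
ABCA7	chr19:1051965:C:T	EFIGA	Missense
ABCA7	chr19:1044708:GGGGCACCTGGT:G	EFIGA	LoF
ABCA7	chr19:1044708:GGGGCACCTGGT:G	AD-FBS	LoF
ABI3	chr17:49217803:G:A	AD-FBS	Missense
ACE	chr17:63479054:G:C	EFIGA	Missense
ADAM10	chr15:58717601:C:T	EFIGA	Missense
ADAMTS1	chr21:26838049:G:A	AD-FBS	Missense
ADAMTS1	chr21:26838216:C:T	EFIGA	Missense
ADAMTS20	chr12:43356572:T:C	EFIGA	Missense
ADAMTS20	chr12:43428519:A:G	EFIGA	Missense
AKAP9	chr7:91992989:G:C	AD-FBS	Missense
AKAP9	chr7:92097077:C:A	AD-FBS	Missense
AKAP9	chr7:92038422:A:G	EFIGA	Missense
AKAP9	chr7:92040807:G:A	EFIGA	Missense
AKAP9	chr7:92102769:G:A	EFIGA	Missense
ANK3	chr10:60070700:T:A	EFIGA	Missense
ANK3	chr10:60073965:T:C	EFIGA	Missense
ANK3	chr10:60074069:A:C	AD-FBS	Missense
ANK3	chr10:60075299:G:A	AD-FBS	Missense
ANK3	chr10:60186803:G:A	AD-FBS	Missense
BCKDK	chr16:31110471:C:T	EFIGA	Missense
CR1	chr1:207511589:C:T	EFIGA	Missense
CR1	chr1:207523952:C:T	EFIGA	Missense
CTSB	chr8:11847108:T:G	AD-FBS	Missense
DOC2A	chr16:30010237:T:C	AD-FBS	LoF
ECHDC3	chr10:11742730:C:T	EFIGA	LoF
EED	chr11:86245326:C:T	EFIGA	Missense
EED	chr11:86245267:C:T	AD-FBS	Missense
EPHA1	chr7:143398406:G:A	AD-FBS	Missense
EPHA1	chr7:143391696:G:A	EFIGA	Missense
GPR141	chr7:37741061:C:A	EFIGA	Missense
GPR141	chr7:37741003:A:T	AD-FBS	Missense
HS3ST5	chr6:114057958:G:A	AD-FBS	Missense
IDUA	chr4:987896:C:G	EFIGA	Missense
IDUA	chr4:987896:C:G	AD-FBS	Missense
IL34	chr16:70654657:C:A	AD-FBS	LoF
LILRB2	chr19:54279530:T:A	EFIGA	Missense
MYO15A	chr17:18120185:G:A	EFIGA	Missense
MYO15A	chr17:18173824:G:A	EFIGA	Missense
MYO15A	chr17:18119509:G:A	AD-FBS	Missense
MYO15A	chr17:18120434:C:T	AD-FBS	Missense
MYO15A	chr17:18133274:G:A	AD-FBS	Missense
MYO15A	chr17:18142122:G:A	AD-FBS	Missense
NME8	chr7:37884404:G:T	EFIGA	LoF
NME8	chr7:37896956:C:CA	AD-FBS	LoF
NYAP1	chr7:100490675:C:T	AD-FBS	Missense
NYAP1	chr7:100488976:C:T	EFIGA	Missense
PLCG2	chr16:81858323:C:T	EFIGA	Missense
PLCG2	chr16:81923501:A:G	AD-FBS	Missense
PRDM7	chr16:90060590:C:G	AD-FBS	Missense
PRDM7	chr16:90062060:A:G	AD-FBS	Missense
PRKD3	chr2:37289451:T:TG	AD-FBS	LoF
PRKD3	chr2:37289452:TACTC:T	AD-FBS	LoF
PRKD3	chr2:37289460:T:TTG	AD-FBS	LoF
PSEN1	chr14:73170945:C:T	AD-FBS	Missense
PSEN1	chr14:73170959:A:G	EFIGA	Missense
PTK2B	chr8:27437198:G:A	EFIGA	Missense
RBCK1	chr20:427337:C:T	AD-FBS	LoF
SFRP4	chr7:37916317:C:T	EFIGA	Missense
SLC26A1	chr4:991652:G:A	AD-FBS	LoF
SLC26A1	chr4:989768:G:A	EFIGA	Missense
SLC26A1	chr4:989896:A:G	EFIGA	Missense
SLC26A1	chr4:989305:G:A	AD-FBS	Missense
SLC26A1	chr4:990080:G:A	AD-FBS	Missense
SLC26A1	chr4:990241:C:T	AD-FBS	Missense
SNX1	chr15:64126203:C:T	AD-FBS	Missense
SNX1	chr15:64131812:C:T	AD-FBS	Missense
SORL1	chr11:121604205:C:T	EFIGA	Missense
SPPL2A	chr15:50722170:A:T	AD-FBS	Missense
TNIP1	chr5:151052238:T:C	AD-FBS	Missense
TPCN1	chr12:113293011:C:T	EFIGA	Missense
TPCN1	chr12:113288795:G:A	AD-FBS	Missense
TREML2	chr6:41198273:C:A	EFIGA	Missense
TSPOAP1	chr17:58307871:C:G	EFIGA	Missense
TSPOAP1	chr17:58325608:C:T	EFIGA	Missense
TSPOAP1	chr17:58327896:G:A	EFIGA	Missense
UNC5CL	chr6:41033992:C:T	EFIGA	Missense
USP6NL	chr10:11463631:G:A	AD-FBS	Missense
WDR81	chr17:1732823:G:A	EFIGA	Missense
WDR81	chr17:1728303:G:C	AD-FBS	Missense
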