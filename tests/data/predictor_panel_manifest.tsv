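CGID	chr	pos	gene	feature
cg02068164	chr5	33439794	TARS	TSS
cg20088245	chr8	1321375	DLGAP2	TSS
cg08735705	chr7	1003645	ADAP1	enhancer
cg22243260	chr3	126946036	NA	NA
cg10279314	chr6	27185896	PRSS16	intron
cg25210835	chr1	110254828	GSTM5	promoter
cg17422692	chr16	420245	MRPL28	promoter
cg03128011	chr8	1321333	DLGAP2	promoter
cg05571310	chr17	72350354	KIF19	intron
cg20540428	chr3	73045686	PPP4R2	promoter
cg15247329	chr7	2764246	GNA12	intron
cg02613380	chr10	99330076	UBTD1	promoter
cg09419670	chr9	123605666	PSMD5	intron
cg20561509	chr13	49427965	FNDC3A	promoter
cg27572370	chr10	14002394	FRMD4A	intron
cg09978860	chr4	56023921	KDR	intron
cg00274965	chr21	34405681	OLIG1	intron
cg11939300	chr2	132584904	CCDC74A	intron
cg14178589	chr6	168726836	NA	NA
cg11480278	chr17	83580	RPH3AL	unknown
cg09817162	chr6	27185676	PRSS16	enhancer
cg11553311	chr5	66541588	CD180	unknown
cg21048050	chr15	51912957	DMXL2	promoter
cg13831575	chr15	48834416	FBN1	promoter
cg11744538	chr17	42646995	NA	NA
cg02408697	chr10	1416920	ADARB2	intron
cg16113156	chr18	76266265	SALL3	unknown
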