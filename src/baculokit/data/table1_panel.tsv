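gene_name	gene_class	category	orf_id	alias
odv-e18	core	structure	orf13
49k	core	structure	orf14
odv-ec43	core	structure	orf47
p48/p45	core	structure	orf74
p40	core	structure	orf76	bv/odv-c42
p6.9	core	structure	orf77
38k	core	structure	orf79
odv-e25	core	structure	orf82
p18	core	structure	orf83
p33	core	structure	orf84
vp39	core	structure	orf87
odv-ec27	core	structure	orf88
ac81	core	structure	orf93
gp41	core	structure	orf94
ac78	core	structure	orf95
desmop	core	structure	orf100
ac53	core	structure	orf120
vp1054	core	structure	orf123
lef-2	core	replication	orf34
lef-1	core	replication	orf64
helicase	core	replication	orf81
dna-pol	core	replication	orf99
alk-exo	core	replication	orf114
p47	core	transcription	orf60
lef-5	core	transcription	orf78
lef-4	core	transcription	orf86
vlf-1	core	transcription	orf96
lef-9	core	transcription	orf106
lef-8	core	transcription	orf117
pif-5	core	oral_infection	orf16
pif-3	core	oral_infection	orf30
pif-2	core	oral_infection	orf41
ac110	core	oral_infection	orf45
p74	core	oral_infection	orf53
pif-1	core	oral_infection	orf65
pif-4	core	oral_infection	orf80
pif-8	core	oral_infection	orf91
pif-6	core	oral_infection	orf103
granulin	lepidopteran_conserved	structure	orf1
pk-1	lepidopteran_conserved	structure	orf3
calyx/pep-1	lepidopteran_conserved	structure	orf20
f-protein	lepidopteran_conserved	structure	orf27
bv-e31	lepidopteran_conserved	structure	orf61
p24	lepidopteran_conserved	structure	orf62
p12	lepidopteran_conserved	structure	orf75
tlp-20	lepidopteran_conserved	structure	orf92
fp25k	lepidopteran_conserved	structure	orf118
lef-11	lepidopteran_conserved	replication	orf51
dbp	lepidopteran_conserved	replication	orf71
lef-3	lepidopteran_conserved	replication	orf102
me53	lepidopteran_conserved	replication	orf128
39k	lepidopteran_conserved	transcription	orf50
lef-6	lepidopteran_conserved	transcription	orf70
38.7k	lepidopteran_conserved	auxiliary	orf63
p10	other	structure	orf17
pep-2	other	structure	orf23
vp80	other	structure	orf24
ie-1	other	replication	orf6
dna-ligase	other	replication	orf108
helicase-2	other	replication	orf115
odv-e66	other	oral_infection	orf31
chitinase	other	auxiliary	orf9
iap-3	other	auxiliary	orf11
gp37	other	auxiliary	orf12
bro	other	auxiliary	orf26
p13	other	auxiliary	orf39
ubiquitin	other	auxiliary	orf46
sod	other	auxiliary	orf52
fgf-1	other	auxiliary	orf66
iap-1	other	auxiliary	orf85	iap-6
iap-2	other	auxiliary	orf105	iap-5
fgf-2	other	auxiliary	orf111
fgf-3	other	auxiliary	orf126
egt	other	auxiliary	orf127
orf22	unique	unique	orf22
orf40	unique	unique	orf40
orf56	unique	unique	orf56
orf101	unique	unique	orf101
orf124	unique	unique	orf124
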