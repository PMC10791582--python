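codon	wc_anticodon	wobble_donors
AAA	TTT	ATT
AAC	GTT	ATT
AAG	CTT	TTT
AAT	ATT	GTT
ACA	TGT	AGT
ACC	GGT	AGT
ACG	CGT	TGT
ACT	AGT	GGT
AGA	TCT	ACT
AGC	GCT	ACT
AGG	CCT	TCT
AGT	ACT	GCT
ATA	TAT	AAT
ATC	GAT	AAT
ATG	CAT	TAT
ATT	AAT	GAT
CAA	TTG	ATG
CAC	GTG	ATG
CAG	CTG	TTG
CAT	ATG	GTG
CCA	TGG	AGG
CCC	GGG	AGG
CCG	CGG	TGG
CCT	AGG	GGG
CGA	TCG	ACG
CGC	GCG	ACG
CGG	CCG	TCG
CGT	ACG	GCG
CTA	TAG	AAG
CTC	GAG	AAG
CTG	CAG	TAG
CTT	AAG	GAG
GAA	TTC	ATC
GAC	GTC	ATC
GAG	CTC	TTC
GAT	ATC	GTC
GCA	TGC	AGC
GCC	GGC	AGC
GCG	CGC	TGC
GCT	AGC	GGC
GGA	TCC	ACC
GGC	GCC	ACC
GGG	CCC	TCC
GGT	ACC	GCC
GTA	TAC	AAC
GTC	GAC	AAC
GTG	CAC	TAC
GTT	AAC	GAC
TAC	GTA	ATA
TAT	ATA	GTA
TCA	TGA	AGA
TCC	GGA	AGA
TCG	CGA	TGA
TCT	AGA	GGA
TGC	GCA	ACA
TGG	CCA	TCA
TGT	ACA	GCA
TTA	TAA	AAA
TTC	GAA	AAA
TTG	CAA	TAA
TTT	AAA	GAA
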