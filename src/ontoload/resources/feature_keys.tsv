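# Feature Table (FTv8 dialect) feature key -> Sequence Ontology accession.
# Snapshot curated from the public ft<->SO mapping; keys absent from SO map
# to the closest region-class term. One key per row: key<TAB>accession<TAB>term name.
-10_signal	SO:0000175	minus_10_signal
-35_signal	SO:0000176	minus_35_signal
3'UTR	SO:0000205	three_prime_UTR
5'UTR	SO:0000204	five_prime_UTR
attenuator	SO:0000140	attenuator
C_region	SO:0001834	C_region
CAAT_signal	SO:0000172	CAAT_signal
CDS	SO:0000316	CDS
D-loop	SO:0000297	D_loop
D_segment	SO:0000458	D_gene
enhancer	SO:0000165	enhancer
exon	SO:0000147	exon
gap	SO:0000730	gap
GC_signal	SO:0000173	GC_rich_promoter_region
gene	SO:0000704	gene
iDNA	SO:0000723	iDNA
intron	SO:0000188	intron
J_segment	SO:0000470	J_gene
LTR	SO:0000286	long_terminal_repeat
mat_peptide	SO:0000419	mature_protein_region
misc_binding	SO:0000409	binding_site
misc_difference	SO:0000413	sequence_difference
misc_feature	SO:0000001	region
misc_recomb	SO:0000298	recombination_feature
misc_RNA	SO:0000673	transcript
misc_signal	SO:0005836	regulatory_region
misc_structure	SO:0000002	sequence_secondary_structure
mobile_element	SO:0001037	mobile_genetic_element
modified_base	SO:0000305	modified_DNA_base
mRNA	SO:0000234	mRNA
ncRNA	SO:0000655	ncRNA
N_region	SO:0001835	N_region
old_sequence	SO:0000413	sequence_difference
operon	SO:0000178	operon
oriT	SO:0000724	oriT
polyA_signal	SO:0000551	polyA_signal_sequence
polyA_site	SO:0000553	polyA_site
precursor_RNA	SO:0000185	primary_transcript
prim_transcript	SO:0000185	primary_transcript
primer_bind	SO:0005850	primer_binding_site
promoter	SO:0000167	promoter
protein_bind	SO:0000410	protein_binding_site
RBS	SO:0000139	ribosome_entry_site
repeat_region	SO:0000657	repeat_region
rep_origin	SO:0000296	origin_of_replication
rRNA	SO:0000252	rRNA
satellite	SO:0000005	satellite_DNA
sig_peptide	SO:0000418	signal_peptide
source	SO:2000061	databank_entry
S_region	SO:0001836	S_region
stem_loop	SO:0000313	stem_loop
STS	SO:0000331	STS
TATA_signal	SO:0000174	TATA_box
terminator	SO:0000141	terminator
tmRNA	SO:0000584	tmRNA
transit_peptide	SO:0000725	transit_peptide
tRNA	SO:0000253	tRNA
unsure	SO:0000001	region
variation	SO:0000109	sequence_variant_obs
V_region	SO:0001833	V_region
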