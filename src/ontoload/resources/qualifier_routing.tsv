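# Feature Table (FTv8 dialect) qualifier -> routing rule.
# route is one of: annotation | collection | taxonomy | suppressed
# target: collection/taxonomy column name, or "-" for annotation qualifiers,
# which are typed by a term in the reserved "local:" namespace named after
# the qualifier itself (mirrors the fallback of naming attributes after the
# GenBank qualifier when no ontology term applies).
allele	annotation	-
anticodon	annotation	-
bio_material	collection	bio_material
bound_moiety	annotation	-
cell_line	annotation	-
cell_type	annotation	-
chromosome	annotation	-
citation	suppressed	-
clone	annotation	-
clone_lib	annotation	-
codon	annotation	-
codon_start	annotation	-
collected_by	collection	collected_by
collection_date	collection	collection_date
compare	suppressed	-
cons_splice	annotation	-
country	collection	country
cultivar	annotation	-
culture_collection	collection	culture_collection
db_xref	taxonomy	taxon_db_xref
dev_stage	annotation	-
direction	annotation	-
EC_number	annotation	-
ecotype	annotation	-
environmental_sample	collection	environmental_sample
estimated_length	annotation	-
exception	annotation	-
experiment	annotation	-
focus	annotation	-
frequency	annotation	-
function	annotation	-
gene	annotation	-
gene_synonym	annotation	-
germline	annotation	-
haplotype	annotation	-
host	collection	host
identified_by	collection	identified_by
inference	annotation	-
isolate	collection	isolate
isolation_source	collection	isolation_source
lab_host	collection	lab_host
label	annotation	-
lat_lon	collection	lat_lon
locus_tag	annotation	-
macronuclear	annotation	-
map	annotation	-
mating_type	annotation	-
mobile_element	annotation	-
mod_base	annotation	-
mol_type	annotation	-
ncRNA_class	annotation	-
note	annotation	-
number	annotation	-
old_locus_tag	annotation	-
operon	annotation	-
organelle	annotation	-
organism	taxonomy	organism_name
partial	annotation	-
PCR_conditions	annotation	-
PCR_primers	annotation	-
phenotype	annotation	-
plasmid	annotation	-
pop_variant	annotation	-
product	annotation	-
protein_id	annotation	-
proviral	annotation	-
pseudo	annotation	-
rearranged	annotation	-
replace	annotation	-
ribosomal_slippage	annotation	-
rpt_family	annotation	-
rpt_type	annotation	-
rpt_unit_range	annotation	-
rpt_unit_seq	annotation	-
satellite	annotation	-
segment	annotation	-
serotype	annotation	-
serovar	annotation	-
sex	annotation	-
specific_host	annotation	-
specimen_voucher	collection	specimen_voucher
standard_name	annotation	-
strain	collection	strain
sub_clone	annotation	-
sub_species	annotation	-
sub_strain	annotation	-
tag_peptide	annotation	-
tissue_lib	annotation	-
tissue_type	annotation	-
transgenic	annotation	-
translation	annotation	-
transl_except	annotation	-
transl_table	annotation	-
trans_splicing	annotation	-
variety	annotation	-
virion	annotation	-
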