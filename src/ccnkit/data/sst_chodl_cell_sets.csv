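taxonomy_id,cell_set_accession_id,cell_set_label,cell_set_preferred_alias,cell_set_aligned_alias,cell_set_additional_aliases,cell_set_alias_assignee,cell_set_alias_citation,cell_set_structure,cell_set_ontology_tag,cell_set_level,cell_set_kind
CCN201912131,CS201912131_40,RNA-seq 040,Inh L1-6 SST NPY,Sst Chodl,,,,primary motor cortex,UBERON:0001384,,leaf
CCN202002272,CS202002272_12,DNAm 12,Inh L1-5 SST AHR,,"RNA-seq 040, 046-047, 050-052, 068 in CCN201912131",,,primary motor cortex,UBERON:0001384,,leaf
CCN202002273,CS202002273_8,ATAC-seq 08,Inh L1-6 SST NPY,Sst Chodl,RNA-seq 040 in CCN201912131,,,primary motor cortex,UBERON:0001384,,leaf
CCN201912132,CS201912132_1,RNA-seq 01,Inh SST NPY,Sst Chodl,,,,primary motor cortex,UBERON:0001384,,leaf
CCN202002013,CS202002013_28,RNA-seq 028,Sst Chodl,Sst Chodl,,,,primary motor cortex,UBERON:0001384,,leaf
CCN202002276,CS202002276_9,DNAm 09,Sst Chodl,Sst Chodl,RNA-seq 028 in CCN202002013,,,primary motor cortex,UBERON:0001384,,leaf
CCN202002277,CS202002277_10,ATAC-seq 10,Sst Chodl,Sst Chodl,RNA-seq 028 in CCN202002013,,,primary motor cortex,UBERON:0001384,,leaf
CCN202002270,CS202002270_14,Integrated 14,Sst Chodl,Sst Chodl,Long-range projecting Sst,,,primary motor cortex,UBERON:0001384,,leaf
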