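taxonomy_id,description,citation,file
CCN201810310,Mouse VISp + ALM transcriptomics taxonomy,,
CCN201908210,Human MTG transcriptomics taxonomy,,
CCN201908211,Joint mouse/human MTG analysis,,
CCN201912130,Human M1 taxonomy using 10x data,,
CCN201912131,Human M1 taxonomy using Smart-seq and 10x data,,
CCN201912132,Marmoset M1 taxonomy using 10x data,,
CCN202002013,Mouse MOp taxonomy using multiple RNA-seq datasets,,
CCN202002270,Cross-species (integrated) transcriptomics taxonomy,,
CCN202002271,"Macaque transcriptomics taxonomy, layer 5/6 only",,
CCN202002272,Human DNA methylation taxonomy,,
CCN202002273,Human ATAC-seq taxonomy,,
CCN202002274,Marmoset DNA methylation taxonomy,,
CCN202002275,Marmoset ATAC-seq taxonomy,,
CCN202002276,Mouse DNA methylation taxonomy,,
CCN202002277,Mouse ATAC-seq taxonomy,,
CCN202005150,"Mouse VISp inhibitory neurons defined using electrophysiology, morphology, and transcriptomics",,
CCN201906170,Mouse VISp neurons defined using electrophysiology and morphology,,
CCN201805250,Turtle pallium transcriptomics taxonomy,,
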