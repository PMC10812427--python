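accession	gene_name	gene_source	protein_name	topology	go_classes	experimental
Q99218	AMELY	uniprot	Amelogenin, Y isoform	SP	CS	yes
Q8NFZ3	NLGN4Y	uniprot	Neuroligin-4, Y-linked	SP+TM	CS,PM	no
Q9BZA8	PCDH11Y	uniprot	Protocadherin-11, Y-linked	SP+TM	PM	no
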