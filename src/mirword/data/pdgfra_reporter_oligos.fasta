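>PDGFRA_3UTR_reporter_oligo_1 sense strand, 99 nt, spans both miR-34a sites
TCGATATGTATATATGTATTTCTATATAGACTTGGAGAATACTGCCAAAACATTTATGAC
AAGCTGTATCACTGCCTTCGTTTATATTTTTTTAACTGT
>PDGFRA_3UTR_reporter_oligo_2 antisense strand of the same segment
GGCCACAGTTAAAAAAATATAAACGAAGGCAGTGATACAGCTTGTCATAAATGTTTTGGC
AGTATTCTCCAAGTCTATATAGAAATACATATATACATA
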