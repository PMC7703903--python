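# SYNTHETIC anchor positions for the 5 autosomal GWAS loci
# (chromosome labels are real; positions are stand-ins).
label	chrom	position
locus_chr3	chr3	100000000
locus_chr5	chr5	1000000
locus_chr6	chr6	32000000
locus_chr11	chr11	34500000
locus_chr16	chr16	28500000
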