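# Transcript geometry for the TSC1/TSC2 coding references used throughout the package.
# cds_length excludes nothing (includes the stop codon); protein_length excludes the stop.
# n_noncoding_leading_exons: TSC1 exons 1-2 are non-coding; TSC2 has 1 non-coding guiding
# exon outside the 1-41 coding-exon numbering.
gene	transcript_id	cds_length	protein_length	n_noncoding_leading_exons
TSC1	NM_000368.4	3495	1164	2
TSC2	NM_000548.3	5424	1807	1
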