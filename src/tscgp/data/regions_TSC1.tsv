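# Two-way N/C split of the TSC1 coding exons at exon 15 (exon 15 itself on the
# N-terminal side by default; configurable in the annotation layer).
name	exon_start	exon_end
N-terminal	3	15
C-terminal	16	23
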