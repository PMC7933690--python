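# Hamartin (TSC1) functional domains. aa coordinates 1-based inclusive; TID is
# defined only by its encoding exons (no published aa interval).
name	aa_start	aa_end	exon_start	exon_end
TMD	127	144	6	6
TID			8	11
CCD	730	996	18	22
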