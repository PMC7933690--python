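# Three-way split of the TSC2 coding exons: HID-TID (E1-E22), the middle region
# (E23-E33), and the GAP region (E34-E41).
name	exon_start	exon_end
HID-TID	1	22
middle	23	33
GAP	34	41
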