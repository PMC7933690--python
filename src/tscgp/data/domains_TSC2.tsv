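# Tuberin (TSC2) functional domains, N- to C-terminal. TAD2 and CaBD overlap at
# aa 1740-1744 and are reported merged as TAD2+CaBD by the annotation layer.
name	aa_start	aa_end	exon_start	exon_end
LZD	81	98	3	3
CCD1	346	371	10	10
CCD2	1008	1021	26	26
TAD1	1163	1259	29	30
GAPD	1517	1674	34	38
TAD2	1690	1744	39	40
CaBD	1740	1755	40	41
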