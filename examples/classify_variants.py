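"""Parse coding-DNA HGVS descriptions and classify them.

Each variant is parsed against the gene's coding geometry, assigned one of
the six mutation types (missense, nonsense, frameshift, splice_site,
in_frame, large_fragment) and the binary PT/NT truncation class.
"""

from tscgp import classify_mutation_type, classify_truncation, get_reference, parse_hgvs_c

examples = [
    ("TSC1", "c.737G>A", "p.Arg246Lys"),      # declared missense substitution
    ("TSC1", "c.100_101del", None),           # 2-nt deletion: frameshift
    ("TSC2", "c.5068+1G>T", None),            # canonical splice-donor offset
    ("TSC2", "c.3487_3777del", None),         # multi-exon deletion: large fragment
    ("TSC2", "c.1000C>T", "p.(Gln334Ter)"),   # declared stop gain: nonsense
    ("TSC2", "c.3022_3027del", None),         # 6-nt deletion: in-frame
]

for gene, hgvs_c, hgvs_p in examples:
    ref = get_reference(gene)
    v = parse_hgvs_c(hgvs_c, gene, ref=ref)
    call = classify_mutation_type(v, hgvs_p, ref=ref)
    print(f"{gene} {hgvs_c:18s} -> {call.type.value:14s} "
          f"({classify_truncation(call).value})"
          f"{'  [low confidence]' if call.low_confidence else ''}")

print("\nPT = protein-truncating, NT = non-truncating; the PT/NT class is the")
print("coarse genotype grouping used in TSC genotype-phenotype comparisons.")
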