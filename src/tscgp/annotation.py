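"""Mapping classified variants onto exons, functional domains and gene regions.

A variant is located by its CDS span (intronic-offset breakpoints anchor to
their coding position).  Domain membership is decided on the residue interval
for domains with a published amino-acid range, and on the exon interval for
exon-only domains (TSC1's TID).  TSC2's overlapping TAD2 and CaBD domains are
reported under the single merged label ``TAD2+CaBD``.  Region membership
(TSC1 N-/C-terminal split at exon 15; TSC2 HID-TID / middle / GAP) is decided
by exon, with multi-exon variants assigned to the region of their 5'-most
exon and flagged when they straddle a boundary.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from .reference import DomainDef, GeneReference, RegionDef, TranscriptRef, cds_to_protein, load_reference
from .variants import MutationCall, MutationType, ParsedVariant, TruncationClass

MERGED_DOMAIN_GROUPS = {"TSC2": {frozenset({"TAD2", "CaBD"}): "TAD2+CaBD"}}


@lru_cache(maxsize=None)
def get_reference(gene: str, reference_dir: Optional[str] = None) -> GeneReference:
    """Cached accessor for the packaged (or overridden) gene reference."""
    return load_reference(gene, reference_dir)


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: ParsedVariant
    call: MutationCall
    exon_start: int
    exon_end: int
    domains: frozenset[str]
    region: str
    residue_start: int
    residue_end: int
    region_ambiguous: bool = False

    @property
    def mutation_type(self) -> MutationType:
        return self.call.type

    @property
    def truncation(self) -> TruncationClass:
        return self.call.truncation

    @property
    def exon(self) -> int | tuple[int, int]:
        return self.exon_start if self.exon_start == self.exon_end \
            else (self.exon_start, self.exon_end)


def cds_to_exon(pos: int, ref: TranscriptRef) -> int:
    """Exon number whose CDS span contains ``pos`` (binary search)."""
    exons = ref.coding_exons
    starts = _exon_starts(ref)
    if not (1 <= pos <= ref.cds_length):
        raise ValueError(f"CDS position {pos} outside [1, {ref.cds_length}]")
    i = bisect_right(starts, pos) - 1
    return exons[i].number


@lru_cache(maxsize=None)
def _exon_starts(ref: TranscriptRef) -> tuple[int, ...]:
    return tuple(e.cds_start for e in ref.coding_exons)


def assign_domains(residue_span: tuple[int, int], exon_span: tuple[int, int],
                   domains: tuple[DomainDef, ...], *, gene: Optional[str] = None,
                   merge_overlapping: bool = True) -> frozenset[str]:
    """Domain labels whose interval intersects the variant.

    aa-interval domains are matched on residues; exon-only domains (TID) on
    exon numbers.  With ``merge_overlapping`` the TAD2/CaBD pair collapses to
    ``TAD2+CaBD``.
    """
    hits: set[str] = set()
    r_lo, r_hi = residue_span
    e_lo, e_hi = exon_span
    for d in domains:
        if d.has_aa:
            if not (r_hi < d.aa_start or r_lo > d.aa_end):
                hits.add(d.name)
        else:
            if not (e_hi < d.exon_start or e_lo > d.exon_end):
                hits.add(d.name)
    if merge_overlapping and gene in MERGED_DOMAIN_GROUPS:
        for group, label in MERGED_DOMAIN_GROUPS[gene].items():
            if hits & group:
                hits -= group
                hits.add(label)
    return frozenset(hits)


def assign_region(exon_span: tuple[int, int], regions: tuple[RegionDef, ...]
                  ) -> tuple[str, bool]:
    """Region of the 5'-most affected exon, plus a boundary-straddle flag."""
    e_lo, e_hi = exon_span
    region = None
    for r in regions:
        if r.exon_start <= e_lo <= r.exon_end:
            region = r.name
            ambiguous = e_hi > r.exon_end
            return region, ambiguous
    raise ValueError(f"exon {e_lo} not covered by any region")


def annotate_variant(v: ParsedVariant, call: MutationCall,
                     ref: Optional[GeneReference] = None,
                     *, propagate_truncation: bool = False) -> AnnotatedVariant:
    """Full positional annotation of one classified variant.

    With ``propagate_truncation`` a truncating lesion is treated as affecting
    everything downstream of its own position as well (off by default: tallies
    count each mutation where it occurs).
    """
    if ref is None:
        ref = get_reference(v.gene)
    t = ref.transcript
    e_lo = cds_to_exon(v.cds_start, t)
    e_hi = cds_to_exon(v.cds_end, t)
    r_lo = cds_to_protein(v.cds_start, t.cds_length)
    r_hi = cds_to_protein(v.cds_end, t.cds_length)
    if propagate_truncation and call.truncation is TruncationClass.PT:
        r_hi = t.protein_length
        e_hi = t.coding_exons[-1].number
    domains = assign_domains((r_lo, r_hi), (e_lo, e_hi), ref.domains,
                             gene=v.gene, merge_overlapping=True)
    region, ambiguous = assign_region((e_lo, e_hi), ref.regions)
    return AnnotatedVariant(
        variant=v, call=call, exon_start=e_lo, exon_end=e_hi,
        domains=domains, region=region,
        residue_start=r_lo, residue_end=r_hi, region_ambiguous=ambiguous,
    )
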