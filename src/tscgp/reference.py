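"""Transcript geometry and functional-domain reference tables for TSC1/TSC2.

Coordinates follow the HGVS convention: CDS positions are 1-based inclusive,
position 1 is the A of the initiator ATG, and the residue carrying CDS
position ``p`` is ``ceil(p / 3)``.  TSC1 (NM_000368.4) has 23 exons of which
exons 1-2 are non-coding; TSC2 (NM_000548.3) is described with 41 coding
exons numbered 1-41 plus one non-coding guiding exon.

The packaged exon boundary tables are synthetic: they are constructed to be
consistent with the published domain/exon attributions and the true CDS
lengths, not copied from a transcript record.  Pass ``reference_dir`` to
:func:`load_reference` to substitute coordinate-accurate tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

GENES = ("TSC1", "TSC2")


class ReferenceError(ValueError):
    """Raised when a reference table is missing or violates an invariant."""


@dataclass(frozen=True)
class Exon:
    number: int
    cds_start: Optional[int]  # None for non-coding exons
    cds_end: Optional[int]
    coding: bool


@dataclass(frozen=True)
class TranscriptRef:
    gene: str
    transcript_id: str
    cds_length: int
    protein_length: int
    exons: tuple[Exon, ...]
    n_noncoding_leading_exons: int

    @property
    def coding_exons(self) -> tuple[Exon, ...]:
        return tuple(e for e in self.exons if e.coding)

    def exon_span(self, number: int) -> tuple[int, int]:
        for e in self.exons:
            if e.number == number and e.coding:
                return e.cds_start, e.cds_end
        raise ReferenceError(f"{self.gene}: no coding exon {number}")


@dataclass(frozen=True)
class DomainDef:
    gene: str
    name: str
    aa_start: Optional[int]
    aa_end: Optional[int]
    exon_start: int
    exon_end: int

    @property
    def has_aa(self) -> bool:
        return self.aa_start is not None


@dataclass(frozen=True)
class RegionDef:
    gene: str
    name: str
    exon_start: int
    exon_end: int


@dataclass(frozen=True)
class GeneReference:
    """Bundle of everything the annotation layer needs for one gene."""

    transcript: TranscriptRef
    domains: tuple[DomainDef, ...]
    regions: tuple[RegionDef, ...]


def cds_to_protein(pos: int, cds_length: Optional[int] = None) -> int:
    """Residue index carrying CDS position ``pos`` (ceil(pos/3))."""
    if pos < 1 or (cds_length is not None and pos > cds_length):
        raise ValueError(f"CDS position {pos} out of range")
    return math.ceil(pos / 3)


def _data_path(name: str, reference_dir: Optional[Path]) -> Path:
    if reference_dir is not None:
        p = Path(reference_dir) / name
        if p.exists():
            return p
        raise ReferenceError(f"reference file not found: {p}")
    res = resources.files("tscgp") / "data" / name
    with resources.as_file(res) as p:
        if not p.exists():
            raise ReferenceError(f"packaged reference file missing: {name}")
        return p


def _read_tsv(name: str, reference_dir: Optional[Path]) -> pd.DataFrame:
    return pd.read_csv(_data_path(name, reference_dir), sep="\t", comment="#")


def _find_exon_table(gene: str, reference_dir: Optional[Path]) -> pd.DataFrame:
    # user-supplied real tables take the plain name; packaged ones are synthetic
    for name in (f"exons_{gene}.tsv", f"exons_{gene}.synthetic.tsv"):
        try:
            return _read_tsv(name, reference_dir)
        except ReferenceError:
            continue
    raise ReferenceError(f"no exon table found for {gene}")


def load_reference(gene: str, reference_dir: Optional[str | Path] = None) -> GeneReference:
    """Load and validate the transcript, domain and region tables for ``gene``.

    Raises :class:`ReferenceError` with a diagnostic naming the offending row
    if any invariant fails.
    """
    if gene not in GENES:
        raise ReferenceError(f"unknown gene {gene!r}; expected one of {GENES}")
    rdir = Path(reference_dir) if reference_dir is not None else None

    tdf = _read_tsv("transcripts.tsv", rdir)
    trow = tdf[tdf["gene"] == gene]
    if trow.empty:
        raise ReferenceError(f"transcripts.tsv has no row for {gene}")
    trow = trow.iloc[0]

    edf = _find_exon_table(gene, rdir)
    exons = []
    for _, r in edf.iterrows():
        coding = bool(int(r["coding"]))
        if coding:
            exons.append(Exon(int(r["exon"]), int(r["cds_start"]), int(r["cds_end"]), True))
        else:
            exons.append(Exon(int(r["exon"]), None, None, False))

    ddf = _read_tsv(f"domains_{gene}.tsv", rdir)
    domains = []
    for _, r in ddf.iterrows():
        aa_s = None if pd.isna(r["aa_start"]) else int(r["aa_start"])
        aa_e = None if pd.isna(r["aa_end"]) else int(r["aa_end"])
        domains.append(DomainDef(gene, str(r["name"]), aa_s, aa_e,
                                 int(r["exon_start"]), int(r["exon_end"])))

    rdf = _read_tsv(f"regions_{gene}.tsv", rdir)
    regions = [RegionDef(gene, str(r["name"]), int(r["exon_start"]), int(r["exon_end"]))
               for _, r in rdf.iterrows()]

    ref = TranscriptRef(
        gene=gene,
        transcript_id=str(trow["transcript_id"]),
        cds_length=int(trow["cds_length"]),
        protein_length=int(trow["protein_length"]),
        exons=tuple(exons),
        n_noncoding_leading_exons=int(trow["n_noncoding_leading_exons"]),
    )
    bundle = GeneReference(ref, tuple(domains), tuple(regions))
    problems = validate_reference(ref, bundle.domains, bundle.regions)
    if problems:
        raise ReferenceError(f"{gene} reference failed validation: " + "; ".join(problems))
    return bundle


def validate_reference(ref: TranscriptRef,
                       domains: Sequence[DomainDef],
                       regions: Sequence[RegionDef]) -> list[str]:
    """Return one diagnostic string per invariant violation (empty if valid)."""
    out: list[str] = []
    coding = [e for e in ref.exons if e.coding]

    # exon spans: disjoint, ordered, tiling [1, cds_length]
    prev_end = 0
    for e in coding:
        if e.cds_start is None or e.cds_end is None:
            out.append(f"exon {e.number}: coding exon with empty span")
            continue
        if e.cds_start != prev_end + 1:
            out.append(f"exon {e.number}: span starts at {e.cds_start}, expected {prev_end + 1}")
        if e.cds_end < e.cds_start:
            out.append(f"exon {e.number}: end {e.cds_end} before start {e.cds_start}")
        prev_end = e.cds_end
    if coding and prev_end != ref.cds_length:
        out.append(f"exon table ends at {prev_end}, cds_length is {ref.cds_length}")

    if ref.protein_length != ref.cds_length // 3 - 1 or ref.cds_length % 3 != 0:
        out.append(
            f"protein_length {ref.protein_length} inconsistent with cds_length "
            f"{ref.cds_length} (expected cds_length/3 - 1)"
        )

    n_noncoding = sum(1 for e in ref.exons if not e.coding)
    if n_noncoding != ref.n_noncoding_leading_exons:
        out.append(
            f"{n_noncoding} non-coding exons in table, transcripts.tsv says "
            f"{ref.n_noncoding_leading_exons}"
        )

    coding_numbers = {e.number for e in coding}
    for d in domains:
        if d.has_aa:
            if not (1 <= d.aa_start <= d.aa_end <= ref.protein_length):
                out.append(f"domain {d.name}: aa {d.aa_start}-{d.aa_end} outside protein "
                           f"1-{ref.protein_length}")
                continue
            # aa interval translated to nucleotides must live in the stated exons
            nt_lo, nt_hi = 3 * (d.aa_start - 1) + 1, 3 * d.aa_end
            spans = {e.number for e in coding if not (e.cds_end < nt_lo or e.cds_start > nt_hi)}
            if spans and (min(spans) != d.exon_start or max(spans) != d.exon_end):
                out.append(f"domain {d.name}: aa interval occupies exons "
                           f"{min(spans)}-{max(spans)}, table says {d.exon_start}-{d.exon_end}")
        if d.exon_start not in coding_numbers or d.exon_end not in coding_numbers:
            out.append(f"domain {d.name}: exon range {d.exon_start}-{d.exon_end} "
                       f"references non-coding or missing exons")

    # regions partition the coding exons
    covered: dict[int, str] = {}
    for r in regions:
        for n in range(r.exon_start, r.exon_end + 1):
            if n in covered:
                out.append(f"region {r.name}: exon {n} already in region {covered[n]}")
            covered[n] = r.name
    for e in coding:
        if e.number not in covered:
            out.append(f"coding exon {e.number} not covered by any region")
    for n in covered:
        if n not in coding_numbers:
            out.append(f"region table references exon {n} which is not a coding exon")

    return out
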