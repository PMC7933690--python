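"""Parsing and classification of coding-DNA HGVS variant descriptions.

Supports the subset of HGVS c.-notation that covers point mutations and
small/large rearrangements in germline screening reports: substitutions
(``c.737G>A``), deletions (``c.1_3del``), duplications, insertions
(``c.100_101insTG``), deletion-insertions, and intronic offsets on either
breakpoint (``c.5068+1G>T``).  Inversions, extensions, mosaic and allele
syntax are deliberately unsupported and raise :class:`UnsupportedVariantError`
so callers can distinguish "not HGVS" from "HGVS we do not model".

Classification follows the six-type taxonomy used in TSC genotype-phenotype
work — missense, nonsense, frameshift, splice_site, in_frame,
large_fragment — and its binary coarsening into protein-truncating (PT:
frameshift, splice_site, nonsense, large_fragment) versus non-truncating
(NT: missense, in_frame) classes.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Optional

from .reference import GeneReference, TranscriptRef, cds_to_protein

__all__ = [
    "MutationType", "TruncationClass", "ParsedVariant", "MutationCall",
    "HgvsParseError", "HgvsRangeError", "UnsupportedVariantError",
    "UnresolvableClassError", "parse_hgvs_c", "serialize_hgvs",
    "classify_mutation_type", "classify_truncation", "cds_to_protein",
]


class HgvsParseError(ValueError):
    """Malformed c.-description."""


class HgvsRangeError(ValueError):
    """Syntactically valid description whose positions fall outside the CDS."""


class UnsupportedVariantError(ValueError):
    """Valid HGVS form that this model deliberately does not handle."""


class UnresolvableClassError(ValueError):
    """Substitution whose missense/nonsense status cannot be determined."""


class MutationType(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    IN_FRAME = "in_frame"
    LARGE_FRAGMENT = "large_fragment"


class TruncationClass(str, enum.Enum):
    PT = "PT"  # protein-truncating
    NT = "NT"  # non-truncating


_PT_TYPES = frozenset({
    MutationType.FRAMESHIFT, MutationType.SPLICE_SITE,
    MutationType.NONSENSE, MutationType.LARGE_FRAGMENT,
})


@dataclass(frozen=True)
class ParsedVariant:
    gene: str
    raw: str
    kind: str  # substitution | deletion | duplication | insertion | delins
    cds_start: int
    cds_end: int
    intron_offset: Optional[int] = None       # offset at the 5' breakpoint
    intron_offset_end: Optional[int] = None   # offset at the 3' breakpoint
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None
    length_change: int = 0
    protein_note: Optional[str] = None

    @property
    def span(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def is_intronic(self) -> bool:
        return bool(self.intron_offset) or bool(self.intron_offset_end)


@dataclass(frozen=True)
class MutationCall:
    """A mutation-type call, with a flag for calls made without full evidence."""

    type: MutationType
    low_confidence: bool = False

    @property
    def truncation(self) -> TruncationClass:
        return classify_truncation(self.type)


_POS = r"(\d+)([+-]\d+)?"
_NUC = r"[ACGTacgt]+"
_RE_SUB = re.compile(rf"^{_POS}([ACGTacgt])>([ACGTacgt])$")
_RE_RANGE = re.compile(rf"^{_POS}(?:_{_POS})?(delins|del|dup|ins)({_NUC})?$")
_UNSUPPORTED = re.compile(r"(inv|con|ext|\[|\]|\(|\)|=|\?|;)")


def _normalize(text: str) -> str:
    return re.sub(r"\s+", "", text)


def parse_hgvs_c(text: str, gene: str, *, ref: Optional[GeneReference | TranscriptRef] = None,
                 cds_length: Optional[int] = None) -> ParsedVariant:
    """Parse one c.-description into a :class:`ParsedVariant`.

    Positions are validated against the gene's CDS length, loaded from the
    packaged reference unless ``ref``/``cds_length`` is given.  Parsing is
    idempotent: re-parsing :func:`serialize_hgvs` of the result yields an
    equal value.
    """
    norm = _normalize(text)
    if not norm.startswith("c."):
        raise HgvsParseError(f"{text!r}: c.-description must start with 'c.'")
    body = norm[2:]
    if not body:
        raise HgvsParseError(f"{text!r}: empty description")
    if _UNSUPPORTED.search(body):
        raise UnsupportedVariantError(f"{text!r}: unsupported HGVS form")

    if cds_length is None:
        if ref is None:
            from .annotation import get_reference  # cached loader; avoids import cycle
            ref = get_reference(gene)
        cds_length = ref.cds_length if isinstance(ref, TranscriptRef) else ref.transcript.cds_length

    m = _RE_SUB.match(body)
    if m:
        pos, off = int(m.group(1)), m.group(2)
        _check_pos(pos, cds_length, text)
        return ParsedVariant(
            gene=gene, raw=text, kind="substitution", cds_start=pos, cds_end=pos,
            intron_offset=int(off) if off else None,
            ref_allele=m.group(3).upper(), alt_allele=m.group(4).upper(),
            length_change=0,
        )

    m = _RE_RANGE.match(body)
    if m:
        start, off1 = int(m.group(1)), m.group(2)
        end = int(m.group(3)) if m.group(3) else start
        off2 = m.group(4) if m.group(3) else off1
        op, seq = m.group(5), m.group(6)
        if end < start:
            raise HgvsParseError(f"{text!r}: end position {end} before start {start}")
        _check_pos(start, cds_length, text)
        _check_pos(end, cds_length, text)
        span = end - start + 1
        seq = seq.upper() if seq else None

        if op == "del":
            if seq and len(seq) != span:
                raise HgvsParseError(f"{text!r}: deleted sequence length {len(seq)} "
                                     f"does not match span {span}")
            kind, length_change, ref_a, alt_a = "deletion", -span, seq, None
        elif op == "dup":
            if seq and len(seq) != span:
                raise HgvsParseError(f"{text!r}: duplicated sequence length {len(seq)} "
                                     f"does not match span {span}")
            kind, length_change, ref_a, alt_a = "duplication", span, seq, None
        elif op == "ins":
            if not seq:
                raise HgvsParseError(f"{text!r}: insertion without inserted sequence")
            if span != 2 and not (off1 or off2):
                raise HgvsParseError(f"{text!r}: insertion requires two flanking positions")
            kind, length_change, ref_a, alt_a = "insertion", len(seq), None, seq
        else:  # delins
            if not seq:
                raise HgvsParseError(f"{text!r}: delins without replacement sequence")
            kind, length_change, ref_a, alt_a = "delins", len(seq) - span, None, seq

        return ParsedVariant(
            gene=gene, raw=text, kind=kind, cds_start=start, cds_end=end,
            intron_offset=int(off1) if off1 else None,
            intron_offset_end=int(off2) if off2 else None,
            ref_allele=ref_a, alt_allele=alt_a, length_change=length_change,
        )

    raise HgvsParseError(f"{text!r}: unrecognized c.-description syntax")


def _check_pos(pos: int, cds_length: int, text: str) -> None:
    if not (1 <= pos <= cds_length):
        raise HgvsRangeError(f"{text!r}: CDS position {pos} outside [1, {cds_length}]")


def serialize_hgvs(v: ParsedVariant) -> str:
    """Canonical c.-string for a parsed variant (round-trips through the parser)."""
    def pos(p: int, off: Optional[int]) -> str:
        return f"{p}{off:+d}" if off else str(p)

    if v.kind == "substitution":
        return f"c.{pos(v.cds_start, v.intron_offset)}{v.ref_allele}>{v.alt_allele}"
    left = pos(v.cds_start, v.intron_offset)
    right = pos(v.cds_end, v.intron_offset_end)
    loc = left if (v.cds_start == v.cds_end and v.intron_offset == v.intron_offset_end) \
        else f"{left}_{right}"
    if v.kind == "deletion":
        return f"c.{loc}del" + (v.ref_allele or "")
    if v.kind == "duplication":
        return f"c.{loc}dup" + (v.ref_allele or "")
    if v.kind == "insertion":
        return f"c.{loc}ins{v.alt_allele}"
    return f"c.{loc}delins{v.alt_allele}"


_TER = re.compile(r"(Ter|\*|X)(?!\w)", re.IGNORECASE)
_AA3 = ("Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val")
_MISSENSE_P = re.compile(rf"p\.\(?({_AA3})\d+({_AA3})\)?", re.IGNORECASE)
_FS_P = re.compile(r"fs", re.IGNORECASE)


def classify_mutation_type(
    v: ParsedVariant,
    declared: Optional[str] = None,
    *,
    ref: Optional[GeneReference] = None,
    splice_window: int = 2,
    large_fragment_nt: int = 50,
    strict: bool = False,
) -> MutationCall:
    """Assign one of the six mutation types to a parsed variant.

    Precedence: splice-site (intronic offset within ``splice_window``, or any
    intronic offset the ``declared`` label calls splicing) → large fragment
    (affected span ≥ ``large_fragment_nt`` or containing an entire exon) →
    frame assessment for indels → missense/nonsense for substitutions, taken
    from the declared protein consequence.  A declared missense consequence
    overrides a splice offset (dual effects are tallied once, as declared).
    A substitution with no usable declared consequence is returned as
    low-confidence missense, or raises in ``strict`` mode.
    """
    declared = declared or v.protein_note or ""

    splice_declared = bool(re.search(r"splic", declared, re.IGNORECASE))
    if v.is_intronic:
        offs = [o for o in (v.intron_offset, v.intron_offset_end) if o]
        within = any(abs(o) <= splice_window for o in offs)
        if _MISSENSE_P.search(declared) and not splice_declared:
            return MutationCall(MutationType.MISSENSE)
        if within or splice_declared:
            return MutationCall(MutationType.SPLICE_SITE)
        if strict:
            raise UnresolvableClassError(
                f"{v.raw!r}: intronic offset beyond ±{splice_window} with no declared label")
        return MutationCall(MutationType.SPLICE_SITE, low_confidence=True)

    if v.kind in ("deletion", "duplication", "delins"):
        if v.span >= large_fragment_nt or _contains_whole_exon(v, ref):
            return MutationCall(MutationType.LARGE_FRAGMENT)

    if v.kind in ("deletion", "duplication", "insertion", "delins"):
        if v.length_change % 3 != 0:
            return MutationCall(MutationType.FRAMESHIFT)
        if _TER.search(declared):
            return MutationCall(MutationType.NONSENSE)
        return MutationCall(MutationType.IN_FRAME)

    # substitution
    if _TER.search(declared):
        return MutationCall(MutationType.NONSENSE)
    if _FS_P.search(declared):
        return MutationCall(MutationType.FRAMESHIFT)
    if _MISSENSE_P.search(declared):
        return MutationCall(MutationType.MISSENSE)
    if strict:
        raise UnresolvableClassError(
            f"{v.raw!r}: substitution with no declared protein consequence")
    return MutationCall(MutationType.MISSENSE, low_confidence=True)


def _contains_whole_exon(v: ParsedVariant, ref: Optional[GeneReference]) -> bool:
    if ref is None:
        return False
    for e in ref.transcript.coding_exons:
        if v.cds_start <= e.cds_start and e.cds_end <= v.cds_end:
            return True
    return False


def classify_truncation(t: MutationType | MutationCall) -> TruncationClass:
    """PT for frameshift/splice-site/nonsense/large-fragment, NT otherwise."""
    if isinstance(t, MutationCall):
        t = t.type
    return TruncationClass.PT if t in _PT_TYPES else TruncationClass.NT


def with_protein_note(v: ParsedVariant, note: Optional[str]) -> ParsedVariant:
    return replace(v, protein_note=note)
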