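"""Packaged example data.

Two things live here:

* :func:`published_tables` / :func:`published_prevalences` — the aggregate
  2x2 contingency counts of a literature-curated cohort of 261 TSC patients
  (54 TSC1 / 207 TSC2) scored for renal angiomyolipoma, loaded from the
  packaged JSON.  These are the exact inputs for reproducing the published
  odds ratios and p-values.

* :func:`example_cohort` — a SYNTHETIC patient-level reconstruction of that
  cohort: 261 records whose gene, mutation-type, sex and RAML margins, and
  whose TSC2 functional-domain contingency counts, equal the aggregate
  counts.  Individual variant positions are representative placements inside
  the relevant domain/region intervals, not real patient variants.  The
  published RAML-side region counts (HID-TID 41 / middle 34 / GAP 21) are
  arithmetically inconsistent with the published RAML-side domain counts
  (GAPD 8 + TAD2/CaBD 14 = 22 mutations all inside the GAP region), so the
  reconstruction reproduces the domain table exactly and the region counts
  come out 41 / 33 / 22 on the RAML side (the non-RAML side, 47 / 27 / 26,
  is consistent and reproduced exactly).
"""

from __future__ import annotations

import json
from importlib import resources
from itertools import cycle

from .pipeline import CohortRecord
from .stats import Table2x2

__all__ = ["published_tables", "published_prevalences", "example_cohort"]


def _load_counts() -> dict:
    text = (resources.files("tscgp") / "data" / "cohort_counts.json").read_text()
    return json.loads(text)


def published_tables() -> dict[str, Table2x2]:
    """Label -> Table2x2 of the published contingency counts."""
    return {k: Table2x2(*v) for k, v in _load_counts()["tables"].items()}


def published_prevalences() -> dict[str, tuple[int, int]]:
    """Label -> (RAML cases, denominator) for the published prevalence figures."""
    return {k: tuple(v) for k, v in _load_counts()["prevalence"].items()}


# ------------------------------------------------------------ example cohort
#
# Slot tables: (count, slot) per gene and RAML status.  A slot names either a
# domain interval, an "others" interval within one region, or a large-fragment
# template.  Types are drawn from per-group type pools so the per-type totals
# match the aggregate counts; the TAD1 slots carry their own published type
# composition.

_AA3 = ["Ala", "Arg", "Asn", "Asp", "Gly", "His", "Leu", "Lys", "Ser", "Val"]

# SNV placement intervals (CDS nt) chosen to lie inside the target domain, or
# inside the target region while avoiding every aa-defined domain; donor
# anchors are exon 3' ends inside the same stratum, for splice variants.
_TSC2_SLOTS = {
    "CCD1": {"interval": (1040, 1110), "donors": [1120]},
    "CCD2": {"interval": (3025, 3060), "donors": []},
    "TAD1": {"interval": (3490, 3770), "donors": [3611]},
    "GAPD": {"interval": (4555, 5015), "donors": [4650, 4760]},
    "TAD2+CaBD": {"interval": (5070, 5260), "donors": [5238]},
    "others_HID": {"interval": (400, 930), "donors": [570, 690, 810]},
    "others_mid": {"interval": (3100, 3400), "donors": [3282]},
    "others_GAP": {"interval": (5024, 5060), "donors": [5030]},
}
_TSC1_SLOTS = {
    "TMD": {"interval": (380, 430), "donors": []},
    "TID": {"interval": (605, 1115), "donors": [737, 860, 990]},
    "CCD": {"interval": (2190, 2985), "donors": [2340, 2520]},
    "others_N": {"interval": (1125, 1695), "donors": [1250, 1440]},
    "others_C": {"interval": (1765, 2175), "donors": [1920]},
}

# (slot, count) in emission order; "TAD1:<type>" pins the type.
_TSC2_PLAN = {
    True: [("CCD1", 3), ("CCD2", 1),
           ("TAD1:nonsense", 8), ("TAD1:splice", 1), ("TAD1:frameshift", 3),
           ("TAD1:missense", 3),
           ("GAPD", 8), ("TAD2+CaBD", 14),
           ("others_HID", 38), ("others_mid", 17), ("others_GAP", 0)],
    False: [("CCD1", 3), ("CCD2", 4),
            ("TAD1:missense", 1), ("TAD1:nonsense", 2), ("TAD1:splice", 1),
            ("TAD1:frameshift", 1),
            ("GAPD", 11), ("TAD2+CaBD", 13),
            ("others_HID", 44), ("others_mid", 18), ("others_GAP", 2)],
}
# remaining type pool per RAML group after the pinned TAD1 slots
_TSC2_POOL = {
    True: [("frameshift", 33), ("nonsense", 13), ("splice", 9),
           ("in_frame", 4), ("missense", 22)],
    False: [("frameshift", 26), ("nonsense", 17), ("splice", 13),
            ("in_frame", 6), ("missense", 33)],
}
_TSC2_LF = {True: 8, False: 3}

_TSC1_PLAN = {
    True: [("TMD", 2), ("TID", 6), ("others_N", 9), ("CCD", 3), ("others_C", 1)],
    False: [("TID", 4), ("others_N", 12), ("CCD", 8), ("others_C", 5)],
}
_TSC1_POOL = {
    True: [("nonsense", 6), ("frameshift", 4), ("missense", 11)],
    False: [("nonsense", 12), ("frameshift", 15), ("missense", 2)],
}
_TSC1_LF = {True: 1, False: 3}

# multi-exon deletion templates (span >= one whole exon)
_LF_TEMPLATES = {
    "TSC1": ["c.141_990del", "c.481_1250del", "c.1761_2700del", "c.2341_2990del"],
    "TSC2": ["c.151_1035del", "c.1036_2030del", "c.2291_3021del", "c.3433_3780del",
             "c.4031_4548del", "c.4549_5030del", "c.811_1770del", "c.2681_3432del",
             "c.241_930del", "c.5031_5424del", "c.1901_2680del"],
}


def _emit_variant(slot: dict, mtype: str, idx: int) -> tuple[str, str | None]:
    """Deterministic (hgvs_c, hgvs_p) for one slot occupant."""
    lo, hi = slot["interval"]
    width = hi - lo - 6
    pos = lo + (7 * idx) % max(width, 1)
    res = (pos + 2) // 3
    aa1, aa2 = _AA3[idx % len(_AA3)], _AA3[(idx + 3) % len(_AA3)]
    if mtype == "missense":
        return f"c.{pos}G>A", f"p.({aa1}{res}{aa2})"
    if mtype == "nonsense":
        return f"c.{pos}C>T", f"p.({aa1}{res}Ter)"
    if mtype == "frameshift":
        return f"c.{pos}_{pos + 1}del", None
    if mtype == "in_frame":
        return f"c.{pos}_{pos + 2}del", None
    if mtype == "splice":
        donors = slot["donors"]
        anchor = donors[idx % len(donors)]
        return f"c.{anchor}{'+' if idx % 2 == 0 else '+'}{1 + idx % 2}G>T", None
    raise ValueError(mtype)


def example_cohort() -> list[CohortRecord]:
    """Deterministic 261-record synthetic reconstruction of the study cohort."""
    records: list[CohortRecord] = []

    def add(gene: str, raml: bool, hgvs_c: str, hgvs_p):
        records.append(CohortRecord(
            patient_id=f"P{len(records) + 1:03d}", gene=gene, hgvs_c=hgvs_c,
            raml=raml, hgvs_p=hgvs_p, sex="unknown", source="synthetic"))

    for gene, slots, plan, pool, lf_n in (
            ("TSC1", _TSC1_SLOTS, _TSC1_PLAN, _TSC1_POOL, _TSC1_LF),
            ("TSC2", _TSC2_SLOTS, _TSC2_PLAN, _TSC2_POOL, _TSC2_LF)):
        for raml in (True, False):
            types = [t for t, n in pool[raml] for _ in range(n)]
            ti = iter(types)
            idx = 0
            for slot_name, count in plan[raml]:
                pinned = None
                if ":" in slot_name:
                    slot_name, pinned = slot_name.split(":")
                slot = slots[slot_name]
                for _ in range(count):
                    mtype = pinned if pinned else next(ti)
                    hgvs_c, hgvs_p = _emit_variant(slot, mtype, idx)
                    add(gene, raml, hgvs_c, hgvs_p)
                    idx += 1
            leftovers = list(ti)
            assert not leftovers, (gene, raml, leftovers)
            for j in range(lf_n[raml]):
                add(gene, raml, _LF_TEMPLATES[gene][j % len(_LF_TEMPLATES[gene])], None)

    # sex margins: 47 F / 21 M among RAML, 38 F / 42 M among non-RAML,
    # remainder unknown (independent of gene and mutation type).
    quotas = {True: {"female": 47, "male": 21}, False: {"female": 38, "male": 42}}
    out: list[CohortRecord] = []
    for rec in records:
        q = quotas[rec.raml]
        sex = "unknown"
        for s in ("female", "male"):
            if q[s] > 0:
                sex, q[s] = s, q[s] - 1
                break
        out.append(CohortRecord(**{**rec.__dict__, "sex": sex}))
    return out
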