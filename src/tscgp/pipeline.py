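"""End-to-end cohort analysis: ingest, annotate, compare, report.

The analysis mirrors the standard genotype-phenotype workup for a TSC
case-control cohort scored for renal angiomyolipoma (RAML):

1. gene (TSC1 vs TSC2) against RAML;
2. sex against RAML, on the known-sex subset;
3. per gene, each mutation type against all other types, and the PT vs NT
   truncation classes;
4. per gene, each functional domain against all other mutations, with
   large-fragment variants excluded (their breakpoints cannot be placed
   within a domain);
5. per gene, the coding-region split (TSC1 N-/C-terminal; TSC2
   HID-TID / middle / GAP), also on the large-fragment-excluded set.

Every comparison carries the rule-selected test, the Woolf odds ratio and,
when configured, the crude logistic odds ratio.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd

from . import __version__
from .annotation import AnnotatedVariant, annotate_variant, get_reference
from .stats import (ORResult, Table2x2, TestResult,
                    logistic_crude_or, odds_ratio_woolf, run_selected_test)
from .variants import (HgvsParseError, HgvsRangeError, MutationType, TruncationClass,
                       UnsupportedVariantError, classify_mutation_type, parse_hgvs_c)

SEXES = ("male", "female", "unknown")
COHORT_COLUMNS = ("patient_id", "gene", "transcript", "hgvs_c", "hgvs_p",
                  "sex", "raml", "source")
MANDATORY_COLUMNS = ("patient_id", "gene", "hgvs_c", "raml")

_METHOD_MARKERS = {"chi_square": "", "chi_square_yates": "&", "fisher_exact": "^"}


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    gene: str
    hgvs_c: str
    raml: bool
    sex: str = "unknown"
    hgvs_p: Optional[str] = None
    transcript: Optional[str] = None
    source: Optional[str] = None


@dataclass
class ValidationReport:
    n_read: int = 0
    n_accepted: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (patient_id, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.rejected


@dataclass(frozen=True)
class AnnotatedRecord:
    record: CohortRecord
    annotation: AnnotatedVariant


@dataclass(frozen=True)
class Comparison:
    gene_scope: str  # "all" or a gene
    family: str      # gene | sex | type | truncation | domain | region
    label: str       # exposure category
    table: Table2x2
    test: Optional[TestResult]
    or_woolf: Optional[ORResult]
    or_logistic: Optional[ORResult] = None
    p_adjusted: Optional[float] = None
    note: Optional[str] = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.gene_scope, self.family, self.label)


@dataclass
class AnalysisReport:
    comparisons: list[Comparison]
    metadata: dict

    def get(self, family: str, label: str, gene_scope: Optional[str] = None) -> Comparison:
        for c in self.comparisons:
            if c.family == family and c.label == label and \
                    (gene_scope is None or c.gene_scope == gene_scope):
                return c
        raise KeyError((family, label, gene_scope))


@dataclass(frozen=True)
class AnalysisConfig:
    logistic: bool = False
    bh: bool = False           # annotate Benjamini-Hochberg adjusted p-values
    alpha: float = 0.05
    strict_classification: bool = False
    reference_dir: Optional[str] = None


def read_cohort(path: str | Path) -> tuple[list[CohortRecord], ValidationReport]:
    """Read a cohort CSV/TSV; return accepted records and an itemized report.

    Machine-checkable exclusions mirror curation practice: unknown gene,
    missing or multi-variant HGVS fields (two ``c.`` descriptions in one
    record), and unparseable descriptions are rejected row by row; a
    duplicated patient_id or a missing mandatory column is a hard error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#").fillna("")
    report = ValidationReport(n_read=len(df))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing mandatory column(s): {missing}")
    if len(df) == 0:
        report.warnings.append("empty cohort file")
        return [], report
    dup = df["patient_id"][df["patient_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate patient_id(s): {sorted(set(dup))}")

    records: list[CohortRecord] = []
    for _, row in df.iterrows():
        pid = row["patient_id"]
        gene = row["gene"].strip().upper()
        hgvs = row["hgvs_c"].strip()
        if gene not in ("TSC1", "TSC2"):
            report.rejected.append((pid, f"unknown gene {row['gene']!r}"))
            continue
        if not hgvs:
            report.rejected.append((pid, "missing hgvs_c"))
            continue
        if hgvs.count("c.") > 1 or ";" in hgvs:
            report.rejected.append((pid, "multiple variants in one record"))
            continue
        raml_raw = row["raml"].strip().lower()
        if raml_raw in ("1", "true", "yes", "y"):
            raml = True
        elif raml_raw in ("0", "false", "no", "n"):
            raml = False
        else:
            report.rejected.append((pid, f"unparseable raml value {row['raml']!r}"))
            continue
        sex = (row.get("sex", "") or "unknown").strip().lower() or "unknown"
        if sex not in SEXES:
            report.rejected.append((pid, f"unparseable sex value {row['sex']!r}"))
            continue
        records.append(CohortRecord(
            patient_id=pid, gene=gene, hgvs_c=hgvs, raml=raml, sex=sex,
            hgvs_p=(row.get("hgvs_p", "") or None) or None,
            transcript=(row.get("transcript", "") or None) or None,
            source=(row.get("source", "") or None) or None,
        ))
    report.n_accepted = len(records)
    return records, report


def annotate_cohort(records: Sequence[CohortRecord],
                    config: AnalysisConfig = AnalysisConfig()
                    ) -> tuple[list[AnnotatedRecord], ValidationReport]:
    """Parse, classify and positionally annotate every record.

    Records whose HGVS description cannot be parsed or classified are
    itemized in the validation report rather than raising.
    """
    out: list[AnnotatedRecord] = []
    report = ValidationReport(n_read=len(records))
    for rec in records:
        try:
            ref = get_reference(rec.gene, config.reference_dir)
            v = parse_hgvs_c(rec.hgvs_c, rec.gene, ref=ref)
            call = classify_mutation_type(v, rec.hgvs_p, ref=ref,
                                          strict=config.strict_classification)
            ann = annotate_variant(v, call, ref)
        except (HgvsParseError, HgvsRangeError, UnsupportedVariantError, ValueError) as e:
            report.rejected.append((rec.patient_id, str(e)))
            continue
        out.append(AnnotatedRecord(rec, ann))
    report.n_accepted = len(out)
    return out, report


def build_table(pairs: Sequence[AnnotatedRecord],
                exposure: Callable[[AnnotatedRecord], bool]) -> Table2x2:
    """Exposure x RAML counts under the orientation contract (a = exposed & RAML)."""
    if not pairs:
        raise ValueError("empty cohort")
    a = b = c = d = 0
    for p in pairs:
        if exposure(p):
            a, b = (a + 1, b) if p.record.raml else (a, b + 1)
        else:
            c, d = (c + 1, d) if p.record.raml else (c, d + 1)
    return Table2x2(a, b, c, d)


def _compare(pairs: Sequence[AnnotatedRecord], exposure, gene_scope: str,
             family: str, label: str, config: AnalysisConfig) -> Comparison:
    table = build_table(pairs, exposure)
    degenerate = 0 in table.row_totals or 0 in table.col_totals
    if degenerate:
        return Comparison(gene_scope, family, label, table, None, None,
                          note="degenerate margin: test and OR undefined")
    test = run_selected_test(table)
    orw = odds_ratio_woolf(table, alpha=config.alpha)
    orl = None
    if config.logistic and min(table.a, table.b, table.c, table.d) > 0:
        orl = logistic_crude_or(table, alpha=config.alpha)
    return Comparison(gene_scope, family, label, table, test, orw, orl)


def analyze(records: Sequence[CohortRecord],
            config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Run every comparison of the standard workup on an ingested cohort."""
    pairs, ann_report = annotate_cohort(records, config)
    comparisons: list[Comparison] = []
    notes: list[str] = []

    genes = sorted({p.record.gene for p in pairs})
    if len(genes) > 1:
        comparisons.append(_compare(
            pairs, lambda p: p.record.gene == "TSC1", "all", "gene", "TSC1", config))
    else:
        notes.append("single-gene cohort: gene comparison omitted")

    known_sex = [p for p in pairs if p.record.sex in ("male", "female")]
    if known_sex and len({p.record.sex for p in known_sex}) > 1:
        comparisons.append(_compare(
            known_sex, lambda p: p.record.sex == "female", "all", "sex", "female", config))
    else:
        notes.append("sex comparison omitted (no contrast among known-sex records)")

    for gene in genes:
        sub = [p for p in pairs if p.record.gene == gene]
        for tc in (TruncationClass.PT, TruncationClass.NT):
            comparisons.append(_compare(
                sub, lambda p, tc=tc: p.annotation.truncation is tc,
                gene, "truncation", tc.value, config))
        present = sorted({p.annotation.mutation_type for p in sub}, key=lambda t: t.value)
        for mt in present:
            comparisons.append(_compare(
                sub, lambda p, mt=mt: p.annotation.mutation_type is mt,
                gene, "type", mt.value, config))

        # domain and region analyses exclude large-fragment variants
        no_lf = [p for p in sub
                 if p.annotation.mutation_type is not MutationType.LARGE_FRAGMENT]
        if not no_lf:
            continue
        ref = get_reference(gene, config.reference_dir)
        labels = _domain_labels(gene, ref)
        for name in labels:
            comparisons.append(_compare(
                no_lf, lambda p, name=name: name in p.annotation.domains,
                gene, "domain", name, config))
        comparisons.append(_compare(
            no_lf, lambda p: not p.annotation.domains, gene, "domain", "Others", config))
        for region in ref.regions:
            comparisons.append(_compare(
                no_lf, lambda p, r=region.name: p.annotation.region == r,
                gene, "region", region.name, config))

    if config.bh:
        comparisons = _annotate_bh(comparisons)

    n_lf = {g: sum(1 for p in pairs if p.record.gene == g and
                   p.annotation.mutation_type is MutationType.LARGE_FRAGMENT)
            for g in genes}
    metadata = {
        "version": __version__,
        "n_records": len(records),
        "n_annotated": len(pairs),
        "n_per_gene": {g: sum(1 for p in pairs if p.record.gene == g) for g in genes},
        "n_unknown_sex": sum(1 for p in pairs if p.record.sex == "unknown"),
        "n_large_fragment": n_lf,
        "annotation_rejected": [list(x) for x in ann_report.rejected],
        "notes": notes,
        "config": {"logistic": config.logistic, "bh": config.bh, "alpha": config.alpha},
    }
    return AnalysisReport(comparisons, metadata)


def _domain_labels(gene: str, ref) -> list[str]:
    from .annotation import MERGED_DOMAIN_GROUPS
    labels, seen = [], set()
    merged = MERGED_DOMAIN_GROUPS.get(gene, {})
    for d in ref.domains:
        label = d.name
        for group, merged_label in merged.items():
            if d.name in group:
                label = merged_label
        if label not in seen:
            labels.append(label)
            seen.add(label)
    return labels


def _annotate_bh(comparisons: list[Comparison]) -> list[Comparison]:
    from dataclasses import replace
    from statsmodels.stats.multitest import multipletests
    idx = [i for i, c in enumerate(comparisons) if c.test is not None]
    if not idx:
        return comparisons
    adj = multipletests([comparisons[i].test.p_value for i in idx], method="fdr_bh")[1]
    out = list(comparisons)
    for i, p in zip(idx, adj):
        out[i] = replace(out[i], p_adjusted=float(p))
    return out


# ---------------------------------------------------------------- reporting

def report_to_dataframe(report: AnalysisReport) -> pd.DataFrame:
    """Tabular view mirroring the published table layout.

    Percentages are column percentages (share of the RAML / non-RAML groups
    within the comparison), rounded to 2 decimals; p-values and ORs to 3.
    """
    rows = []
    for c in report.comparisons:
        t = c.table
        n_raml, n_non = t.col_totals
        row = {
            "gene_scope": c.gene_scope, "family": c.family, "category": c.label,
            "raml_n": t.a,
            "raml_pct": round(100 * t.a / n_raml, 2) if n_raml else None,
            "nonraml_n": t.b,
            "nonraml_pct": round(100 * t.b / n_non, 2) if n_non else None,
            "p": round(c.test.p_value, 3) if c.test else None,
            "method": (c.test.method + _marker(c)) if c.test else "-",
            "or": round(c.or_woolf.or_point, 3) if c.or_woolf and c.or_woolf.defined else None,
            "ci_low": round(c.or_woolf.ci_low, 3) if c.or_woolf and c.or_woolf.defined else None,
            "ci_high": round(c.or_woolf.ci_high, 3) if c.or_woolf and c.or_woolf.defined else None,
        }
        if c.or_logistic is not None:
            row["logistic_or"] = round(c.or_logistic.or_point, 3)
            row["logistic_p"] = round(c.or_logistic.p_value, 3)
        if c.p_adjusted is not None:
            row["p_bh"] = round(c.p_adjusted, 3)
        rows.append(row)
    return pd.DataFrame(rows)


def _marker(c: Comparison) -> str:
    return _METHOD_MARKERS.get(c.test.method, "") if c.test else ""


def write_report(report: AnalysisReport, path: Optional[str | Path] = None,
                 fmt: str = "tsv") -> str:
    """Serialize a report to TSV (rounded, table-style) or JSON (lossless)."""
    if fmt == "tsv":
        df = report_to_dataframe(report)
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        text = buf.getvalue()
    elif fmt == "json":
        text = json.dumps(report_to_json_dict(report), indent=2, sort_keys=True)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def report_to_json_dict(report: AnalysisReport) -> dict:
    def ord_(o: Optional[ORResult]):
        return None if o is None else {
            "or": o.or_point, "ci_low": o.ci_low, "ci_high": o.ci_high,
            "alpha": o.alpha, "method": o.method, "p_value": o.p_value,
            "adjusted": o.adjusted}
    return {
        "metadata": report.metadata,
        "comparisons": [{
            "gene_scope": c.gene_scope, "family": c.family, "label": c.label,
            "table": [c.table.a, c.table.b, c.table.c, c.table.d],
            "test": None if c.test is None else c.test.to_dict(),
            "or_woolf": ord_(c.or_woolf), "or_logistic": ord_(c.or_logistic),
            "p_adjusted": c.p_adjusted, "note": c.note,
        } for c in report.comparisons],
    }


def report_from_json_dict(d: dict) -> AnalysisReport:
    def orr(o):
        return None if o is None else ORResult(
            o["or"], o["ci_low"], o["ci_high"], o["alpha"], o["method"],
            p_value=o["p_value"], adjusted=o["adjusted"])
    comps = []
    for c in d["comparisons"]:
        test = None if c["test"] is None else TestResult(
            method=c["test"]["method"], p_value=c["test"]["p_value"],
            statistic=c["test"]["statistic"])
        comps.append(Comparison(
            c["gene_scope"], c["family"], c["label"], Table2x2(*c["table"]),
            test, orr(c["or_woolf"]), orr(c["or_logistic"]),
            p_adjusted=c["p_adjusted"], note=c["note"]))
    return AnalysisReport(comps, d["metadata"])
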