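"""Screening-vs-diagnostic concordance: parsing, matching and metrics.

The diagnostic comparator (chromosomal microarray, CMA) reports findings as
ISCN-like strings, e.g. ``arr[GRCh37] 21q11.2q22.3(15,016,486_48,093,361)×3``.
This module parses that dialect, classifies findings (common trisomy, rare
autosomal trisomy, sex-chromosome aneuploidy, CNV, ROH), matches screening
calls against findings and reduces the matched cohort to the clinical
metrics: sensitivity (detected over diagnostic-positives), PPV (confirmed
over screen-positives) and miss rate, with 95% confidence intervals
(Wilson score with continuity correction by default).

Coordinates: printed strings are 1-based inclusive; internally everything
is 0-based half-open (BED convention), so a printed pair (s, e) becomes
(s−1, e) and the reported fragment size is the printed difference e − s.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GRCH37, GenomeInfo

__all__ = [
    "DiagnosticFinding",
    "DiagnosticFindingSet",
    "ConcordancePair",
    "MetricRow",
    "ConcordanceReport",
    "parse_iscn",
    "classify_finding",
    "finding_size_mb",
    "match_calls",
    "compute_metrics",
    "stratify_cnv",
    "annotate_syndrome",
    "build_report",
    "wilson_cc_interval",
    "SYNDROME_REGIONS",
    "CNV_STRATA",
]

# canonical karyotype tokens for whole-karyotype findings
_KARYOTYPES = {
    "45,X": "45,X", "45,XO": "45,X", "45,X0": "45,X",
    "47,XXY": "47,XXY", "47,XXX": "47,XXX", "47,XYY": "47,XYY",
}

# share of the reportable span an interval must cover to count as a
# whole-chromosome (aneuploidy-equivalent) finding.  Printed trisomy
# intervals cover 62–100% of their chromosomes (acrocentric q arms only,
# occasionally stopping short of qter), so the cut sits at 70%.
WHOLE_CHROM_COVERAGE = 0.70

# diagnostic selection floor: deletions > 0.5 Mb, duplications > 1 Mb enter
# the concordance; smaller CMA findings are excluded
MIN_DEL_MB = 0.5
MIN_DUP_MB = 1.0

#: CNV size strata (Mb).  Boundary membership follows the table wording:
#: 1.0 falls in "500 kb to ≤ 1 Mb", 5.0 in "3 to ≤ 5 Mb", 10.0 in "≥ 10 Mb".
CNV_STRATA: tuple[tuple[str, float, float], ...] = (
    ("500 kb to <=1 Mb", 0.5, 1.0),
    ("1 to <=2 Mb", 1.0, 2.0),
    ("2 to <=3 Mb", 2.0, 3.0),
    ("3 to <=5 Mb", 3.0, 5.0),
    ("5 to <10 Mb", 5.0, 10.0),
    (">=10 Mb", 10.0, np.inf),
)

#: Canonical GRCh37 regions of the recurrent microdeletion/microduplication
#: syndromes (approximate literature coordinates).  sign: -1 deletion,
#: +1 duplication, 0 either.
SYNDROME_REGIONS: dict[str, tuple[str, int, int, int]] = {
    "1p36 microdeletion": ("chr1", 0, 10_000_000, -1),
    "cri-du-chat (5p15)": ("chr5", 0, 12_500_000, -1),
    "Williams-Beuren (7q11.23)": ("chr7", 72_700_000, 74_200_000, -1),
    "9p deletion/duplication": ("chr9", 0, 16_000_000, 0),
    "Angelman/Prader-Willi (15q11-q13)": ("chr15", 22_800_000, 28_400_000, -1),
    "RCAD (17q12)": ("chr17", 34_800_000, 36_200_000, -1),
    "DiGeorge (22q11.2)": ("chr22", 18_900_000, 21_500_000, -1),
}


@dataclass(frozen=True)
class DiagnosticFinding:
    """One parsed CMA finding.

    ``start``/``end`` are internal 0-based half-open (None for
    whole-karyotype findings); ``copy_number_range`` is set for mosaic
    findings ("×2–3"); ``category`` is one of T21/T18/T13/RAT/SCA/
    CNV_DUP/CNV_DEL/ROH.
    """

    chromosome: str
    start: int | None
    end: int | None
    copy_number: int
    copy_number_range: tuple[int, int] | None
    mosaic: bool
    category: str
    karyotype: str | None
    raw: str
    band: str = ""

    @property
    def interval_scoped(self) -> bool:
        return self.start is not None

    def format(self) -> str:
        """Canonical ISCN-like rendering (inverse of :func:`parse_iscn`)."""
        if not self.interval_scoped:
            return self.karyotype or self.raw
        chrom_token = self.chromosome.removeprefix("chr")
        if self.copy_number_range is not None:
            lo, hi = self.copy_number_range
            cn = f"{lo}–{hi}"
        else:
            cn = str(self.copy_number)
        return (
            f"arr[GRCh37] {chrom_token}{self.band}"
            f"({self.start + 1:,}_{self.end:,})×{cn}"
        )


_ISCN_RE = re.compile(
    r"^arr\[GRCh37\]\]?\s*"
    r"(?P<chrom>[0-9]{1,2}|[XY])"
    r"(?P<band>[pq][0-9.]*(?:ter)?(?:[pq][0-9.]*(?:ter)?)?)?"
    r"\(\s*(?P<start>[0-9,]+)\s*_\s*(?P<end>[0-9,]+)\s*\)"
    r"[×xX](?P<cn>\d+)(?:[–—\-_](?P<cn2>\d+))?"
    r"\s*(?P<hmz>hmz)?\s*$"
)


def parse_iscn(raw: str, genome: GenomeInfo = GRCH37) -> DiagnosticFinding:
    """Parse one ISCN-like result string or whole-karyotype token."""
    s = raw.strip()
    token = s.upper().replace(" ", "")
    if token in _KARYOTYPES:
        karyo = _KARYOTYPES[token]
        chrom = "chrX" if karyo != "47,XYY" else "chrY"
        return DiagnosticFinding(
            chromosome=chrom, start=None, end=None,
            copy_number={"45,X": 1, "47,XXX": 3, "47,XXY": 2, "47,XYY": 2}[karyo],
            copy_number_range=None, mosaic=False,
            category="SCA", karyotype=karyo, raw=raw,
        )
    m = _ISCN_RE.match(s)
    if m is None:
        raise ValueError(f"cannot parse ISCN string: {raw!r}")
    chrom = "chr" + m.group("chrom")
    if chrom not in genome.lengths:
        raise ValueError(f"unknown chromosome token {m.group('chrom')!r} in {raw!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if not start1 < end1:
        raise ValueError(f"degenerate interval in {raw!r}")
    cn = int(m.group("cn"))
    cn2 = m.group("cn2")
    if cn2 is not None:
        lo, hi = sorted((cn, int(cn2)))
        cn_range: tuple[int, int] | None = (lo, hi)
        mosaic = True
        # representative copy state: the endpoint farther from diploid;
        # symmetric ranges (1-3) resolve to the loss side
        cn = lo if (2 - lo) >= (hi - 2) else hi
    else:
        cn_range, mosaic = None, False
    f = DiagnosticFinding(
        chromosome=chrom, start=start1 - 1, end=end1,
        copy_number=cn, copy_number_range=cn_range, mosaic=mosaic,
        category="", karyotype=None, raw=raw, band=m.group("band") or "",
    )
    if m.group("hmz"):
        return replace(f, category="ROH")
    return classify_finding(f, genome)


def classify_finding(f: DiagnosticFinding, genome: GenomeInfo = GRCH37) -> DiagnosticFinding:
    """Assign the screening-relevant category to a parsed finding."""
    if f.category == "ROH" or not f.interval_scoped:
        return f
    span_lo, span_hi = genome.reportable_span(f.chromosome)
    span = max(span_hi - span_lo, 1)
    overlap = max(0, min(f.end, span_hi) - max(f.start, span_lo))
    whole = overlap >= WHOLE_CHROM_COVERAGE * span
    cn = f.copy_number
    if f.chromosome == "chrX" and whole:
        karyo = {1: "45,X", 2: "47,XXY", 3: "47,XXX"}.get(cn)
        if karyo:
            return replace(f, category="SCA", karyotype=karyo)
    if f.chromosome == "chrY" and whole:
        karyo = {0: "45,X", 2: "47,XYY"}.get(cn)
        if karyo:
            return replace(f, category="SCA", karyotype=karyo)
    if whole and f.chromosome not in ("chrX", "chrY"):
        if cn > 2:
            num = f.chromosome.removeprefix("chr")
            if num in ("21", "18", "13"):
                return replace(f, category=f"T{num}")
            return replace(f, category="RAT")
        # whole-chromosome loss of an autosome: treat as a giant deletion
        return replace(f, category="CNV_DEL")
    # baseline copy state: 1 for the single male chrY, 2 elsewhere
    baseline = 1 if f.chromosome == "chrY" else 2
    if cn == baseline:
        # a copy-neutral interval (printed only for homozygous stretches)
        return replace(f, category="ROH")
    return replace(f, category="CNV_DUP" if cn > baseline else "CNV_DEL")


def finding_size_mb(f: DiagnosticFinding) -> float:
    """Fragment size in Mb, the printed-coordinate difference."""
    if not f.interval_scoped:
        raise ValueError("whole-karyotype finding has no fragment size")
    return (f.end - (f.start + 1)) / 1e6


@dataclass
class DiagnosticFindingSet:
    """All CMA findings of one sample."""

    sample_id: str
    findings: list[DiagnosticFinding] = field(default_factory=list)

    def merged(self, genome: GenomeInfo = GRCH37, gap_bp: int = 1_000_000
               ) -> list[DiagnosticFinding]:
        """Merge abutting same-copy-number interval findings, reclassify.

        Arrays print one chromosome-scale event as several adjacent
        segments (the printed 47,XYY is two abutting chrY ×2 intervals);
        merging recovers the chromosome-scale interpretation.
        """
        intervals = [f for f in self.findings if f.interval_scoped and f.category != "ROH"]
        rest = [f for f in self.findings if not f.interval_scoped or f.category == "ROH"]
        out: list[DiagnosticFinding] = []
        bychrom: dict[tuple[str, int, bool], list[DiagnosticFinding]] = {}
        for f in intervals:
            bychrom.setdefault((f.chromosome, f.copy_number, f.mosaic), []).append(f)
        for group in bychrom.values():
            group = sorted(group, key=lambda f: f.start)
            cur = group[0]
            for f in group[1:]:
                if f.start - cur.end <= gap_bp:
                    cur = replace(cur, end=max(cur.end, f.end),
                                  raw=cur.raw + " + " + f.raw)
                else:
                    out.append(classify_finding(cur, genome))
                    cur = f
            out.append(classify_finding(cur, genome))
        return rest + out

    def categories(self, genome: GenomeInfo = GRCH37) -> dict:
        """Screening-comparable content: trisomy chroms, SCA, CNV findings."""
        trisomies: set[str] = set()
        sca: str | None = None
        cnvs: list[DiagnosticFinding] = []
        for f in self.merged(genome):
            if f.category in ("T21", "T18", "T13", "RAT"):
                trisomies.add(f.chromosome)
            elif f.category == "SCA":
                sca = f.karyotype
            elif f.category in ("CNV_DUP", "CNV_DEL"):
                size = finding_size_mb(f)
                floor = MIN_DUP_MB if f.category == "CNV_DUP" else MIN_DEL_MB
                if size >= floor:
                    cnvs.append(f)
            # ROH findings are not screenable and never count
        return {"trisomies": trisomies, "sca": sca, "cnvs": cnvs}


def stratify_cnv(size_mb: float) -> str | None:
    """Size-stratum label, or ``None`` below the 0.5 Mb selection floor."""
    if size_mb < 0.5:
        return None
    if size_mb <= 1.0:
        return "500 kb to <=1 Mb"
    if size_mb <= 2.0:
        return "1 to <=2 Mb"
    if size_mb <= 3.0:
        return "2 to <=3 Mb"
    if size_mb <= 5.0:
        return "3 to <=5 Mb"
    if size_mb < 10.0:
        return "5 to <10 Mb"
    return ">=10 Mb"


def annotate_syndrome(
    f: DiagnosticFinding,
    table: dict[str, tuple[str, int, int, int]] = SYNDROME_REGIONS,
) -> str | None:
    """Name the recurrent syndrome a finding hits (≥ 50% region overlap)."""
    if not f.interval_scoped:
        return None
    sign = 1 if f.copy_number > 2 else -1 if f.copy_number < 2 else 0
    for name, (chrom, lo, hi, s) in table.items():
        if f.chromosome != chrom:
            continue
        if s != 0 and sign != s:
            continue
        overlap = max(0, min(f.end, hi) - max(f.start, lo))
        if overlap >= 0.5 * (hi - lo):
            return name
    return None


# ---------------------------------------------------------------------------
# Matching and metrics
# ---------------------------------------------------------------------------

ANEUPLOIDY_LABELS = ("T21", "T18", "T13", "SCA", "RAT")


@dataclass
class ConcordancePair:
    """One sample's screening calls matched against its CMA findings."""

    sample_id: str
    counts: dict[str, dict[str, int]]
    cnv_rows: list[dict]   # one per eligible diagnostic CNV finding
    fp_cnvs: list[dict]    # screening CNV calls with no diagnostic match


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = max(0, min(a_end, b_end) - max(a_start, b_start))
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def match_calls(
    screening,
    diagnostic: DiagnosticFindingSet,
    genome: GenomeInfo = GRCH37,
    overlap_rule: float = 0.25,
    syndrome_table: dict | None = None,
) -> ConcordancePair:
    """Classify one sample's calls as TP/FP/FN/TN per category.

    ``screening`` needs ``autosome_calls`` (with .chromosome/.call),
    ``sca_karyotype``, ``cnv_calls`` (with .chromosome/.start_bp/.end_bp/
    .state/.origin) and ``no_call``.  Aneuploidies match by chromosome or
    karyotype identity; CNVs by same sign and reciprocal overlap.
    """
    diag = diagnostic.categories(genome)
    no_call = bool(getattr(screening, "no_call", False))
    s_tri = set() if no_call else {
        c.chromosome for c in screening.autosome_calls if c.call == "trisomy"
    }
    s_mono = set() if no_call else {
        c.chromosome for c in screening.autosome_calls if c.call == "monosomy"
    }
    s_sca = None if no_call else screening.sca_karyotype
    s_cnvs = [] if no_call else list(screening.cnv_calls)

    counts = {lab: {"TP": 0, "FP": 0, "FN": 0, "TN": 0} for lab in
              ANEUPLOIDY_LABELS + ("CNV",)}

    for lab, chrom in (("T21", "chr21"), ("T18", "chr18"), ("T13", "chr13")):
        s, d = chrom in s_tri, chrom in diag["trisomies"]
        key = "TP" if (s and d) else "FP" if s else "FN" if d else "TN"
        counts[lab][key] += 1

    common = {"chr21", "chr18", "chr13"}
    s_rat = (s_tri - common) | s_mono
    d_rat = diag["trisomies"] - common
    counts["RAT"]["TP"] += len(s_rat & d_rat)
    counts["RAT"]["FP"] += len(s_rat - d_rat)
    counts["RAT"]["FN"] += len(d_rat - s_rat)
    if not s_rat and not d_rat:
        counts["RAT"]["TN"] += 1

    if s_sca or diag["sca"]:
        if s_sca and diag["sca"]:
            if s_sca == diag["sca"]:
                counts["SCA"]["TP"] += 1
            else:  # discordant karyotypes: one FP and one FN
                counts["SCA"]["FP"] += 1
                counts["SCA"]["FN"] += 1
        elif s_sca:
            counts["SCA"]["FP"] += 1
        else:
            counts["SCA"]["FN"] += 1
    else:
        counts["SCA"]["TN"] += 1

    # CNVs: greedy best-overlap matching, same sign, reciprocal >= rule
    used: set[int] = set()
    cnv_rows = []
    for f in diag["cnvs"]:
        sign = "dup" if f.category == "CNV_DUP" else "del"
        best, best_ov = None, 0.0
        for i, c in enumerate(s_cnvs):
            if i in used or c.state != sign or c.chromosome != f.chromosome:
                continue
            ov = _reciprocal_overlap(c.start_bp, c.end_bp, f.start, f.end)
            if ov >= overlap_rule and ov > best_ov:
                best, best_ov = i, ov
        detected = best is not None
        if detected:
            used.add(best)
            counts["CNV"]["TP"] += 1
        else:
            counts["CNV"]["FN"] += 1
        size = finding_size_mb(f)
        cnv_rows.append({
            "sample_id": diagnostic.sample_id,
            "size_mb": size,
            "stratum": stratify_cnv(size),
            "detected": detected,
            "maternal_origin": detected and s_cnvs[best].origin == "maternal",
            "larger_called": detected and (
                (s_cnvs[best].end_bp - s_cnvs[best].start_bp) / 1e6 > 2 * size
            ),
            "syndrome": annotate_syndrome(f, syndrome_table) if syndrome_table
            else annotate_syndrome(f),
        })
    fp_cnvs = []
    for i, c in enumerate(s_cnvs):
        if i not in used:
            counts["CNV"]["FP"] += 1
            fp_cnvs.append({
                "sample_id": diagnostic.sample_id, "chromosome": c.chromosome,
                "size_mb": c.size_mb, "state": c.state, "origin": c.origin,
            })
    if not diag["cnvs"] and not s_cnvs:
        counts["CNV"]["TN"] += 1

    return ConcordancePair(
        sample_id=diagnostic.sample_id, counts=counts,
        cnv_rows=cnv_rows, fp_cnvs=fp_cnvs,
    )


def wilson_cc_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction, on proportions."""
    from scipy.stats import norm

    if n == 0:
        raise ValueError("zero denominator")
    z = norm.ppf(1 - (1 - conf) / 2)
    p = k / n
    z2 = z * z
    denom = 2 * (n + z2)
    if k == 0:
        lo = 0.0
    else:
        lo = (2 * n * p + z2 - 1 - z * np.sqrt(
            z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
    if k == n:
        hi = 1.0
    else:
        hi = (2 * n * p + z2 + 1 + z * np.sqrt(
            z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
    return max(0.0, lo), min(1.0, hi)


def _interval(k: int, n: int, method: str) -> tuple[float, float]:
    if method == "wilson_cc":
        return wilson_cc_interval(k, n)
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
    return float(lo), float(hi)


@dataclass
class MetricRow:
    """One row of a sensitivity/PPV table (percentages)."""

    label: str
    n_screen_positive: int | None = None
    n_confirmed: int | None = None
    n_diagnostic_positive: int | None = None
    n_detected: int | None = None
    sensitivity: float | None = None
    ppv: float | None = None
    miss_rate: float | None = None
    ci95: tuple[float, float] | None = None
    flagged: bool = False


def compute_metrics(
    label: str,
    n_screen_positive: int | None = None,
    n_confirmed: int | None = None,
    n_diagnostic_positive: int | None = None,
    n_detected: int | None = None,
    ci_method: str = "wilson_cc",
) -> MetricRow:
    """Sensitivity/PPV/miss-rate row from raw counts.

    The 95% CI covers the primary rate: sensitivity when diagnostic counts
    are present, PPV otherwise.  Zero denominators leave the rate undefined
    and flag the row.
    """
    row = MetricRow(
        label=label,
        n_screen_positive=n_screen_positive,
        n_confirmed=n_confirmed,
        n_diagnostic_positive=n_diagnostic_positive,
        n_detected=n_detected,
    )
    if n_diagnostic_positive is not None and n_detected is not None:
        if n_detected > n_diagnostic_positive:
            raise ValueError(f"{label}: detected exceeds diagnostic positives")
        if n_diagnostic_positive > 0:
            row.sensitivity = 100.0 * n_detected / n_diagnostic_positive
            row.miss_rate = 100.0 - row.sensitivity
            lo, hi = _interval(n_detected, n_diagnostic_positive, ci_method)
            row.ci95 = (100.0 * lo, 100.0 * hi)
        else:
            row.flagged = True
    if n_screen_positive is not None and n_confirmed is not None:
        if n_confirmed > n_screen_positive:
            raise ValueError(f"{label}: confirmed exceeds screen positives")
        if n_screen_positive > 0:
            row.ppv = 100.0 * n_confirmed / n_screen_positive
            if row.ci95 is None:
                lo, hi = _interval(n_confirmed, n_screen_positive, ci_method)
                row.ci95 = (100.0 * lo, 100.0 * hi)
        else:
            row.flagged = True
    if row.sensitivity is None and row.ppv is None:
        row.flagged = True
    return row


@dataclass
class ConcordanceReport:
    """Stratified metric tables mirroring a screening-vs-CMA comparison."""

    aneuploidy: list[MetricRow]
    cnv_strata: list[MetricRow]
    cnv_maternal: dict[str, int]
    syndromes: list[MetricRow]
    n_pairs: int

    def to_dict(self) -> dict:
        def rows(rws):
            return [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in r.__dict__.items()} for r in rws
            ]

        return {
            "n_pairs": self.n_pairs,
            "aneuploidy": rows(self.aneuploidy),
            "cnv_strata": rows(self.cnv_strata),
            "cnv_maternal_origin": self.cnv_maternal,
            "syndromes": rows(self.syndromes),
        }


def build_report(
    pairs: list[ConcordancePair], ci_method: str = "wilson_cc"
) -> ConcordanceReport:
    """Aggregate matched pairs into the metric tables.

    Per category: diagnostic positives = TP+FN, detected = TP, screen
    positives = TP+FP, confirmed = TP (count conservation by construction).
    """
    labels = ANEUPLOIDY_LABELS
    agg = {lab: {"TP": 0, "FP": 0, "FN": 0, "TN": 0} for lab in labels + ("CNV",)}
    for p in pairs:
        for lab, c in p.counts.items():
            for k, v in c.items():
                agg[lab][k] += v

    aneu_rows = []
    for lab in labels:
        c = agg[lab]
        aneu_rows.append(compute_metrics(
            lab,
            n_screen_positive=c["TP"] + c["FP"], n_confirmed=c["TP"],
            n_diagnostic_positive=c["TP"] + c["FN"], n_detected=c["TP"],
            ci_method=ci_method,
        ))
    tot = {k: sum(agg[lab][k] for lab in labels) for k in ("TP", "FP", "FN", "TN")}
    aneu_rows.append(compute_metrics(
        "aneuploidy_total",
        n_screen_positive=tot["TP"] + tot["FP"], n_confirmed=tot["TP"],
        n_diagnostic_positive=tot["TP"] + tot["FN"], n_detected=tot["TP"],
        ci_method=ci_method,
    ))

    cnv_rows_all = [r for p in pairs for r in p.cnv_rows]
    strata_rows, maternal = [], {}
    for label, _, _ in CNV_STRATA:
        sub = [r for r in cnv_rows_all if r["stratum"] == label]
        if not sub:
            continue
        det = sum(r["detected"] for r in sub)
        strata_rows.append(compute_metrics(
            label, n_diagnostic_positive=len(sub), n_detected=det,
            ci_method=ci_method,
        ))
        maternal[label] = sum(r["maternal_origin"] for r in sub)
    if cnv_rows_all:
        strata_rows.append(compute_metrics(
            "total", n_diagnostic_positive=len(cnv_rows_all),
            n_detected=sum(r["detected"] for r in cnv_rows_all),
            ci_method=ci_method,
        ))
        maternal["total"] = sum(r["maternal_origin"] for r in cnv_rows_all)

    syn_rows = []
    named = [r for r in cnv_rows_all if r.get("syndrome")]
    for name in SYNDROME_REGIONS:
        sub = [r for r in named if r["syndrome"] == name]
        if sub:
            syn_rows.append(compute_metrics(
                name, n_diagnostic_positive=len(sub),
                n_detected=sum(r["detected"] for r in sub), ci_method=ci_method,
            ))

    return ConcordanceReport(
        aneuploidy=aneu_rows, cnv_strata=strata_rows, cnv_maternal=maternal,
        syndromes=syn_rows, n_pairs=len(pairs),
    )


def fixture_metrics(rows: list[dict], ci_method: str = "wilson_cc") -> list[MetricRow]:
    """Metric rows from transcribed count fixtures (label + count columns)."""
    out = []
    for r in rows:
        def geti(key):
            v = r.get(key)
            if v is None or v == "":
                return None
            return int(v)

        out.append(compute_metrics(
            str(r["label"]),
            n_screen_positive=geti("n_screen_positive"),
            n_confirmed=geti("n_confirmed"),
            n_diagnostic_positive=geti("n_diagnostic_positive"),
            n_detected=geti("n_detected"),
            ci_method=ci_method,
        ))
    return out
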