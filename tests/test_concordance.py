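"""ISCN parsing, call matching, metric arithmetic and report building."""

import csv
from types import SimpleNamespace

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from cfscreen.concordance import (
    ANEUPLOIDY_LABELS,
    DiagnosticFinding,
    DiagnosticFindingSet,
    annotate_syndrome,
    build_report,
    compute_metrics,
    finding_size_mb,
    fixture_metrics,
    match_calls,
    parse_iscn,
    stratify_cnv,
    wilson_cc_interval,
)
from cfscreen.io import fixture_path, read_fixture


def _strings_fixture():
    with open(fixture_path("iscn_strings.tsv"), newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


class TestParseIscn:
    @pytest.mark.parametrize("row", _strings_fixture(),
                             ids=lambda r: r["raw"][:40])
    def test_diagnostic_strings_classified(self, row):
        f = parse_iscn(row["raw"])
        assert f.chromosome == row["chromosome"]
        assert f.category == row["category"]
        assert (f.karyotype or "") == row["karyotype"]
        assert f.mosaic == (row["mosaic"] == "True")

    def test_format_parse_idempotent(self):
        for row in _strings_fixture():
            once = parse_iscn(row["raw"]).format()
            twice = parse_iscn(once).format()
            assert once == twice

    def test_coordinates_and_size(self):
        f = parse_iscn("arr[GRCh37] 21q11.2q22.3(15,016,486_48,093,361)×3")
        assert f.start == 15_016_485 and f.end == 48_093_361  # 0-based half-open
        assert finding_size_mb(f) == pytest.approx(33.076875, abs=1e-9)
        y = parse_iscn("arr[GRCh37] Yp11.2q11.23(5,997,807_28,799,653)×0")
        assert finding_size_mb(y) == pytest.approx(22.801846, abs=1e-9)

    def test_mosaic_range_parsed(self):
        f = parse_iscn("arr[GRCh37] 21q21.3q22.3(28,054,301_48,093,361)×2–3")
        assert f.mosaic and f.copy_number_range == (2, 3)

    @pytest.mark.parametrize("bad", [
        "arr[GRCh38] 21q11(1_2)×3",      # wrong build token
        "arr[GRCh37] 21q11(5_2)×3",      # degenerate interval
        "arr[GRCh37] 25q11(1_2)×3",      # no such chromosome
        "21q11.2q22.3(1_2)×3",           # missing arr prefix
        "arr[GRCh37] 21q11(1_2)",        # missing copy number
    ])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_iscn(bad)

    def test_karyotype_size_undefined(self):
        with pytest.raises(ValueError):
            finding_size_mb(parse_iscn("45,XO"))

    def test_whole_karyotype_tokens(self):
        assert parse_iscn("45,XO").karyotype == "45,X"
        assert parse_iscn("47,xyy").karyotype == "47,XYY"


class TestFindingSet:
    def test_adjacent_y_duplications_merge_to_xyy(self):
        s = DiagnosticFindingSet("s1", [
            parse_iscn("arr[GRCh37] Yp11.31p11.2(2,650,424_9,172,827)×2"),
            parse_iscn("arr[GRCh37] Yp11.2q11.23(9,329,329_28,799,654)×2"),
        ])
        cats = s.categories()
        assert cats["sca"] == "47,XYY" and not cats["cnvs"]

    def test_roh_never_screenable(self):
        s = DiagnosticFindingSet("s2", [
            parse_iscn("arr[GRCh37]16p13.3q24.3(85,880_45,000,000)×2 hmz"),
        ])
        cats = s.categories()
        assert not cats["cnvs"] and not cats["trisomies"] and cats["sca"] is None

    def test_small_cma_findings_excluded(self):
        s = DiagnosticFindingSet("s3", [
            parse_iscn("arr[GRCh37]10q25.3(116,000,001_116,400,000)×1"),  # 0.4 Mb del
            parse_iscn("arr[GRCh37]10q25.3(116,000,001_116,800,000)×3"),  # 0.8 Mb dup
        ])
        assert s.categories()["cnvs"] == []


class TestStratify:
    @pytest.mark.parametrize("size, label", [
        (1.0, "500 kb to <=1 Mb"),
        (10.0, ">=10 Mb"),
        (0.4, None),
        (5.0, "3 to <=5 Mb"),
        (9.99, "5 to <10 Mb"),
        (2.5, "2 to <=3 Mb"),
    ])
    def test_boundaries(self, size, label):
        assert stratify_cnv(size) == label


class TestSyndromes:
    def test_named_regions(self):
        f = parse_iscn("arr[GRCh37]22q11.21(18,900,001_21,460,000)×1")
        assert annotate_syndrome(f) == "DiGeorge (22q11.2)"
        f = parse_iscn("arr[GRCh37]17q12(34,820,001_36,190,000)×1")
        assert annotate_syndrome(f) == "RCAD (17q12)"

    def test_sign_and_overlap_required(self):
        dup = parse_iscn("arr[GRCh37]22q11.21(18,900,001_21,460,000)×3")
        assert annotate_syndrome(dup) is None  # DiGeorge region is a deletion
        other = parse_iscn("arr[GRCh37]2p16(30,000,001_34,000,000)×3")
        assert annotate_syndrome(other) is None


class TestMetrics:
    def test_sensitivity_and_ppv_examples(self):
        row = compute_metrics("T21", n_diagnostic_positive=29, n_detected=28)
        assert row.sensitivity == pytest.approx(96.55, abs=0.005)
        assert row.miss_rate == pytest.approx(100 - 96.55, abs=0.005)
        row = compute_metrics("T21", n_screen_positive=31, n_confirmed=28)
        assert row.ppv == pytest.approx(90.32, abs=0.005)
        row = compute_metrics("RAT", n_screen_positive=8, n_confirmed=4)
        assert row.ppv == pytest.approx(50.0, abs=1e-9)

    def test_zero_denominator_flagged(self):
        row = compute_metrics("x", n_diagnostic_positive=0, n_detected=0)
        assert row.flagged and row.sensitivity is None

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics("x", n_diagnostic_positive=5, n_detected=6)

    def test_ci_brackets_point_and_shrinks(self):
        small = compute_metrics("x", n_diagnostic_positive=10, n_detected=9)
        large = compute_metrics("x", n_diagnostic_positive=1000, n_detected=900)
        for row in (small, large):
            lo, hi = row.ci95
            assert 0 <= lo <= row.sensitivity <= hi <= 100
        assert (large.ci95[1] - large.ci95[0]) < (small.ci95[1] - small.ci95[0])

    def test_wilson_cc_wider_than_wilson(self):
        for k, n in [(28, 29), (4, 8), (1, 4)]:
            lo_cc, hi_cc = wilson_cc_interval(k, n)
            lo_w, hi_w = proportion_confint(k, n, method="wilson")
            assert lo_cc <= lo_w and hi_cc >= hi_w
            assert 0 <= lo_cc <= k / n <= hi_cc <= 1


def _screen(trisomies=(), sca=None, cnvs=(), no_call=False):
    return SimpleNamespace(
        no_call=no_call,
        autosome_calls=[SimpleNamespace(chromosome=c, call="trisomy")
                        for c in trisomies],
        sca_karyotype=sca,
        cnv_calls=[SimpleNamespace(chromosome=c[0], start_bp=c[1], end_bp=c[2],
                                   state=c[3], origin=c[4], size_mb=(c[2]-c[1])/1e6)
                   for c in cnvs],
    )


def _diag(strings, sample_id="s"):
    return DiagnosticFindingSet(sample_id, [parse_iscn(s) for s in strings])


class TestMatchCalls:
    def test_concordant_t21(self):
        pair = match_calls(
            _screen(trisomies=("chr21",)),
            _diag(["arr[GRCh37] 21q11.2q22.3(15,016,486_48,093,361)×3"]))
        assert pair.counts["T21"] == {"TP": 1, "FP": 0, "FN": 0, "TN": 0}

    def test_discordant_sca_is_fp_plus_fn(self):
        pair = match_calls(_screen(sca="45,X"), _diag(["47,XYY"]))
        assert pair.counts["SCA"]["FP"] == 1 and pair.counts["SCA"]["FN"] == 1

    def test_cnv_reciprocal_overlap_match(self):
        # screening call inside a larger diagnostic CNV, ~30% reciprocal
        diag = _diag(["arr[GRCh37]4q31(140,000,001_150,000,000)×1"])
        pair = match_calls(
            _screen(cnvs=[("chr4", 141_000_000, 144_100_000, "del", "fetal")]),
            diag)
        assert pair.counts["CNV"]["TP"] == 1
        assert pair.cnv_rows[0]["detected"]
        # printed size 150,000,000 − 140,000,001 = 9.999999 Mb
        assert pair.cnv_rows[0]["stratum"] == "5 to <10 Mb"

    def test_cnv_below_overlap_is_fp_and_fn(self):
        diag = _diag(["arr[GRCh37]4q31(140,000,001_150,000,000)×1"])
        pair = match_calls(
            _screen(cnvs=[("chr4", 141_000_000, 142_000_000, "del", "fetal")]),
            diag)
        assert pair.counts["CNV"] == {"TP": 0, "FP": 1, "FN": 1, "TN": 0}

    def test_sign_must_agree(self):
        diag = _diag(["arr[GRCh37]4q31(140,000,001_150,000,000)×1"])
        pair = match_calls(
            _screen(cnvs=[("chr4", 140_000_000, 150_000_000, "dup", "fetal")]),
            diag)
        assert pair.counts["CNV"]["FN"] == 1 and pair.counts["CNV"]["FP"] == 1

    def test_all_negative_is_tn(self):
        pair = match_calls(_screen(), _diag([]))
        for lab in ANEUPLOIDY_LABELS + ("CNV",):
            assert pair.counts[lab]["TN"] == 1

    def test_rat_matched_by_chromosome(self):
        pair = match_calls(
            _screen(trisomies=("chr16",)),
            _diag(["arr[GRCh37]16p13.3q24.3(85,880_90,155,062)×2–3"]))
        assert pair.counts["RAT"]["TP"] == 1

    def test_count_conservation_in_report(self):
        pairs = [
            match_calls(_screen(trisomies=("chr21",)),
                        _diag(["arr[GRCh37] 21q11.2q22.3(15,016,486_48,093,361)×3"])),
            match_calls(_screen(trisomies=("chr21",)), _diag([])),
            match_calls(_screen(), _diag(["47,XXY"])),
        ]
        report = build_report(pairs)
        t21 = next(r for r in report.aneuploidy if r.label == "T21")
        assert t21.n_diagnostic_positive == 1 and t21.n_detected == 1
        assert t21.n_screen_positive == 2 and t21.n_confirmed == 1
        sca = next(r for r in report.aneuploidy if r.label == "SCA")
        assert sca.n_diagnostic_positive == 1 and sca.n_detected == 0


class TestFixtures:
    def test_ppv_fixture_shape(self):
        rows = read_fixture(fixture_path("aneuploidy_ppv.tsv"))
        assert len(rows) == 5
        assert [r["label"] for r in rows] == ["T21", "T18", "T13", "SCA", "RAT"]

    def test_all_count_fixtures_reproduce_printed_rates(self):
        from cfscreen.io import list_fixtures
        for name in list_fixtures():
            if "iscn" in name:
                continue
            raw = read_fixture(fixture_path(name))
            rows = fixture_metrics(raw)
            for rec, row in zip(raw, rows):
                if "printed_pct" not in rec:
                    continue
                got = row.sensitivity if row.sensitivity is not None else row.ppv
                assert got == pytest.approx(rec["printed_pct"], abs=0.0051), (
                    f"{name}:{row.label}")

    def test_empty_report_no_crash(self):
        report = build_report([])
        assert report.n_pairs == 0 and report.cnv_strata == []
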