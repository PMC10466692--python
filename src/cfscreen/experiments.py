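"""Validation experiments exercising the pipeline end to end.

Each function runs one self-contained study on synthetic cohorts — null
calibration of the Z statistic, fetal-fraction parameter recovery,
segmentation-vs-DP agreement, CNV size–sensitivity, and the confined-
placental-mosaicism / fetal-mosaicism discordance mechanisms — and returns
plain numbers.  The acceptance script and the test suite both run these,
so the reported figures are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .aneuploidy import AUTOSOMES
from .cnv import SegmentationConfig, optimal_partition, segment
from .concordance import match_calls
from .fetal_fraction import estimate_ff_seqff, estimate_ff_y, train_seqff
from .genome import SyntheticGenome
from .io import fixture_path, read_fixture
from .pipeline import ScreeningPipeline
from .simulate import (
    GenomicEvent,
    SimSampleSpec,
    simulate_cohort,
    simulate_sample,
    truth_to_diagnostic,
)

__all__ = [
    "default_pipeline",
    "fixture_rates",
    "null_calibration",
    "ff_recovery",
    "segmentation_oracle",
    "size_sensitivity",
    "mechanism_rates",
]


def default_pipeline(seed: int = 42,
                     panel_n: int = 50) -> tuple[SyntheticGenome, ScreeningPipeline]:
    """Reduced genome plus a pipeline fitted on a euploid reference panel."""
    genome = SyntheticGenome()
    panel = simulate_cohort(panel_n, {}, seed=seed, genome=genome)
    pipe = ScreeningPipeline(genome).fit([(b, p) for b, p, _ in panel], seed=seed)
    return genome, pipe


# -- transcribed-count fixtures ---------------------------------------------

def fixture_rates() -> dict[str, dict]:
    """Rates recomputed from the packaged screening-vs-CMA count fixtures."""
    from .concordance import fixture_metrics

    def rows(name):
        raw = read_fixture(fixture_path(name))
        return {r.label: r for r in fixture_metrics(raw)}

    t2 = rows("aneuploidy_sensitivity.tsv")
    t3 = rows("aneuploidy_ppv.tsv")
    t4 = rows("cnv_size_sensitivity.tsv")
    t5 = rows("syndrome_sensitivity.tsv")
    cc = rows("cohort_counts.tsv")

    def sens(row):
        return {"value": round(row.sensitivity, 4),
                "n": row.n_diagnostic_positive}

    def ppv(row):
        return {"value": round(row.ppv, 4), "n": row.n_screen_positive}

    out = {
        "cohort_cma_positive_rate_pct": sens(cc["cma_positive_rate"]),
        "aneuploidy_overall_sensitivity_pct": sens(t2["aneuploidy_total"]),
        "t21_sensitivity_pct": sens(t2["T21"]),
        "x_monosomy_sensitivity_pct": sens(t2["45,X"]),
        "rat_sensitivity_pct": sens(t2["RAT"]),
        "t21_ppv_pct": ppv(t3["T21"]),
        "t18_ppv_pct": ppv(t3["T18"]),
        "t13_ppv_pct": ppv(t3["T13"]),
        "sca_ppv_pct": ppv(t3["SCA"]),
        "rat_ppv_pct": ppv(t3["RAT"]),
        "cnv_total_sensitivity_pct": sens(t4["total"]),
        "cnv_sens_500kb_to_1mb_pct": sens(t4["500 kb to <=1 Mb"]),
        "cnv_sens_1_to_2mb_pct": sens(t4["1 to <=2 Mb"]),
        "cnv_sens_2_to_3mb_pct": sens(t4["2 to <=3 Mb"]),
        "cnv_sens_3_to_5mb_pct": sens(t4["3 to <=5 Mb"]),
        "cnv_sens_5_to_10mb_pct": sens(t4["5 to <10 Mb"]),
        "cnv_sens_ge_10mb_pct": sens(t4[">=10 Mb"]),
        "digeorge_sensitivity_pct": sens(t5["DiGeorge (22q11.2)"]),
        "rcad_sensitivity_pct": sens(t5["RCAD (17q12)"]),
    }
    return out


# -- simulation studies ------------------------------------------------------

def null_calibration(pipe: ScreeningPipeline, genome: SyntheticGenome,
                     n_samples: int = 5000, seed: int = 77,
                     threshold: float = 3.0) -> dict:
    """Per-autosome false-positive rate of the |Z| >= threshold rule."""
    samples = simulate_cohort(n_samples, {}, seed=seed, genome=genome)
    hits = 0
    total = 0
    per: dict[str, int] = {c: 0 for c in AUTOSOMES}
    for fine, _, _ in samples:
        z = pipe.autosomal_z(fine)
        for c, v in z.items():
            total += 1
            if abs(v) >= threshold:
                hits += 1
                per[c] += 1
    return {
        "rate": hits / total,
        "n": total,
        "per_chromosome_max": max(per.values()) / n_samples,
    }


def ff_recovery(pipe: ScreeningPipeline, genome: SyntheticGenome,
                n_y: int = 100, n_train: int = 100, n_test: int = 50,
                seed: int = 177) -> dict:
    """Parameter recovery of both fetal-fraction estimators."""
    rng = np.random.default_rng(seed)

    errs = []
    for _ in range(n_y):
        ff = float(rng.uniform(0.05, 0.30))
        spec = SimSampleSpec(sample_id="y", fetal_fraction=ff,
                             fetal_sex="male", seed=int(rng.integers(2**31)))
        fine, _, _ = simulate_sample(spec, genome)
        est = estimate_ff_y(pipe._normalize(fine), pipe.background_y,
                            pipe.male_reference_y)
        errs.append(abs(est - ff))
    ffy_mae = float(np.mean(errs))

    def draw(n):
        out = []
        for _ in range(n):
            ff = float(rng.uniform(0.04, 0.30))
            spec = SimSampleSpec(sample_id="f", fetal_fraction=ff,
                                 seed=int(rng.integers(2**31)))
            _, prof, _ = simulate_sample(spec, genome)
            out.append((prof, ff))
        return out

    model = train_seqff(draw(n_train))
    test = draw(n_test)
    seqff_mae = float(np.mean(
        [abs(estimate_ff_seqff(model, p) - ff) for p, ff in test]))
    return {"chry_mae": ffy_mae, "n_y": n_y,
            "seqff_mae": seqff_mae, "n_test": n_test}


def segmentation_oracle(n_instances: int = 100, seed: int = 2024) -> dict:
    """Agreement of recursive segmentation with the exact DP partition.

    Instances: up to 200 windows, up to 3 changepoints, jumps of 0.2–0.5
    against noise SD 0.01 (20–50 sigma), so split retention is certain and
    the check isolates breakpoint placement.  Retention runs at 5 sigma to
    keep noise splits out of the comparison.
    """
    rng = np.random.default_rng(seed)
    cfg = SegmentationConfig(min_bins=8, split_z=5.0)
    agree = 0
    for _ in range(n_instances):
        b = int(rng.integers(0, 4))
        n = int(rng.integers(max(40, 14 * (b + 1)), 201))
        lengths = 12 + rng.multinomial(n - 12 * (b + 1),
                                       np.full(b + 1, 1 / (b + 1)))
        breaks = np.cumsum(lengths)[:-1]
        levels = [1.0]
        for _ in range(b):
            levels.append(levels[-1] + rng.uniform(0.2, 0.5) * rng.choice([-1, 1]))
        x = np.empty(n)
        edges = np.concatenate([[0], breaks, [n]]).astype(int)
        for (lo, hi), lev in zip(zip(edges[:-1], edges[1:]), levels):
            x[lo:hi] = lev
        x += rng.normal(0, 0.01, n)
        segs = segment(x, cfg)
        got = sorted(s.start_bin for s in segs[1:])
        agree += got == optimal_partition(x, len(segs))
    return {"agreement": agree / n_instances, "n": n_instances}


def _cnv_detected(pipe, genome, rng, size_mb, ff, maternal=False, cn=1):
    size = max(genome.bin_size,
               int(size_mb * 1e6) // genome.bin_size * genome.bin_size)
    chrom = "chr1"
    start = int(rng.integers(
        0, (genome.lengths[chrom] - size) // genome.bin_size)) * genome.bin_size
    ev = GenomicEvent(chrom, cn, start, start + size)
    kw = ({"maternal_events": [ev]} if maternal
          else {"fetal_events": [ev], "placental_events": [ev]})
    spec = SimSampleSpec(sample_id="c", fetal_fraction=ff,
                         seed=int(rng.integers(2**31)), **kw)
    fine, prof, _ = simulate_sample(spec, genome)
    cs = pipe.screen(fine, prof)
    want = "del" if cn < 2 else "dup"
    return any(
        c.chromosome == chrom and c.state == want
        and min(c.end_bp, start + size) - max(c.start_bp, start) > 0
        for c in cs.cnv_calls
    )


def size_sensitivity(pipe: ScreeningPipeline, genome: SyntheticGenome,
                     sizes_mb=(0.75, 1.5, 2.5, 4.0, 7.5), ff: float = 0.10,
                     n_per_size: int = 60, seed: int = 505) -> dict:
    """Fetal CNV sensitivity by size, and maternal detection across ff."""
    rng = np.random.default_rng(seed)
    curve = {}
    for s in sizes_mb:
        det = sum(_cnv_detected(pipe, genome, rng, s, ff)
                  for _ in range(n_per_size))
        curve[s] = det / n_per_size
    maternal = {}
    for ffm in (0.05, 0.15, 0.25):
        det = sum(
            _cnv_detected(pipe, genome, rng, 1.5, ffm, maternal=True,
                          cn=rng.choice([1, 3]))
            for _ in range(30))
        maternal[ffm] = det / 30
    return {"curve": curve, "maternal": maternal, "n_per_size": n_per_size}


def mechanism_rates(pipe: ScreeningPipeline, genome: SyntheticGenome,
                    n: int = 30, seed: int = 606) -> dict:
    """False-positive / false-negative mechanisms from mosaicism.

    Confined placental mosaicism (placental trisomy, normal fetus) should
    surface as screening-positive / diagnostic-negative discordance;
    low-fraction fetal mosaicism as the converse.  Both emerge from the
    simulator plus caller without special-casing, classified through the
    standard matching machinery.
    """
    rng = np.random.default_rng(seed)

    def pair_counts(spec):
        fine, prof, truth = simulate_sample(spec, genome)
        cs = pipe.screen(fine, prof, sample_id=truth.sample_id)
        diag = truth_to_diagnostic(truth, genome)
        return match_calls(cs, diag, genome=genome.info).counts

    cpm_fp = 0
    for _ in range(n):
        chrom = "chr" + str(rng.choice([21, 16, 20, 22]))
        spec = SimSampleSpec(
            sample_id="cpm", fetal_fraction=float(rng.uniform(0.10, 0.30)),
            placental_events=[GenomicEvent(chrom, 3)],
            seed=int(rng.integers(2**31)))
        counts = pair_counts(spec)
        fp = sum(c["FP"] for c in counts.values())
        fn = sum(c["FN"] for c in counts.values())
        cpm_fp += fp > 0 and fn == 0
    mosaic_fn = 0
    for _ in range(n):
        pi = float(rng.uniform(0.10, 0.20))
        ev = GenomicEvent("chr21", 3)
        spec = SimSampleSpec(
            sample_id="mos", fetal_fraction=float(rng.uniform(0.10, 0.25)),
            fetal_events=[ev], placental_events=[ev],
            fetal_mosaic_fraction=pi, placental_mosaic_fraction=pi,
            seed=int(rng.integers(2**31)))
        counts = pair_counts(spec)
        mosaic_fn += counts["T21"]["FN"] > 0
    return {"cpm_fp_rate": cpm_fp / n, "mosaic_fn_rate": mosaic_fn / n, "n": n}
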