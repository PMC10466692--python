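"""Normalization front-end: relative reads, GC fit/correction, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfscreen.windows import (
    BinTable,
    GcFit,
    aggregate_windows,
    correct_gc,
    fit_gc,
    make_windows,
    relative_reads,
)


def _table(gc, counts, chrom="chr1"):
    n = len(counts)
    return BinTable(
        chrom=np.array([chrom] * n, dtype=object),
        start=np.arange(n) * 1000,
        end=np.arange(1, n + 1) * 1000,
        gc=np.asarray(gc, float),
        raw_count=np.asarray(counts, float),
    )


class TestRelativeReads:
    @pytest.mark.parametrize(
        "raw, expected",
        [([10, 20, 30], [0.5, 1.0, 1.5]), ([7, 7, 7, 7], [1, 1, 1, 1])],
    )
    def test_known_values(self, raw, expected):
        np.testing.assert_allclose(relative_reads(raw), expected)

    def test_matches_bruteforce_and_mean_one(self, rng):
        raw = rng.gamma(5, 20, size=500)
        r = relative_reads(raw)
        np.testing.assert_allclose(r, raw / raw.mean(), atol=1e-12)
        assert abs(r.mean() - 1.0) < 1e-9

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_reads(np.zeros(10))


class TestFitGc:
    def test_flat_signal(self, rng):
        gc = rng.uniform(0.3, 0.6, 100)
        fit = fit_gc(gc, np.ones(100))
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_recovery(self, rng):
        gc = rng.uniform(0.3, 0.6, 200)
        r = 0.5 + 1.2 * gc
        fit = fit_gc(gc, r)
        assert fit.intercept == pytest.approx(0.5, abs=1e-9)
        assert fit.slope == pytest.approx(1.2, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        gc = rng.uniform(0.3, 0.6, 300)
        r = 0.8 + 0.9 * gc + rng.normal(0, 0.05, 300)
        fit = fit_gc(gc, r)
        X = np.column_stack([np.ones_like(gc), gc])
        beta = np.linalg.solve(X.T @ X, X.T @ r)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
        assert fit.slope == pytest.approx(beta[1], abs=1e-9)

    def test_constant_gc_degenerate(self):
        fit = fit_gc(np.full(10, 0.4), np.linspace(0.9, 1.1, 10))
        assert fit.degenerate and fit.slope == 0.0

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            fit_gc(np.array([0.3, 0.4]), np.array([1.0, 1.0]))


class TestCorrectGc:
    def test_slope_zero_identity(self, rng):
        t = _table(rng.uniform(0.3, 0.6, 50), rng.poisson(100, 50) + 1)
        out = correct_gc(t, GcFit(intercept=1.0, slope=0.0, residual_sd=0.0))
        np.testing.assert_allclose(out.corrected_ratio, out.relative_reads,
                                   atol=1e-12)

    def test_linear_bias_removed(self, rng):
        gc = rng.uniform(0.3, 0.6, 400)
        bias = 0.6 + 1.0 * gc
        counts = 200 * bias * rng.gamma(200, 1 / 200, 400)
        t = _table(gc, counts)
        out = correct_gc(t)
        fit_before = fit_gc(gc, out.relative_reads)
        fit_after = fit_gc(gc, out.corrected_ratio)
        assert abs(fit_after.slope) < 0.1 * abs(fit_before.slope)
        assert out.corrected_ratio.var() < out.relative_reads.var()
        assert abs(out.corrected_ratio.mean() - 1.0) < 1e-9

    def test_exact_linear_bias_idempotent(self, rng):
        gc = rng.uniform(0.3, 0.6, 200)
        t = _table(gc, 1000 * (0.5 + 1.5 * gc))
        once = correct_gc(t)
        np.testing.assert_allclose(once.corrected_ratio, 1.0, atol=1e-9)
        twice = correct_gc(once)
        assert np.max(np.abs(
            twice.corrected_ratio - once.corrected_ratio)) < 1e-9

    def test_quadratic_misspecification_leaves_curvature(self, rng):
        gc = rng.uniform(0.3, 0.6, 500)
        t = _table(gc, 1000 * (0.2 + 4.0 * (gc - 0.45) ** 2 + 0.5))
        out = correct_gc(t)
        # linear correction cannot remove a quadratic effect: the residual
        # correlates with centred-gc squared
        resid = out.corrected_ratio - 1.0
        q = (gc - gc.mean()) ** 2
        corr = np.corrcoef(resid, q)[0, 1]
        assert abs(corr) > 0.5

    def test_nonpositive_fit_clamped_and_flagged(self):
        t = _table([0.3, 0.4, 0.5, 0.9], [10, 10, 10, 10])
        out = correct_gc(t, GcFit(intercept=1.6, slope=-2.0, residual_sd=0.0))
        assert out.flagged[-1] and not out.flagged[0]
        assert np.all(out.corrected_ratio > 0)


class TestMakeWindows:
    def test_uniform_symmetry(self):
        chrom = np.array(["chr1"] * 16, dtype=object)
        b = make_windows(chrom, np.full(16, 10.0), 4)
        np.testing.assert_array_equal(b.edges["chr1"], [0, 4, 8, 12, 16])

    def test_denser_left_half_gives_narrower_windows(self):
        counts = np.concatenate([np.full(40, 20.0), np.full(40, 10.0)])
        chrom = np.array(["chr1"] * 80, dtype=object)
        b = make_windows(chrom, counts, 6)
        widths = np.diff(b.edges["chr1"])
        # expected reads doubled on the left: left windows about half as wide
        assert widths[0] < widths[-1]
        # quantile-construction oracle: each window mass within one fine-bin
        # quantum of the ideal equal share
        cum = np.concatenate([[0], np.cumsum(counts)])
        masses = np.diff(cum[b.edges["chr1"]])
        assert masses.max() - masses.min() <= 2 * counts.max()

    def test_one_window_per_chromosome(self):
        chrom = np.array(["chr1"] * 10 + ["chr2"] * 10, dtype=object)
        b = make_windows(chrom, np.ones(20), 2)
        assert len(b.edges["chr1"]) == 2 and len(b.edges["chr2"]) == 2

    def test_equal_mass_property(self, rng):
        counts = rng.gamma(20, 5, size=600) + 1
        chrom = np.array(["chr1"] * 600, dtype=object)
        k = 30
        b = make_windows(chrom, counts, k)
        masses = np.diff(np.concatenate([[0], np.cumsum(counts)])[b.edges["chr1"]])
        quantum = counts.max()
        assert masses.max() / masses.min() <= 1 + 2 * quantum / masses.mean()

    def test_rejects_bad_window_counts(self):
        chrom = np.array(["chr1"] * 4 + ["chr2"] * 4, dtype=object)
        with pytest.raises(ValueError):
            make_windows(chrom, np.ones(8), 9)   # more windows than bins
        with pytest.raises(ValueError):
            make_windows(chrom, np.ones(8), 1)   # fewer than chromosomes
        with pytest.raises(ValueError):
            make_windows(chrom, np.zeros(8), 4)  # no read mass


class TestAggregate:
    def test_counts_and_gc(self):
        chrom = np.array(["chr1"] * 6, dtype=object)
        start = np.arange(6) * 100
        end = start + 100
        gc = np.array([0.3, 0.5, 0.4, 0.6, 0.2, 0.4])
        counts = np.array([1.0, 2, 3, 4, 5, 6])
        b = make_windows(chrom, np.ones(6), 3)
        t = aggregate_windows(chrom, start, end, gc, counts, b)
        np.testing.assert_allclose(t.raw_count, [3, 7, 11])
        np.testing.assert_allclose(t.gc, [0.4, 0.5, 0.3])
        assert t.start[0] == 0 and t.end[-1] == 600


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 10_000), min_size=3, max_size=60))
def test_relative_reads_mean_is_one(raw):
    assert abs(relative_reads(np.array(raw, float)).mean() - 1.0) < 1e-9
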