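"""Synthetic cohort generator: mixture math, compartments, reproducibility."""

import numpy as np
import pytest

import cfscreen as cf
from cfscreen.concordance import parse_iscn
from cfscreen.simulate import expected_profile, truth_to_diagnostic
from cfscreen.windows import correct_gc, relative_reads


def _spec(**kw):
    base = dict(sample_id="s", fetal_fraction=0.2, seed=0)
    base.update(kw)
    return cf.SimSampleSpec(**base)


class TestExpectedProfile:
    def test_expected_mass_conserves_depth(self, genome):
        spec = _spec(fetal_events=[cf.GenomicEvent("chr21", 3)],
                     placental_events=[cf.GenomicEvent("chr21", 3)])
        expected, _, _ = expected_profile(spec, genome)
        assert abs(expected.sum() - spec.depth) / spec.depth < 1e-3

    def test_no_events_identity_ratio(self, genome):
        _, ratio, _ = expected_profile(_spec(fetal_fraction=0.0), genome)
        off_y = ~genome.chrom_mask("chrY")
        np.testing.assert_allclose(ratio[off_y], 1.0, atol=1e-12)

    def test_maternal_duplication_mixture_value(self, genome):
        # maternal het dup (m=3) not inherited, ff=0.10:
        # (1-0.10)*1.5 + 0.10*1.0 = 1.45 exactly
        ev = cf.GenomicEvent("chr2", 3, 1_000_000, 3_000_000)
        spec = _spec(fetal_fraction=0.10, maternal_events=[ev])
        _, ratio, _ = expected_profile(spec, genome)
        region = genome.bins_in("chr2", 1_000_000, 3_000_000)
        np.testing.assert_allclose(ratio[region], 1.45, atol=1e-12)

    def test_placental_mosaic_scaling(self, genome):
        ev = cf.GenomicEvent("chr21", 3)
        spec = _spec(fetal_fraction=0.2, placental_events=[ev],
                     placental_mosaic_fraction=0.5)
        _, ratio, _ = expected_profile(spec, genome)
        m = genome.chrom_mask("chr21")
        np.testing.assert_allclose(ratio[m], 1 + 0.2 * 0.5 / 2, atol=1e-12)

    def test_fetal_only_event_leaves_plasma_flat(self, genome):
        spec = _spec(fetal_events=[cf.GenomicEvent("chr21", 3)])
        _, ratio, _ = expected_profile(spec, genome)
        np.testing.assert_allclose(ratio[genome.chrom_mask("chr21")], 1.0,
                                   atol=1e-12)

    def test_event_outside_genome_rejected(self, genome):
        ev = cf.GenomicEvent("chr21", 3, 0, genome.lengths["chr21"] + 50_000)
        with pytest.raises(ValueError):
            expected_profile(_spec(fetal_events=[ev], placental_events=[ev]),
                             genome)

    def test_ff_zero_with_events_warns(self, genome):
        ev = cf.GenomicEvent("chr21", 3)
        with pytest.warns(UserWarning, match="undetectable"):
            expected_profile(
                _spec(fetal_fraction=0.0, placental_events=[ev]), genome)


class TestSimulateSample:
    def test_seed_reproducibility(self, genome):
        a = cf.simulate_sample(_spec(seed=9), genome)
        b = cf.simulate_sample(_spec(seed=9), genome)
        np.testing.assert_array_equal(a[0].raw_count, b[0].raw_count)
        np.testing.assert_array_equal(a[1].n_short, b[1].n_short)

    def test_trisomy_ratio_recovered_monte_carlo(self, genome):
        """Mean corrected chr21 ratio approaches 1 + ff/2 = 1.10 (200 reps)."""
        ev = cf.GenomicEvent("chr21", 3)
        auto = ~(genome.chrom_mask("chrX") | genome.chrom_mask("chrY"))
        m21 = genome.chrom_mask("chr21")
        means = []
        for seed in range(200):
            spec = _spec(fetal_fraction=0.20, fetal_events=[ev],
                         placental_events=[ev], seed=seed)
            bins, _, _ = cf.simulate_sample(spec, genome)
            bins.relative_reads = relative_reads(bins.raw_count)
            out = correct_gc(bins, norm_mask=auto)
            means.append(out.corrected_ratio[m21].mean())
        assert np.mean(means) == pytest.approx(1.10, abs=0.005)

    def test_fragment_profile_short_enrichment(self, genome):
        low = cf.simulate_sample(_spec(fetal_fraction=0.05, seed=3), genome)[1]
        high = cf.simulate_sample(_spec(fetal_fraction=0.40, seed=3), genome)[1]
        assert (high.n_short.sum() / high.n_total.sum()
                > low.n_short.sum() / low.n_total.sum())

    def test_profile_on_50kb_grid(self, genome):
        profile = cf.simulate_sample(_spec(seed=1), genome)[1]
        widths = profile.end - profile.start
        assert np.median(widths) == 50_000


class TestSimulateCohort:
    def test_determinism(self, genome):
        a = cf.simulate_cohort(20, {}, seed=5, genome=genome)
        b = cf.simulate_cohort(20, {}, seed=5, genome=genome)
        for (ba, _, ta), (bb, _, tb) in zip(a, b):
            np.testing.assert_array_equal(ba.raw_count, bb.raw_count)
            assert ta.fetal_fraction == tb.fetal_fraction

    def test_scenario_prevalence_binomial(self, genome):
        cohort = cf.simulate_cohort(200, {"t21": 0.5}, seed=11, genome=genome)
        n_t21 = sum(
            any(e.chromosome == "chr21" and e.copy_number == 3
                for e in t.fetal_events) for _, _, t in cohort)
        # Binomial(200, 0.5): 99.9% interval roughly [67, 133]
        assert 67 <= n_t21 <= 133

    def test_cpm_scenario_separates_compartments(self, genome):
        cohort = cf.simulate_cohort(10, {"cpm_trisomy": 1.0}, seed=2,
                                    genome=genome)
        for _, _, truth in cohort:
            assert truth.placental_events and not truth.fetal_events
            spec = _spec(fetal_fraction=0.2,
                         placental_events=truth.placental_events)
            _, ratio, _ = expected_profile(spec, genome)
            chrom = truth.placental_events[0].chromosome
            assert ratio[genome.chrom_mask(chrom)].mean() > 1.05

    def test_invalid_inputs(self, genome):
        with pytest.raises(ValueError):
            cf.simulate_cohort(0, {}, seed=1, genome=genome)
        with pytest.raises(ValueError):
            cf.simulate_cohort(5, {"t21": -0.1}, seed=1, genome=genome)
        with pytest.raises(ValueError):
            cf.simulate_cohort(5, {"t21": 0.7, "t18": 0.5}, seed=1,
                               genome=genome)


class TestTruthToDiagnostic:
    def _truth(self, genome, events, pi=1.0):
        spec = _spec(fetal_events=events, placental_events=events,
                     fetal_mosaic_fraction=pi)
        return cf.simulate_sample(spec, genome)[2]

    def test_whole_trisomy_renders_and_roundtrips(self, genome):
        truth = self._truth(genome, [cf.GenomicEvent("chr21", 3)])
        findings = truth_to_diagnostic(truth, genome).findings
        assert len(findings) == 1
        f = findings[0]
        assert f.category == "T21" and f.copy_number == 3
        again = parse_iscn(f.format(), genome.info)
        assert again.category == "T21"
        assert again.chromosome == "chr21"

    def test_small_deletion_rendered_with_size(self, genome):
        ev = cf.GenomicEvent("chr4", 1, 2_000_000, 3_200_000)
        truth = self._truth(genome, [ev])
        (f,) = truth_to_diagnostic(truth, genome).findings
        assert f.copy_number == 1 and f.category == "CNV_DEL"
        assert (f.end - f.start) == pytest.approx(1.2e6)

    def test_mosaic_reported_as_range(self, genome):
        truth = self._truth(genome, [cf.GenomicEvent("chr21", 3)], pi=0.14)
        (f,) = truth_to_diagnostic(truth, genome).findings
        assert f.mosaic and f.copy_number_range == (2, 3)
        assert "2–3" in f.format()

    def test_low_mosaic_dropped_high_mosaic_plain(self, genome):
        ev = [cf.GenomicEvent("chr21", 3)]
        assert not truth_to_diagnostic(
            self._truth(genome, ev, pi=0.05), genome).findings
        (f,) = truth_to_diagnostic(
            self._truth(genome, ev, pi=0.95), genome).findings
        assert not f.mosaic

    def test_sub_reporting_threshold_dropped(self, genome):
        ev = cf.GenomicEvent("chr4", 1, 2_000_000, 2_050_000)
        truth = self._truth(genome, [ev])
        assert truth_to_diagnostic(truth, genome, min_size=100_000).findings == []
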