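"""End-to-end screening pipeline: fit a euploid reference, screen samples.

:class:`ScreeningPipeline` is the fitted object binding the stages:

1. equal-read windows built from the panel-mean fine-bin counts;
2. per-sample relative read numbers and least-squares GC correction;
3. a euploid reference panel of chromosomal fractions (autosomal
   statistics renormalized over autosomes so they are fetal-sex free;
   X/Y statistics from the Y-negative panel members);
4. self-calibrated chrY fetal-fraction references and a seqFF model
   trained on the male panel members with their chrY estimates as
   targets — no external truth enters the fit;
5. per-sample Z scores (finite-panel calibrated), autosomal and
   sex-chromosome aneuploidy calls, CNV segmentation with origin
   attribution, all gated by the 3.5% fetal-fraction detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import aneuploidy as an
from . import cnv as cnvmod
from .fetal_fraction import (
    DEFAULT_LOD,
    FetalFractionEstimate,
    FragmentProfile,
    SeqffModel,
    calibrate_y_reference,
    combine_ff,
    estimate_ff_seqff,
    estimate_ff_y,
    train_seqff,
)
from .genome import AUTOSOMES, SyntheticGenome
from .windows import (
    BinTable,
    aggregate_windows,
    correct_gc,
    make_windows,
    relative_reads,
)

__all__ = ["RunConfig", "ScreeningCallSet", "ScreeningPipeline"]


@dataclass
class RunConfig:
    """Global pipeline constants."""

    genome_scale: float = 1.0 / 20.0
    bin_size: int = 50_000
    #: number of equal-read windows; None keeps each fine bin as its own
    #: window (the default at reduced scale, where coarser aggregation
    #: would leave a rounding quantum comparable to the window mass)
    n_windows: int | None = None
    z_threshold: float = 3.0
    segmentation: cnvmod.SegmentationConfig = field(
        default_factory=cnvmod.SegmentationConfig
    )
    ff_lod: float = DEFAULT_LOD
    ci_method: str = "wilson_cc"
    overlap_rule: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_windows is not None and self.n_windows <= 0:
            raise ValueError("n_windows must be positive")
        if not 0 < self.ff_lod < 1:
            raise ValueError("ff_lod must be in (0, 1)")


@dataclass
class ScreeningCallSet:
    """Everything the screen reports for one sample."""

    sample_id: str
    ff: FetalFractionEstimate
    z: dict[str, float]
    autosome_calls: list[an.AneuploidyCall]
    sca_karyotype: str | None
    cnv_calls: list[cnvmod.CnvCall]
    no_call: bool = False


class ScreeningPipeline:
    """Fitted screening front-end; build with :meth:`fit`, then screen."""

    def __init__(self, genome: SyntheticGenome, config: RunConfig | None = None):
        self.genome = genome
        self.config = config or RunConfig()
        self.boundaries = None
        self.panel: an.ReferencePanel | None = None
        self.x_mean: float | None = None
        self.x_sd: float | None = None
        self.y_sd: float | None = None
        self.seqff: SeqffModel | None = None
        self.background_y, self.male_reference_y = calibrate_y_reference(genome)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        panel_samples: list[tuple[BinTable, FragmentProfile]],
        seed: int | None = None,
    ) -> "ScreeningPipeline":
        """Train windows, reference panel and fetal-fraction models."""
        if len(panel_samples) < 20:
            raise ValueError("need at least 20 euploid panel samples")
        tables = [s[0] for s in panel_samples]
        profiles = [s[1] for s in panel_samples]
        mean_counts = np.mean([t.raw_count for t in tables], axis=0)
        n_windows = self.config.n_windows or mean_counts.size
        self.boundaries = make_windows(tables[0].chrom, mean_counts, n_windows)
        corrected = [self._normalize(t) for t in tables]
        fracs = [an.chromosome_fractions(b) for b in corrected]
        self.panel = an.build_panel(fracs, seed=seed)

        y_fracs = np.array([f.get("chrY", 0.0) for f in fracs])
        female = y_fracs < self._y_female_threshold()
        if female.sum() >= 5:
            x_vals = np.array([f["chrX"] for f in fracs])[female]
            self.x_mean = float(x_vals.mean())
            self.x_sd = float(x_vals.std(ddof=1))
            self.y_sd = float(y_fracs[female].std(ddof=1))
        else:  # heavily male panel: fall back to pooled statistics
            self.x_mean = self.panel.mean["chrX"]
            self.x_sd = self.panel.sd["chrX"]
            self.y_sd = self.panel.sd["chrY"]

        calibration = []
        for b, p, is_f in zip(corrected, profiles, female):
            if is_f:
                continue
            ffy = estimate_ff_y(b, self.background_y, self.male_reference_y)
            if ffy is not None:
                calibration.append((p, ffy))
        if len(calibration) >= 10:
            self.seqff = train_seqff(calibration)
        return self

    def _y_female_threshold(self) -> float:
        span = self.male_reference_y - self.background_y
        return self.background_y + 0.02 * span

    def _normalize(self, fine: BinTable) -> BinTable:
        agg = aggregate_windows(
            fine.chrom, fine.start, fine.end, fine.gc, fine.raw_count,
            self.boundaries,
        )
        agg.relative_reads = relative_reads(agg.raw_count)
        chrom = np.asarray(agg.chrom, dtype=object)
        auto = (chrom != "chrX") & (chrom != "chrY")
        return correct_gc(agg, norm_mask=auto)

    def _require_fit(self) -> None:
        if self.panel is None:
            raise RuntimeError("pipeline is not fitted; call fit() first")

    # -- screening ---------------------------------------------------------

    def autosomal_z(self, fine: BinTable) -> dict[str, float]:
        """Calibrated autosomal z-scores only (no CNV masking, no calls).

        The statistic the |z| >= 3 positivity rule thresholds; useful for
        null-calibration studies where the CNV stage is irrelevant.
        """
        self._require_fit()
        bins = self._normalize(fine)
        fracs = an.chromosome_fractions(bins)
        auto_total = sum(fracs[c] for c in AUTOSOMES if c in fracs)
        out = {}
        for c in AUTOSOMES:
            if c not in fracs:
                continue
            x = fracs[c] / auto_total
            raw = (x - self.panel.auto_mean[c]) / self.panel.auto_sd[c]
            out[c] = self.panel.calibrate_z(raw)
        return out

    def estimate_ff(self, bins: BinTable, profile: FragmentProfile
                    ) -> tuple[FetalFractionEstimate, bool]:
        """Combined fetal-fraction estimate plus chrY-presence evidence."""
        self._require_fit()
        fracs = an.chromosome_fractions(bins)
        y_excess = fracs.get("chrY", 0.0) - self.background_y
        y_present = y_excess > 4.0 * self.y_sd
        ffy = estimate_ff_y(
            bins, self.background_y, self.male_reference_y,
            noise_margin=4.0 * self.y_sd,
        )
        ffs = (
            estimate_ff_seqff(self.seqff, profile)
            if self.seqff is not None else None
        )
        est = combine_ff(ffy, ffs, male_evidence=y_present, lod=self.config.ff_lod)
        return est, y_present

    def screen(
        self, fine: BinTable, profile: FragmentProfile, sample_id: str = ""
    ) -> ScreeningCallSet:
        """Run the full screen on one sample's fine-bin counts."""
        self._require_fit()
        bins = self._normalize(fine)
        est, y_present = self.estimate_ff(bins, profile)

        if est.qc_fail or est.below_lod or est.ff_combined is None:
            return ScreeningCallSet(
                sample_id=sample_id, ff=est, z={}, autosome_calls=[],
                sca_karyotype=None, cnv_calls=[], no_call=True,
            )
        ff = est.ff_combined
        # sex-chromosome arithmetic uses the fragment-length (seqFF) route
        # when available: it is karyotype-neutral, whereas the chrY route
        # doubles under 47,XYY
        ff_sex = est.ff_seqff if est.ff_seqff is not None else ff

        # CNVs first: called regions are masked out of the chromosome
        # fractions so a large (typically maternal) CNV cannot masquerade
        # as a whole-chromosome aneuploidy
        cnv_calls: list[cnvmod.CnvCall] = []
        masked = bins.corrected_ratio.copy()
        for chrom in AUTOSOMES:
            m = bins.chrom_mask(chrom)
            ratios = bins.corrected_ratio[m]
            segs = cnvmod.segment(
                ratios, self.config.segmentation, chromosome=chrom,
                start_bp=bins.start[m], end_bp=bins.end[m],
            )
            sigma = cnvmod.robust_noise_sd(ratios)
            chrom_calls = cnvmod.call_cnvs(
                segs, ff, self.config.segmentation, sigma=sigma
            )
            cnv_calls.extend(chrom_calls)
            if chrom_calls:
                idx = np.flatnonzero(m)
                inside = np.zeros(idx.size, dtype=bool)
                for c in chrom_calls:
                    inside |= (bins.start[m] >= c.start_bp) & (bins.end[m] <= c.end_bp)
                if inside.any() and not inside.all():
                    # impute the diploid baseline: median imputation would
                    # amplify the remaining windows' noise into the
                    # chromosome fraction
                    masked[idx[inside]] = 1.0

        masked_bins = replace(bins, corrected_ratio=masked)
        fracs = an.chromosome_fractions(masked_bins)

        # autosomal z on autosome-renormalized fractions (fetal-sex free)
        auto_total = sum(fracs[c] for c in AUTOSOMES if c in fracs)
        z: dict[str, float] = {}
        for c in AUTOSOMES:
            if c not in fracs:
                continue
            x = fracs[c] / auto_total
            raw = (x - self.panel.auto_mean[c]) / self.panel.auto_sd[c]
            z[c] = self.panel.calibrate_z(raw)

        # chrX z referenced to the fetal-sex-expected mass
        x_expected = self.x_mean * (1.0 - ff_sex / 2.0) if y_present else self.x_mean
        zx = self.panel.calibrate_z((fracs["chrX"] - x_expected) / self.x_sd)
        zy = (fracs.get("chrY", 0.0) - self.background_y) / self.y_sd
        z["chrX"], z["chrY"] = zx, zy

        autosome_calls = an.call_autosomes(z, threshold=self.config.z_threshold)
        for c in autosome_calls:
            c.ff_used = ff
        sca = an.call_sex_chromosomes(
            zx, zy, fracs.get("chrY", 0.0), ff_sex,
            background_y=self.background_y,
            male_reference_y=self.male_reference_y,
            y_sd=self.y_sd,
            threshold=self.config.z_threshold,
        )

        return ScreeningCallSet(
            sample_id=sample_id, ff=est, z=z, autosome_calls=autosome_calls,
            sca_karyotype=sca, cnv_calls=cnv_calls,
        )

    def screen_cohort(
        self, samples: list[tuple[BinTable, FragmentProfile]],
        sample_ids: list[str] | None = None,
    ) -> list[ScreeningCallSet]:
        ids = sample_ids or [f"S{i:04d}" for i in range(len(samples))]
        return [
            self.screen(b, p, sample_id=i)
            for (b, p), i in zip(samples, ids)
        ]
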