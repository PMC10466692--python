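"""Synthetic maternal-plasma cfDNA cohort generator.

A plasma sample is a mixture of three genomes: the mother's, the placental
(trophoblast) genome that actually sheds the "fetal" cfDNA, and the fetal
genome proper that the diagnostic test (CMA on amniocytes) sees.  The
expected read count of fine bin *i* is

    E[c_i] ∝ depth · (a + b·GC_i) · q_i,
    q_i = (1 − ff)·m_i/2 + ff·[(1 − π)·b_i + π·k_i]/2,

with ff the fetal fraction, m_i the maternal copy number, b_i/k_i the
baseline and event placental copy numbers and π the placental mosaic
fraction.  Counts are drawn Poisson or negative-binomial.  Diagnostic truth
records the *fetal* genotype, so confined placental mosaicism (placental
event, normal fetus) produces screening-positive / diagnostic-negative
discordance by construction, and fetal mosaicism at low fraction produces
the converse.

Fragment lengths are a two-component Gaussian mixture (maternal ~N(166,18),
fetal ~N(143,18), truncated to [50, 250] bp); only the per-bin count of
short 100–150 bp fragments is materialized, which is what the seqFF-style
estimator consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .fetal_fraction import FragmentProfile
from .genome import AUTOSOMES, SyntheticGenome
from .windows import BinTable

__all__ = [
    "GenomicEvent",
    "SimSampleSpec",
    "SimTruth",
    "FragmentLengthModel",
    "simulate_sample",
    "simulate_cohort",
    "truth_to_diagnostic",
    "sample_fetal_fraction",
    "SCENARIOS",
]

_GC_EFFECT_FLOOR = 0.05


@dataclass(frozen=True)
class GenomicEvent:
    """A copy-number event on one chromosome.

    ``start``/``end`` are 0-based half-open bp coordinates; both ``None``
    marks a whole-chromosome event.  ``copy_number`` is the event copy
    number (2 is diploid-normal and therefore not an event).
    """

    chromosome: str
    copy_number: int
    start: int | None = None
    end: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.copy_number == 2 and self.chromosome not in ("chrX", "chrY"):
            raise ValueError("copy_number 2 on an autosome is not an event")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if (self.start is None) != (self.end is None):
            raise ValueError("interval events need both start and end")
        if self.start is not None and not self.start < self.end:
            raise ValueError("start must be < end")

    @property
    def whole_chromosome(self) -> bool:
        return self.start is None

    def size_bp(self, chrom_length: int) -> int:
        if self.whole_chromosome:
            return chrom_length
        return self.end - self.start


@dataclass
class SimSampleSpec:
    """Everything needed to simulate one plasma sample."""

    sample_id: str
    fetal_fraction: float
    fetal_sex: str = "female"
    fetal_events: list[GenomicEvent] = field(default_factory=list)
    placental_events: list[GenomicEvent] = field(default_factory=list)
    maternal_events: list[GenomicEvent] = field(default_factory=list)
    placental_mosaic_fraction: float = 1.0
    fetal_mosaic_fraction: float = 1.0
    depth: float = 425_000.0
    gc_bias_coefficients: tuple[float, float] = (0.58, 1.0)
    noise_model: str = "negative_binomial"
    dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError("fetal_fraction must be in [0, 1]")
        for name in ("placental_mosaic_fraction", "fetal_mosaic_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.depth > 0:
            raise ValueError("depth must be positive")
        if self.fetal_sex not in ("male", "female"):
            raise ValueError("fetal_sex must be 'male' or 'female'")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError("noise_model must be poisson or negative_binomial")


@dataclass
class SimTruth:
    """Diagnostic ground truth: the fetal genotype plus provenance."""

    sample_id: str
    fetal_sex: str
    fetal_fraction: float
    fetal_events: list[GenomicEvent]
    fetal_mosaic_fraction: float
    placental_events: list[GenomicEvent]
    placental_mosaic_fraction: float
    maternal_events: list[GenomicEvent]
    seed: int

    def to_dict(self) -> dict:
        def ev(e: GenomicEvent) -> dict:
            return {
                "chromosome": e.chromosome, "copy_number": e.copy_number,
                "start": e.start, "end": e.end, "label": e.label,
            }

        return {
            "sample_id": self.sample_id,
            "fetal_sex": self.fetal_sex,
            "fetal_fraction": self.fetal_fraction,
            "fetal_events": [ev(e) for e in self.fetal_events],
            "fetal_mosaic_fraction": self.fetal_mosaic_fraction,
            "placental_events": [ev(e) for e in self.placental_events],
            "placental_mosaic_fraction": self.placental_mosaic_fraction,
            "maternal_events": [ev(e) for e in self.maternal_events],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        def ev(x: dict) -> GenomicEvent:
            return GenomicEvent(
                chromosome=x["chromosome"], copy_number=x["copy_number"],
                start=x["start"], end=x["end"], label=x.get("label", ""),
            )

        return cls(
            sample_id=d["sample_id"], fetal_sex=d["fetal_sex"],
            fetal_fraction=d["fetal_fraction"],
            fetal_events=[ev(e) for e in d["fetal_events"]],
            fetal_mosaic_fraction=d["fetal_mosaic_fraction"],
            placental_events=[ev(e) for e in d["placental_events"]],
            placental_mosaic_fraction=d["placental_mosaic_fraction"],
            maternal_events=[ev(e) for e in d["maternal_events"]],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class FragmentLengthModel:
    """Two-component truncated-Gaussian fragment-length mixture.

    Only the probability that a fragment falls in the short 100–150 bp
    window matters downstream, so the model reduces to two constants.
    """

    maternal_mean: float = 166.0
    fetal_mean: float = 143.0
    sd: float = 18.0
    lo: float = 50.0
    hi: float = 250.0
    short_lo: float = 100.0
    short_hi: float = 150.0

    def p_short(self, mean: float) -> float:
        a, b = (self.lo - mean) / self.sd, (self.hi - mean) / self.sd
        return float(
            truncnorm.cdf((self.short_hi - mean) / self.sd, a, b)
            - truncnorm.cdf((self.short_lo - mean) / self.sd, a, b)
        )

    @property
    def p_short_maternal(self) -> float:
        return self.p_short(self.maternal_mean)

    @property
    def p_short_fetal(self) -> float:
        return self.p_short(self.fetal_mean)


DEFAULT_FRAGMENT_MODEL = FragmentLengthModel()


def _copy_profile(
    genome: SyntheticGenome,
    base_x: int,
    base_y: int,
    events: list[GenomicEvent],
    mosaic_fraction: float,
) -> np.ndarray:
    """Effective per-fine-bin copy number of one genomic compartment."""
    copies = np.full(genome.n_bins, 2.0)
    copies[genome.chrom_mask("chrX")] = base_x
    copies[genome.chrom_mask("chrY")] = base_y
    for e in events:
        if e.whole_chromosome:
            genome.validate_interval(e.chromosome, 0, genome.lengths[e.chromosome])
            mask = genome.chrom_mask(e.chromosome)
        else:
            genome.validate_interval(e.chromosome, e.start, e.end)
            mask = genome.bins_in(e.chromosome, e.start, e.end)
        copies[mask] = (1 - mosaic_fraction) * copies[mask] + mosaic_fraction * e.copy_number
    return copies


def expected_profile(
    spec: SimSampleSpec, genome: SyntheticGenome
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected counts, plasma copy ratio and local fetal share, noise-free.

    Returns ``(expected, plasma_ratio, fetal_share)``; ``expected`` sums to
    ``spec.depth`` exactly.
    """
    ff = spec.fetal_fraction
    if ff == 0 and (spec.fetal_events or spec.placental_events):
        warnings.warn(
            "fetal_fraction is 0: fetal/placental events are undetectable by "
            "construction", stacklevel=2,
        )
    bx, by = (1, 1) if spec.fetal_sex == "male" else (2, 0)
    maternal = _copy_profile(genome, 2, 0, spec.maternal_events, 1.0)
    placental = _copy_profile(
        genome, bx, by, spec.placental_events, spec.placental_mosaic_fraction
    )
    plasma_ratio = (1 - ff) * maternal / 2 + ff * placental / 2
    rate = plasma_ratio.copy()
    ymask = genome.chrom_mask("chrY")
    rate[ymask] += genome.y_background  # mismapped background reads
    a, b = spec.gc_bias_coefficients
    gc_effect = np.maximum(a + b * genome.gc, _GC_EFFECT_FLOOR)
    w = gc_effect * rate
    expected = spec.depth * w / w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        fetal_share = np.where(rate > 0, ff * placental / 2 / rate, 0.0)
    return expected, plasma_ratio, fetal_share


def _profile_50kb(
    genome: SyntheticGenome, n_short: np.ndarray, n_total: np.ndarray
) -> FragmentProfile:
    """Aggregate fine-bin fragment counts onto the 50 kb profile grid."""
    target = 50_000
    per = max(1, target // genome.bin_size)
    chroms, starts, ends, gcs, shorts, totals = [], [], [], [], [], []
    for c in dict.fromkeys(genome.chrom):
        m = genome.chrom_mask(c)
        idx = np.arange(0, int(m.sum()), per)
        chroms.extend([c] * idx.size)
        starts.append(genome.start[m][idx])
        last = np.minimum(idx + per - 1, m.sum() - 1)
        ends.append(genome.end[m][last])
        gcs.append(np.add.reduceat(genome.gc[m], idx) / np.diff(
            np.concatenate([idx, [m.sum()]])))
        shorts.append(np.add.reduceat(n_short[m], idx))
        totals.append(np.add.reduceat(n_total[m], idx))
    return FragmentProfile(
        chrom=np.asarray(chroms, dtype=object),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        n_short=np.concatenate(shorts),
        n_total=np.concatenate(totals),
        gc=np.concatenate(gcs),
    )


def simulate_sample(
    spec: SimSampleSpec,
    genome: SyntheticGenome,
    fragment_model: FragmentLengthModel = DEFAULT_FRAGMENT_MODEL,
) -> tuple[BinTable, FragmentProfile, SimTruth]:
    """Draw one sample: fine-bin counts, fragment profile, diagnostic truth."""
    expected, _, fetal_share = expected_profile(spec, genome)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "poisson":
        counts = rng.poisson(expected).astype(float)
    else:
        # Gamma-Poisson mixture: Var = mu + dispersion * mu^2
        d = spec.dispersion
        lam = rng.gamma(shape=1.0 / d, scale=expected * d)
        counts = rng.poisson(lam).astype(float)

    bins = BinTable(
        chrom=genome.chrom.copy(),
        start=genome.start.copy(),
        end=genome.end.copy(),
        gc=genome.gc.copy(),
        raw_count=counts,
    )

    p_f = fragment_model.p_short_fetal
    p_m = fragment_model.p_short_maternal
    p_short = np.clip(fetal_share * p_f + (1 - fetal_share) * p_m, 0.0, 1.0)
    n_short = rng.binomial(counts.astype(np.int64), p_short).astype(float)
    profile = _profile_50kb(genome, n_short, counts)

    truth = SimTruth(
        sample_id=spec.sample_id,
        fetal_sex=spec.fetal_sex,
        fetal_fraction=spec.fetal_fraction,
        fetal_events=list(spec.fetal_events),
        fetal_mosaic_fraction=spec.fetal_mosaic_fraction,
        placental_events=list(spec.placental_events),
        placental_mosaic_fraction=spec.placental_mosaic_fraction,
        maternal_events=list(spec.maternal_events),
        seed=spec.seed,
    )
    return bins, profile, truth


# ---------------------------------------------------------------------------
# Scenario library and cohort generation
# ---------------------------------------------------------------------------

def sample_fetal_fraction(rng: np.random.Generator) -> float:
    """Cohort fetal-fraction draw: Beta(2, 6.5), clipped to [4.2%, 88.3%].

    Mean ≈ 23.5% with the clinical 4.2–88.3% span.
    """
    return float(np.clip(rng.beta(2.0, 6.5), 0.042, 0.883))


def _trisomy(chrom: str) -> GenomicEvent:
    return GenomicEvent(chromosome=chrom, copy_number=3, label="trisomy")


def _interval_event(
    rng: np.random.Generator, genome: SyntheticGenome, copy_number: int,
    size_mb_range: tuple[float, float], label: str,
) -> GenomicEvent:
    lo, hi = size_mb_range
    size = int(np.exp(rng.uniform(np.log(lo * 1e6), np.log(hi * 1e6))))
    hosts = [
        c for c in AUTOSOMES
        if genome.lengths[c] > size + 4 * genome.bin_size
    ]
    if not hosts:
        raise ValueError(f"no chromosome can host a {size/1e6:.1f} Mb event")
    chrom = rng.choice(hosts)
    start = int(rng.integers(0, genome.lengths[chrom] - size))
    # snap to fine-bin grid so the event occupies whole bins
    start = (start // genome.bin_size) * genome.bin_size
    size = max(genome.bin_size, (size // genome.bin_size) * genome.bin_size)
    return GenomicEvent(chromosome=chrom, copy_number=copy_number,
                        start=start, end=start + size, label=label)


def _scenario(name: str, rng: np.random.Generator, genome: SyntheticGenome) -> dict:
    sex = "male" if rng.random() < 0.5 else "female"
    out: dict = {"fetal_sex": sex}
    if name == "euploid":
        return out
    if name in ("t21", "t18", "t13"):
        ev = _trisomy("chr" + name[1:])
        out.update(fetal_events=[ev], placental_events=[ev])
    elif name == "rat":
        chrom = "chr" + str(rng.choice([2, 7, 9, 15, 16, 20, 22]))
        ev = _trisomy(chrom)
        out.update(fetal_events=[ev], placental_events=[ev])
    elif name == "mosaic_t21":
        ev = _trisomy("chr21")
        pi = float(rng.uniform(0.10, 0.45))
        out.update(fetal_events=[ev], placental_events=[ev],
                   fetal_mosaic_fraction=pi, placental_mosaic_fraction=pi)
    elif name == "cpm_trisomy":
        chrom = "chr" + str(rng.choice([21, 16, 20, 22, 7]))
        out.update(placental_events=[_trisomy(chrom)])
    elif name == "45x":
        ev = GenomicEvent("chrX", 1, label="SCA_karyotype")
        out.update(fetal_sex="female", fetal_events=[ev], placental_events=[ev])
    elif name == "47xxx":
        ev = GenomicEvent("chrX", 3, label="SCA_karyotype")
        out.update(fetal_sex="female", fetal_events=[ev], placental_events=[ev])
    elif name == "47xxy":
        ev = GenomicEvent("chrX", 2, label="SCA_karyotype")
        out.update(fetal_sex="male", fetal_events=[ev], placental_events=[ev])
    elif name == "47xyy":
        ev = GenomicEvent("chrY", 2, label="SCA_karyotype")
        out.update(fetal_sex="male", fetal_events=[ev], placental_events=[ev])
    elif name == "47xyy_weak_y":
        # XYY with a placental mosaic so the chrY excess is attenuated; probes
        # the known screening failure mode of XYY read as 45,X.
        ev = GenomicEvent("chrY", 2, label="SCA_karyotype")
        out.update(fetal_sex="male", fetal_events=[ev], placental_events=[ev],
                   placental_mosaic_fraction=float(rng.uniform(0.2, 0.5)))
    elif name == "fetal_cnv_del":
        ev = _interval_event(rng, genome, 1, (0.5, 8.0), "del")
        out.update(fetal_events=[ev], placental_events=[ev])
    elif name == "fetal_cnv_dup":
        ev = _interval_event(rng, genome, 3, (0.5, 8.0), "dup")
        out.update(fetal_events=[ev], placental_events=[ev])
    elif name == "maternal_cnv_del":
        out.update(maternal_events=[_interval_event(rng, genome, 1, (0.5, 3.0), "del")])
    elif name == "maternal_cnv_dup":
        out.update(maternal_events=[_interval_event(rng, genome, 3, (0.5, 3.0), "dup")])
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return out


SCENARIOS: tuple[str, ...] = (
    "euploid", "t21", "t18", "t13", "rat", "mosaic_t21", "cpm_trisomy",
    "45x", "47xxx", "47xxy", "47xyy", "47xyy_weak_y",
    "fetal_cnv_del", "fetal_cnv_dup", "maternal_cnv_del", "maternal_cnv_dup",
)


def simulate_cohort(
    n: int,
    scenario_mix: dict[str, float],
    seed: int,
    genome: SyntheticGenome,
    **spec_overrides,
) -> list[tuple[BinTable, FragmentProfile, SimTruth]]:
    """Draw ``n`` samples from a scenario mix (remainder euploid)."""
    if n <= 0:
        raise ValueError("n must be positive")
    for name, p in scenario_mix.items():
        if p < 0:
            raise ValueError(f"negative prevalence for {name!r}")
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
    total = sum(scenario_mix.values())
    if total > 1 + 1e-12:
        raise ValueError("scenario prevalences must sum to <= 1")

    rng = np.random.default_rng(seed)
    names = list(scenario_mix) + ["euploid"]
    probs = np.array(list(scenario_mix.values()) + [max(0.0, 1.0 - total)])
    probs = probs / probs.sum()
    out = []
    for i in range(n):
        name = names[int(rng.choice(len(names), p=probs))]
        fields = _scenario(name, rng, genome)
        slope = float(np.clip(rng.normal(1.0, 0.15), 0.3, 1.7))
        spec = SimSampleSpec(
            sample_id=f"S{i:04d}",
            fetal_fraction=sample_fetal_fraction(rng),
            gc_bias_coefficients=(0.58, slope),
            seed=int(rng.integers(0, 2**31 - 1)),
            **{**fields, **spec_overrides},
        )
        out.append(simulate_sample(spec, genome))
    return out


def truth_to_diagnostic(truth: SimTruth, genome: SyntheticGenome, min_size: int = 100_000):
    """Render the fetal genotype as a CMA-style finding set.

    Findings below the 100 kb reporting floor are dropped.  Fetal mosaic
    fractions in [0.1, 0.9] are reported as copy-number ranges ("×2–3");
    below 0.1 the majority (normal) genotype wins and nothing is reported,
    above 0.9 the event is reported non-mosaic.
    """
    from .concordance import DiagnosticFinding, DiagnosticFindingSet, classify_finding

    pi = truth.fetal_mosaic_fraction
    findings = []
    for e in truth.fetal_events:
        if pi < 0.1:
            continue
        mosaic = 0.1 <= pi <= 0.9
        if e.chromosome in ("chrX", "chrY") and e.whole_chromosome:
            karyo = {
                ("chrX", 1): "45,X", ("chrX", 3): "47,XXX",
                ("chrX", 2): "47,XXY", ("chrY", 2): "47,XYY",
            }.get((e.chromosome, e.copy_number))
            if karyo is not None:
                f = DiagnosticFinding(
                    chromosome=e.chromosome, start=None, end=None,
                    copy_number=e.copy_number,
                    copy_number_range=None, mosaic=mosaic,
                    category="SCA", karyotype=karyo, raw=karyo,
                )
                findings.append(f)
                continue
        if e.whole_chromosome:
            start, end = genome.info.reportable_span(e.chromosome)
        else:
            start, end = e.start, e.end
        if end - start < min_size:
            continue
        cn = e.copy_number
        cn_range = (min(cn, 2), max(cn, 2)) if mosaic else None
        f = DiagnosticFinding(
            chromosome=e.chromosome, start=start, end=end, copy_number=cn,
            copy_number_range=cn_range, mosaic=mosaic,
            category="", karyotype=None, raw="",
        )
        f = classify_finding(f, genome.info)
        f = replace(f, raw=f.format())
        findings.append(f)
    return DiagnosticFindingSet(sample_id=truth.sample_id, findings=findings)
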