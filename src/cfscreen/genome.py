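"""Reference-genome metadata and the reduced synthetic genome build.

Two genome notions coexist:

* :data:`GRCH37` — chromosome lengths and array-reportable spans of the real
  human reference, used when parsing diagnostic (CMA) result strings printed
  in GRCh37 coordinates.
* :class:`SyntheticGenome` — a scaled-down build (default 1/20 of GRCh37,
  50 kb bins) on which whole samples simulate in milliseconds.  The math of
  every downstream stage is scale-free, so nothing but runtime depends on
  the reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: GRCh37 / hg19 chromosome lengths (bp).
GRCH37_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("chrX", "chrY")

# Region of each chromosome that a diagnostic SNP array actually reports.
# Acrocentric p arms (13/14/15/21/22) carry no probes; chrY coverage is the
# male-specific region.  A whole-chromosome gain/loss printed as an interval
# covers (nearly) all of this span, a sub-chromosomal CNV does not.
_QARM_START = {
    "chr13": 19020000, "chr14": 19000000, "chr15": 20000000,
    "chr21": 13200000, "chr22": 14700000,
}
REPORTABLE_SPAN: dict[str, tuple[int, int]] = {
    c: (_QARM_START.get(c, 0), GRCH37_LENGTHS[c]) for c in CHROMOSOMES
}
REPORTABLE_SPAN["chrY"] = (2650000, 28800000)


@dataclass(frozen=True)
class GenomeInfo:
    """Chromosome lengths plus reportable spans, the parsing context."""

    lengths: dict[str, int]
    reportable: dict[str, tuple[int, int]]

    def reportable_span(self, chrom: str) -> tuple[int, int]:
        return self.reportable.get(chrom, (0, self.lengths[chrom]))


GRCH37 = GenomeInfo(lengths=GRCH37_LENGTHS, reportable=REPORTABLE_SPAN)


@dataclass
class SyntheticGenome:
    """Reduced diploid genome with per-bin GC fractions.

    Parameters
    ----------
    scale
        Linear reduction factor relative to GRCh37 (default 1/20).
    bin_size
        Fine-bin width in bp (default 25 kb, giving ~6,200 bins at 1/20
        scale — the same windows-per-event geometry as the full-scale
        300,000-window design; fragment profiles are emitted on the 50 kb
        grid regardless).
    gc_seed
        Seed for the smooth per-bin GC track.
    y_background
        Expected chrY read rate in a male-fetus-free sample, as a fraction of
        the autosomal diploid rate.  Emulates female reads mismapping to chrY
        and gives the chrY fetal-fraction estimator a realistic baseline.
    """

    scale: float = 1.0 / 20.0
    bin_size: int = 25_000
    gc_seed: int = 20170
    y_background: float = 0.05

    chrom: np.ndarray = field(init=False, repr=False)
    start: np.ndarray = field(init=False, repr=False)
    end: np.ndarray = field(init=False, repr=False)
    gc: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        chroms, starts, ends = [], [], []
        self.lengths: dict[str, int] = {}
        for c in CHROMOSOMES:
            n_bins = max(4, int(round(GRCH37_LENGTHS[c] * self.scale / self.bin_size)))
            length = n_bins * self.bin_size
            self.lengths[c] = length
            edges = np.arange(n_bins + 1) * self.bin_size
            chroms.extend([c] * n_bins)
            starts.append(edges[:-1])
            ends.append(edges[1:])
        self.chrom = np.asarray(chroms, dtype=object)
        self.start = np.concatenate(starts)
        self.end = np.concatenate(ends)
        self._slices: dict[str, tuple[int, int]] = {}
        lo = 0
        for c in CHROMOSOMES:
            n_c = self.lengths[c] // self.bin_size
            self._slices[c] = (lo, lo + n_c)
            lo += n_c
        # Smooth GC track: a long-wavelength random walk clipped to a
        # realistic range, deterministic given gc_seed.
        rng = np.random.default_rng(self.gc_seed)
        n = self.chrom.size
        walk = np.cumsum(rng.normal(0.0, 0.012, size=n))
        walk -= np.linspace(walk[0], walk[-1], n)  # detrend, keep wiggles
        gc = 0.42 + 0.05 * np.sin(np.linspace(0, 40, n)) + walk
        self.gc = np.clip(gc, 0.30, 0.62)
        self.info = GenomeInfo(
            lengths=dict(self.lengths),
            reportable={c: (0, self.lengths[c]) for c in CHROMOSOMES},
        )

    @property
    def n_bins(self) -> int:
        return int(self.chrom.size)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        mask = np.zeros(self.n_bins, dtype=bool)
        lo, hi = self._slices[chrom]
        mask[lo:hi] = True
        return mask

    def bins_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of fine bins overlapping [start, end) on ``chrom``."""
        mask = np.zeros(self.n_bins, dtype=bool)
        lo, hi = self._slices[chrom]
        i0 = lo + max(0, start // self.bin_size)
        i1 = lo + min(hi - lo, -(-end // self.bin_size))
        mask[i0:i1] = True
        return mask

    def validate_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside genome "
                f"(length {self.lengths[chrom]})"
            )
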