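"""Sub-chromosomal CNV detection by least-squares changepoint segmentation.

The corrected per-window ratios of one chromosome are split recursively at
the point minimizing the residual sum of squares (a quadratic cost); a
split is retained only when the two candidate segments' means differ by
more than the *dynamic threshold*

    z_t · σ̂ · sqrt(1/L_left + 1/L_right),

where σ̂ is the robust per-window noise (scaled median absolute successive
difference) and L the segment lengths — so shorter segments must deviate
more to survive.  Segments deviating from the diploid baseline become dup
or del calls, and the magnitude of the deviation attributes the event to
the fetal (≈ ff/2 for a heterozygous event) or the maternal (≈ (1−ff)/2 or
1/2) genome.

:func:`optimal_partition` is an exhaustive dynamic-programming solver for
the same sum-of-squares objective; it serves as the exact small-instance
cross-check of the recursive heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentationConfig",
    "Segment",
    "CnvCall",
    "robust_noise_sd",
    "segment",
    "optimal_partition",
    "call_cnvs",
    "infer_origin",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Dynamic-threshold segmentation parameters."""

    z_t: float = 3.0              # call-threshold multiplier, matches the aneuploidy rule
    min_bins: int = 3             # minimum segment length and call size floor
    max_depth: int = 20           # recursion cap
    deviation_floor: float = 0.01  # minimum |mean ratio − 1| for a call
    max_chrom_fraction: float = 0.9  # larger events are aneuploidy, not CNV
    #: split-retention multiplier.  Changepoint proposal is deliberately
    #: more liberal (two-sided 1%) than calling: a retained-but-spurious
    #: segment still has to clear the Bonferroni-adjusted z_t call gate,
    #: while a missed boundary cannot be recovered later.
    split_z: float = 2.576

    def __post_init__(self) -> None:
        if self.z_t <= 0 or self.split_z <= 0:
            raise ValueError("z thresholds must be positive")
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")


@dataclass
class Segment:
    chromosome: str
    start_bin: int
    end_bin: int            # half-open
    start_bp: int
    end_bp: int
    mean_deviation: float   # mean corrected ratio − 1
    n_bins: int
    segment_z: float        # deviation over σ̂/sqrt(n_bins), signed


def robust_noise_sd(x: np.ndarray) -> float:
    """Per-window noise SD from successive differences.

    1.4826·median|Δx|/√2 — insensitive to the (piecewise-constant) signal.
    """
    x = np.asarray(x, float)
    if x.size < 2:
        return 0.0
    mad = np.median(np.abs(np.diff(x)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _best_split(cum: np.ndarray, cum2: np.ndarray, lo: int, hi: int,
                min_bins: int) -> tuple[int, float] | None:
    """Best single changepoint in [lo, hi) by residual sum of squares.

    Returns (split index k, SSE gain) with segments [lo,k) and [k,hi), or
    ``None`` when the segment is too short to split.
    """
    n = hi - lo
    if n < 2 * min_bins:
        return None
    ks = np.arange(lo + min_bins, hi - min_bins + 1)
    s_all = cum[hi] - cum[lo]
    nl = ks - lo
    nr = hi - ks
    sl = cum[ks] - cum[lo]
    sr = s_all - sl
    # SSE(seg) = Σx² − (Σx)²/n; the Σx² terms cancel in the gain
    gain = sl**2 / nl + sr**2 / nr - s_all**2 / n
    i = int(np.argmax(gain))
    return int(ks[i]), float(gain[i])


def segment(
    ratios: np.ndarray,
    cfg: SegmentationConfig = SegmentationConfig(),
    chromosome: str = "",
    start_bp: np.ndarray | None = None,
    end_bp: np.ndarray | None = None,
    sigma: float | None = None,
) -> list[Segment]:
    """Recursive binary least-squares segmentation of one chromosome."""
    x = np.asarray(ratios, float)
    n = x.size
    if n == 0:
        raise ValueError("empty ratio vector")
    if start_bp is None:
        start_bp = np.arange(n)
        end_bp = np.arange(1, n + 1)
    if sigma is None:
        sigma = robust_noise_sd(x)
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x**2)])

    breaks: list[int] = []

    def rec(lo: int, hi: int, depth: int) -> None:
        if depth > cfg.max_depth:
            return
        found = _best_split(cum, cum2, lo, hi, cfg.min_bins)
        if found is None:
            return
        k, _ = found
        mean_l = (cum[k] - cum[lo]) / (k - lo)
        mean_r = (cum[hi] - cum[k]) / (hi - k)
        if sigma > 0:
            thresh = cfg.split_z * sigma * np.sqrt(1.0 / (k - lo) + 1.0 / (hi - k))
        else:
            thresh = 0.0
        if abs(mean_l - mean_r) <= thresh:
            return
        breaks.append(k)
        rec(lo, k, depth + 1)
        rec(k, hi, depth + 1)

    rec(0, n, 0)
    edges = [0] + sorted(breaks) + [n]
    segs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mean = (cum[hi] - cum[lo]) / (hi - lo)
        dev = mean - 1.0
        z = dev / (sigma / np.sqrt(hi - lo)) if sigma > 0 else np.inf * np.sign(dev or 1)
        segs.append(Segment(
            chromosome=chromosome, start_bin=lo, end_bin=hi,
            start_bp=int(start_bp[lo]), end_bp=int(end_bp[hi - 1]),
            mean_deviation=float(dev), n_bins=hi - lo, segment_z=float(z),
        ))
    return segs


def optimal_partition(x: np.ndarray, n_segments: int) -> list[int]:
    """Exact minimal-SSE partition into ``n_segments`` pieces (DP).

    Returns the sorted interior breakpoints.  O(m·n²); intended for small
    instances as the independent oracle for :func:`segment`.
    """
    x = np.asarray(x, float)
    n = x.size
    if not 1 <= n_segments <= n:
        raise ValueError("need 1 <= n_segments <= len(x)")
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x**2)])

    # cost[k][j]: best SSE of x[:j] in k segments
    js = np.arange(1, n + 1)
    prev = np.full(n + 1, np.inf)
    prev[1:] = cum2[js] - cum[js] ** 2 / js
    back = np.zeros((n_segments + 1, n + 1), dtype=int)
    for k in range(2, n_segments + 1):
        cur = np.full(n + 1, np.inf)
        for j in range(k, n + 1):
            i = np.arange(k - 1, j)
            s = cum[j] - cum[i]
            cand = prev[i] + (cum2[j] - cum2[i]) - s * s / (j - i)
            b = int(np.argmin(cand))
            cur[j] = cand[b]
            back[k][j] = b + (k - 1)
        prev = cur
    cuts = []
    j = n
    for k in range(n_segments, 1, -1):
        j = int(back[k][j])
        cuts.append(j)
    return sorted(cuts)


@dataclass
class CnvCall:
    chromosome: str
    start_bp: int
    end_bp: int
    size_mb: float
    state: str              # dup | del
    origin: str             # fetal | maternal | indeterminate
    mean_deviation: float
    segment_z: float


def call_cnvs(
    segments: list[Segment],
    ff: float | None,
    cfg: SegmentationConfig = SegmentationConfig(),
    sigma: float | None = None,
) -> list[CnvCall]:
    """Turn deviating segments into dup/del calls with origin attribution.

    Whole-chromosome-scale segments (more than ``cfg.max_chrom_fraction``
    of the chromosome's windows) are left to the aneuploidy caller.
    """
    from scipy.stats import norm

    by_chrom: dict[str, int] = {}
    for s in segments:
        by_chrom[s.chromosome] = by_chrom.get(s.chromosome, 0) + s.n_bins
    calls = []
    for s in segments:
        if s.n_bins < cfg.min_bins:
            continue
        n_chrom = by_chrom[s.chromosome]
        if s.n_bins > cfg.max_chrom_fraction * n_chrom:
            continue
        # the segmentation selected the most deviant stretch among ~n_chrom
        # candidate boundaries; Bonferroni-adjust the call threshold so the
        # per-chromosome false-call rate stays at the nominal z_t level
        z_call = max(cfg.z_t, -norm.ppf(norm.sf(cfg.z_t) / n_chrom))
        if abs(s.segment_z) < z_call or abs(s.mean_deviation) < cfg.deviation_floor:
            continue
        call = CnvCall(
            chromosome=s.chromosome,
            start_bp=s.start_bp,
            end_bp=s.end_bp,
            size_mb=(s.end_bp - s.start_bp) / 1e6,
            state="dup" if s.mean_deviation > 0 else "del",
            origin="indeterminate",
            mean_deviation=s.mean_deviation,
            segment_z=s.segment_z,
        )
        seg_sigma = sigma if sigma is not None else abs(
            s.mean_deviation / s.segment_z
        ) * np.sqrt(s.n_bins) if s.segment_z else 0.0
        call.origin = infer_origin(call, ff, seg_sigma, s.n_bins)
        calls.append(call)
    return calls


def infer_origin(
    call: CnvCall, ff: float | None, sigma: float, n_bins: int
) -> str:
    """Attribute a CNV to the fetal or the maternal genome by its magnitude.

    A heterozygous fetal-only event shifts the ratio by ff/2; a maternal
    heterozygous event by (1−ff)/2 if not inherited or 1/2 if inherited —
    both collapse to "maternal".  Classification is to the nearest
    expectation; when the fetal and maternal expectations are closer than
    two standard errors (σ̂/√L), or the deviation sits exactly midway, the
    origin is indeterminate.
    """
    if ff is None:
        return "indeterminate"
    dev = abs(call.mean_deviation)
    fetal_exp = ff / 2.0
    maternal_exps = ((1.0 - ff) / 2.0, 0.5)
    se = sigma / np.sqrt(n_bins) if n_bins > 0 else 0.0
    if abs(fetal_exp - maternal_exps[0]) < 2.0 * se:
        return "indeterminate"
    d_fetal = abs(dev - fetal_exp)
    d_maternal = min(abs(dev - m) for m in maternal_exps)
    if np.isclose(d_fetal, d_maternal, rtol=0.0, atol=1e-12):
        return "indeterminate"
    return "fetal" if d_fetal < d_maternal else "maternal"
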