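"""Equal-read windowing, relative read numbers and GC-bias correction.

This is the normalization front-end every caller consumes.  The screening
signal is the *relative* read number per window (window count over the mean
window count); the systematic linear dependence of that ratio on window GC
content is fitted by ordinary least squares and divided out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinTable",
    "GcFit",
    "WindowBoundaries",
    "make_windows",
    "aggregate_windows",
    "relative_reads",
    "fit_gc",
    "correct_gc",
]

_EPS = 1e-6  # floor for fitted GC factors; guards divide-by-zero


@dataclass
class BinTable:
    """Per-window read counts with GC content and normalized ratios.

    Windows are 0-based half-open intervals tiling each chromosome without
    overlap.  ``relative_reads`` has mean exactly 1; ``corrected_ratio`` is
    the GC-corrected relative read number, renormalized to mean 1.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    raw_count: np.ndarray
    relative_reads: np.ndarray | None = None
    corrected_ratio: np.ndarray | None = None
    flagged: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.raw_count)
        for name in ("chrom", "start", "end", "gc"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")

    @property
    def n_windows(self) -> int:
        return int(len(self.raw_count))

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return np.asarray(self.chrom) == chrom

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "gc": self.gc,
            "raw_count": self.raw_count,
        }
        if self.relative_reads is not None:
            cols["relative_reads"] = self.relative_reads
        if self.corrected_ratio is not None:
            cols["corrected_ratio"] = self.corrected_ratio
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinTable":
        required = ["chrom", "start", "end", "gc", "raw_count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        kw = {}
        for opt in ("relative_reads", "corrected_ratio"):
            if opt in df.columns:
                kw[opt] = df[opt].to_numpy(float)
        return cls(
            chrom=df["chrom"].to_numpy(object),
            start=df["start"].to_numpy(np.int64),
            end=df["end"].to_numpy(np.int64),
            gc=df["gc"].to_numpy(float),
            raw_count=df["raw_count"].to_numpy(float),
            **kw,
        )


@dataclass(frozen=True)
class GcFit:
    """OLS line relating window GC content to relative read number."""

    intercept: float
    slope: float
    residual_sd: float
    degenerate: bool = False  # constant GC → identity fit

    def fitted(self, gc: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(gc, float)


@dataclass(frozen=True)
class WindowBoundaries:
    """Equal-read window edges expressed as fine-bin index ranges.

    ``edges`` maps chromosome → array of fine-bin indices (into the
    chromosome's own bins) of length n_windows+1.
    """

    edges: dict[str, np.ndarray]

    @property
    def n_windows(self) -> int:
        return sum(len(e) - 1 for e in self.edges.values())


def make_windows(
    chrom: np.ndarray,
    reference_counts: np.ndarray,
    n_windows: int,
) -> WindowBoundaries:
    """Partition fine bins into windows of (near-)equal expected read mass.

    Windows never span chromosomes: each chromosome receives a share of the
    ``n_windows`` proportional to its expected read mass (at least one, at
    most its fine-bin count, largest-remainder rounding), and within a
    chromosome the cut points are mass quantiles of the cumulative expected
    counts.  Equality is therefore exact up to one fine-bin quantum.
    """
    chrom = np.asarray(chrom, dtype=object)
    counts = np.asarray(reference_counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("reference counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total expected reads must be positive")
    chroms = list(dict.fromkeys(chrom))
    if n_windows < len(chroms):
        raise ValueError("n_windows must be at least the number of chromosomes")
    if n_windows > counts.size:
        raise ValueError("n_windows exceeds the number of fine bins")

    masks = {c: chrom == c for c in chroms}
    masses = np.array([counts[masks[c]].sum() for c in chroms])
    nbins = np.array([int(masks[c].sum()) for c in chroms])
    # Largest-remainder allocation with [1, nbins] clamping.
    ideal = masses / total * n_windows
    alloc = np.clip(np.floor(ideal).astype(int), 1, nbins)
    while alloc.sum() != n_windows:
        if alloc.sum() < n_windows:
            room = alloc < nbins
            frac = np.where(room, ideal - alloc, -np.inf)
            alloc[int(np.argmax(frac))] += 1
        else:
            shrink = alloc > 1
            frac = np.where(shrink, ideal - alloc, np.inf)
            alloc[int(np.argmin(frac))] -= 1

    edges: dict[str, np.ndarray] = {}
    for c, k in zip(chroms, alloc):
        cm = counts[masks[c]]
        n = cm.size
        cum = np.cumsum(cm)
        targets = cum[-1] * np.arange(1, k) / k
        cuts = np.searchsorted(cum, targets, side="left") + 1
        # enforce strictly increasing cuts so every window holds >= 1 bin
        cuts = np.maximum.accumulate(np.clip(cuts, 1, n - 1))
        for i in range(1, cuts.size):
            if cuts[i] <= cuts[i - 1]:
                cuts[i] = cuts[i - 1] + 1
        cuts = np.minimum(cuts, n - (k - 1) + np.arange(cuts.size))
        edges[c] = np.concatenate([[0], cuts, [n]]).astype(int)
    return WindowBoundaries(edges=edges)


def aggregate_windows(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    gc: np.ndarray,
    counts: np.ndarray,
    boundaries: WindowBoundaries,
) -> BinTable:
    """Sum fine-bin counts into the given equal-read windows.

    Window GC is the unweighted mean of member fine-bin GC (fine bins share
    one width).
    """
    chrom = np.asarray(chrom, dtype=object)
    counts = np.asarray(counts, float)
    block_starts = np.concatenate([[0], np.flatnonzero(chrom[1:] != chrom[:-1]) + 1])
    block_ends = np.concatenate([block_starts[1:], [chrom.size]])
    blocks = {str(chrom[s]): (int(s), int(t))
              for s, t in zip(block_starts, block_ends)}
    out_chrom, out_start, out_end, out_gc, out_counts = [], [], [], [], []
    for c, e in boundaries.edges.items():
        lo, hi = blocks[c]
        sl = slice(lo, hi)
        cs, ce, cgc, cc = start[sl], end[sl], gc[sl], counts[sl]
        if cs.size < e[-1]:
            raise ValueError(f"boundaries for {c} exceed available fine bins")
        sums = np.add.reduceat(cc, e[:-1])
        gcs = np.add.reduceat(cgc, e[:-1]) / np.diff(e)
        out_chrom.extend([c] * (len(e) - 1))
        out_start.append(cs[e[:-1]])
        out_end.append(ce[e[1:] - 1])
        out_gc.append(gcs)
        out_counts.append(sums)
    return BinTable(
        chrom=np.asarray(out_chrom, dtype=object),
        start=np.concatenate(out_start),
        end=np.concatenate(out_end),
        gc=np.concatenate(out_gc),
        raw_count=np.concatenate(out_counts),
    )


def relative_reads(raw_counts: np.ndarray) -> np.ndarray:
    """Window count over the mean window count; the mean of the result is 1."""
    c = np.asarray(raw_counts, dtype=float)
    mean = c.mean()
    if not mean > 0:
        raise ValueError("mean read count must be positive")
    return c / mean


def fit_gc(gc: np.ndarray, r: np.ndarray) -> GcFit:
    """Least-squares line of relative read number on GC content."""
    gc = np.asarray(gc, float)
    r = np.asarray(r, float)
    if gc.size < 3:
        raise ValueError("need at least 3 windows to fit the GC effect")
    if np.ptp(gc) == 0:
        return GcFit(intercept=float(r.mean()), slope=0.0,
                     residual_sd=float(r.std(ddof=1)), degenerate=True)
    res = stats.linregress(gc, r)
    resid = r - (res.intercept + res.slope * gc)
    dof = max(gc.size - 2, 1)
    return GcFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def correct_gc(
    bins: BinTable,
    fit: GcFit | None = None,
    norm_mask: np.ndarray | None = None,
) -> BinTable:
    """Divide relative reads by the fitted GC factor; renormalize to mean 1.

    The correction is multiplicative so positivity and scale invariance are
    preserved.  Windows whose fitted factor is non-positive are clamped to a
    small epsilon and flagged.  ``norm_mask`` restricts the mean-1
    renormalization (and the default fit) to a subset of windows — the
    pipeline passes the autosomes, whose copy state is diploid regardless
    of fetal sex, so the near-empty chrY windows cannot drag the baseline.
    """
    rel = bins.relative_reads
    if rel is None:
        rel = relative_reads(bins.raw_count)
    if fit is None:
        if norm_mask is not None:
            fit = fit_gc(bins.gc[norm_mask], rel[norm_mask])
        else:
            fit = fit_gc(bins.gc, rel)
    factor = fit.fitted(bins.gc)
    flagged = factor <= 0
    factor = np.where(flagged, _EPS, factor)
    corrected = rel / factor
    denom = corrected[norm_mask].mean() if norm_mask is not None else corrected.mean()
    corrected = corrected / denom
    return replace(bins, relative_reads=rel, corrected_ratio=corrected,
                   flagged=flagged)
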