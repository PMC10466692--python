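"""Fetal-fraction (cffDNA proportion) estimation.

Two independent routes, as used clinically:

* **chrY route** — in a male pregnancy, chrY reads above the female
  mismapping background scale linearly with fetal fraction; invert that
  line.  Undefined for female fetuses.
* **seqFF-style route** — placentally derived fragments are shorter, so the
  genome-wide proportion of 100–150 bp fragments rises with fetal fraction.
  A ridge regression of true ff on {short-fragment proportion, mean GC,
  log total fragments} is trained on calibration samples and applied to any
  sample regardless of fetal sex.

The two are combined (mean when Y evidence is present, seqFF alone
otherwise) and checked against the 3.5% lower detection limit below which a
sample is a no-call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

__all__ = [
    "FragmentProfile",
    "FetalFractionEstimate",
    "SeqffModel",
    "estimate_ff_y",
    "train_seqff",
    "estimate_ff_seqff",
    "combine_ff",
    "DEFAULT_LOD",
]

DEFAULT_LOD = 0.035  # lower detection limit on the combined cffDNA fraction


@dataclass
class FragmentProfile:
    """Per-bin fragment-length class counts (50 kb bins).

    ``n_short`` counts fragments of 100–150 bp; ``n_total`` all fragments.
    ``gc`` is optional (the seqFF GC feature falls back to a constant, and
    the model to its univariate form, when it is absent).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    n_short: np.ndarray
    n_total: np.ndarray
    gc: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.n_short > self.n_total):
            raise ValueError("short-fragment count exceeds total count")

    def autosomal_mask(self) -> np.ndarray:
        c = np.asarray(self.chrom, dtype=object)
        return (c != "chrX") & (c != "chrY")

    def features(self) -> np.ndarray:
        """seqFF feature vector: short proportion, mean GC, log total reads."""
        m = self.autosomal_mask()
        tot = float(self.n_total[m].sum())
        if tot <= 0:
            raise ValueError("profile holds no autosomal fragments")
        short_prop = float(self.n_short[m].sum()) / tot
        if self.gc is not None:
            mean_gc = float(np.average(self.gc[m], weights=self.n_total[m]))
        else:
            mean_gc = 0.5
        return np.array([short_prop, mean_gc, np.log(tot)])

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "n_short_100_150": self.n_short, "n_total": self.n_total,
        }
        if self.gc is not None:
            cols["gc"] = self.gc
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FragmentProfile":
        required = ["chrom", "start", "end", "n_short_100_150", "n_total"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        return cls(
            chrom=df["chrom"].to_numpy(object),
            start=df["start"].to_numpy(np.int64),
            end=df["end"].to_numpy(np.int64),
            n_short=df["n_short_100_150"].to_numpy(float),
            n_total=df["n_total"].to_numpy(float),
            gc=df["gc"].to_numpy(float) if "gc" in df.columns else None,
        )


@dataclass
class FetalFractionEstimate:
    """Combined cffDNA proportion with the no-call (LOD) flag."""

    ff_y: float | None
    ff_seqff: float | None
    ff_combined: float | None
    below_lod: bool
    lod: float = DEFAULT_LOD
    qc_fail: bool = False


def estimate_ff_y(
    bins,
    background_y: float,
    male_reference_y: float,
    noise_margin: float = 0.0,
) -> float | None:
    """chrY-route fetal fraction; ``None`` when no Y signal (female fetus).

    ``bins`` is a GC-corrected :class:`~cfscreen.windows.BinTable`.  The
    observed chrY mass fraction is interpolated between the female
    background (``background_y``) and the pure-fetal male reference
    (``male_reference_y``, the fraction at ff = 1) and clamped to [0, 1].
    """
    if not background_y < male_reference_y:
        raise ValueError("background_y must be below male_reference_y")
    values = bins.corrected_ratio
    if values is None:
        values = bins.raw_count.astype(float)
    ymask = bins.chrom_mask("chrY")
    if not ymask.any():
        warnings.warn("no chrY windows: chrY fetal fraction undefined", stacklevel=2)
        return None
    observed = float(values[ymask].sum() / values.sum())
    if observed <= background_y + noise_margin:
        return None
    return float(np.clip(
        (observed - background_y) / (male_reference_y - background_y), 0.0, 1.0
    ))


@dataclass
class SeqffModel:
    """Ridge regression of fetal fraction on fragment-profile features."""

    coef: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    feature_names: tuple[str, ...] = (
        "short_fragment_proportion", "mean_gc", "log_total_reads",
    )
    n_train: int = 0
    univariate_fallback: bool = False
    feature_min: np.ndarray = field(default=None, repr=False)
    feature_max: np.ndarray = field(default=None, repr=False)
    last_extrapolated: bool = field(default=False, repr=False)

    def predict(self, features: np.ndarray) -> float:
        z = (np.asarray(features, float) - self.feature_mean) / self.feature_sd
        return float(self.intercept + z @ self.coef)


def train_seqff(
    calibration: list[tuple[FragmentProfile, float]],
    alpha: float = 1e-3,
) -> SeqffModel:
    """Fit the seqFF regression on (profile, true ff) calibration pairs.

    Features are standardized; the ridge penalty (default 1e-3) leaves the
    intercept free, so the model predicts the training-mean ff at the
    training-mean feature vector exactly.  Rank-deficient features (any
    constant column) trigger a flagged univariate fall-back on the
    short-fragment proportion alone.
    """
    if len(calibration) < 20:
        raise ValueError("need at least 20 calibration samples")
    X = np.vstack([p.features() for p, _ in calibration])
    y = np.array([ff for _, ff in calibration], float)

    sd = X.std(axis=0, ddof=0)
    fallback = bool(np.any(sd[1:] == 0))
    if sd[0] == 0:
        raise ValueError("short-fragment proportion is constant: cannot calibrate")
    if fallback:
        X = X[:, :1]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = (X - mean) / sd
    model = Ridge(alpha=alpha, fit_intercept=True)
    model.fit(Z, y)
    return SeqffModel(
        coef=model.coef_.copy(),
        intercept=float(model.intercept_),
        feature_mean=mean,
        feature_sd=sd,
        feature_names=("short_fragment_proportion",) if fallback else
        ("short_fragment_proportion", "mean_gc", "log_total_reads"),
        n_train=len(calibration),
        univariate_fallback=fallback,
        feature_min=X.min(axis=0),
        feature_max=X.max(axis=0),
    )


def estimate_ff_seqff(model: SeqffModel, profile: FragmentProfile) -> float:
    """Predict the cffDNA proportion for one sample, clamped to [0, 1].

    Sets ``model.last_extrapolated`` when any feature falls outside the
    training range.
    """
    x = profile.features()[: model.coef.size]
    model.last_extrapolated = bool(
        np.any(x < model.feature_min) or np.any(x > model.feature_max)
    )
    # clamp the nuisance features (mean GC, log read count — near-constant
    # in calibration) to the calibrated range so they cannot extrapolate
    # wildly; the short-fragment proportion itself extrapolates linearly
    if x.size > 1:
        x = np.concatenate([
            x[:1], np.clip(x[1:], model.feature_min[1:], model.feature_max[1:])
        ])
    return float(np.clip(model.predict(x), 0.0, 1.0))


def combine_ff(
    ff_y: float | None,
    ff_seqff: float | None,
    male_evidence: bool,
    lod: float = DEFAULT_LOD,
) -> FetalFractionEstimate:
    """Combine the two routes: mean when male evidence, seqFF otherwise."""
    if ff_y is None and ff_seqff is None:
        return FetalFractionEstimate(
            ff_y=None, ff_seqff=None, ff_combined=None,
            below_lod=True, lod=lod, qc_fail=True,
        )
    if male_evidence and ff_y is not None and ff_seqff is not None:
        combined = 0.5 * (ff_y + ff_seqff)
    elif ff_seqff is not None:
        combined = ff_seqff
    else:
        combined = ff_y
    return FetalFractionEstimate(
        ff_y=ff_y, ff_seqff=ff_seqff, ff_combined=float(combined),
        below_lod=bool(combined < lod), lod=lod,
    )


def calibrate_y_reference(genome) -> tuple[float, float]:
    """Analytic (background_y, male_reference_y) for a synthetic genome.

    Computed from noise-free expectations of a pure-female (ff = 0) and a
    hypothetical all-fetal male (ff = 1) synthesis with neutral GC, so the
    estimator is self-calibrating against the simulator's own genome.
    """
    ymask = genome.chrom_mask("chrY")
    n = genome.n_bins

    def y_fraction(y_rate: float, x_rate: float) -> float:
        rate = np.ones(n)
        rate[genome.chrom_mask("chrX")] = x_rate
        rate[ymask] = y_rate + genome.y_background
        return float(rate[ymask].sum() / rate.sum())

    background = y_fraction(0.0, 1.0)          # female: X ratio 1, Y only background
    male_ref = y_fraction(0.5, 0.5)            # ff=1 male: one X, one Y per diploid
    return background, male_ref
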